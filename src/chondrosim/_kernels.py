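"""Numba kernels for force accumulation and blocked forward-Euler integration.

Two accumulators compute the same net forces:

* ``accumulate_all_pairs`` -- O(N^2) loop over unordered pairs, each pair's
  contribution added to both cells with exact antisymmetry. For a fixed row
  ``i`` contributions arrive in ascending partner order.
* ``accumulate_grid`` -- linked-cell accumulation on a uniform grid of bin
  width ``s``. The compact support of the force guarantees the visited pair
  set is identical to all-pairs; only the floating-point summation order
  differs (documented in docs/methods.md). Falls back to all-pairs when the
  population is small or spread over too many bins.

``integrate_block`` advances several pure-mechanics steps (no divisions due)
in one call: synchronous Euler update from forces evaluated at the
pre-update positions, then projection of midpoints back onto the rigid
boundary planes in z. Coincident midpoints (distance < 1e-12) abort the
block so the caller can apply the randomised-direction policy outside
numba.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_COINCIDENT = 1


@njit(cache=True)
def accumulate_all_pairs(pos, mu, s, F):
    n = pos.shape[0]
    s2 = s * s
    ncoin = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= s2:
                continue
            if r2 < 1e-24:
                ncoin += 1
                continue
            r = np.sqrt(r2)
            f = -mu * (1.0 - r / s) ** 2 / r
            fx = f * dx
            fy = f * dy
            fz = f * dz
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz
    return ncoin


@njit(cache=True)
def accumulate_grid(pos, mu, s, F):
    n = pos.shape[0]
    if n < 64:
        return accumulate_all_pairs(pos, mu, s, F)
    xmin = pos[0, 0]
    xmax = pos[0, 0]
    ymin = pos[0, 1]
    ymax = pos[0, 1]
    zmin = pos[0, 2]
    zmax = pos[0, 2]
    for i in range(1, n):
        if pos[i, 0] < xmin:
            xmin = pos[i, 0]
        elif pos[i, 0] > xmax:
            xmax = pos[i, 0]
        if pos[i, 1] < ymin:
            ymin = pos[i, 1]
        elif pos[i, 1] > ymax:
            ymax = pos[i, 1]
        if pos[i, 2] < zmin:
            zmin = pos[i, 2]
        elif pos[i, 2] > zmax:
            zmax = pos[i, 2]
    inv = 1.0 / s
    nx = int((xmax - xmin) * inv) + 1
    ny = int((ymax - ymin) * inv) + 1
    nz = int((zmax - zmin) * inv) + 1
    nb = nx * ny * nz
    if nb > 8 * n + 1024:
        return accumulate_all_pairs(pos, mu, s, F)

    binidx = np.empty(n, dtype=np.int64)
    bx = np.empty(n, dtype=np.int64)
    by = np.empty(n, dtype=np.int64)
    bz = np.empty(n, dtype=np.int64)
    for i in range(n):
        bx[i] = int((pos[i, 0] - xmin) * inv)
        by[i] = int((pos[i, 1] - ymin) * inv)
        bz[i] = int((pos[i, 2] - zmin) * inv)
        binidx[i] = (bx[i] * ny + by[i]) * nz + bz[i]
    head = np.full(nb, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    # build linked lists in reverse so traversal is in ascending row order
    for i in range(n - 1, -1, -1):
        nxt[i] = head[binidx[i]]
        head[binidx[i]] = i

    s2 = s * s
    ncoin = 0
    for i in range(n):
        for ox in range(-1, 2):
            cx = bx[i] + ox
            if cx < 0 or cx >= nx:
                continue
            for oy in range(-1, 2):
                cy = by[i] + oy
                if cy < 0 or cy >= ny:
                    continue
                for oz in range(-1, 2):
                    cz = bz[i] + oz
                    if cz < 0 or cz >= nz:
                        continue
                    j = head[(cx * ny + cy) * nz + cz]
                    while j >= 0:
                        if j > i:
                            dx = pos[j, 0] - pos[i, 0]
                            dy = pos[j, 1] - pos[i, 1]
                            dz = pos[j, 2] - pos[i, 2]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < s2:
                                if r2 < 1e-24:
                                    ncoin += 1
                                else:
                                    r = np.sqrt(r2)
                                    f = -mu * (1.0 - r / s) ** 2 / r
                                    fx = f * dx
                                    fy = f * dy
                                    fz = f * dz
                                    F[i, 0] += fx
                                    F[i, 1] += fy
                                    F[i, 2] += fz
                                    F[j, 0] -= fx
                                    F[j, 1] -= fy
                                    F[j, 2] -= fz
                        j = nxt[j]
    return ncoin


@njit(cache=True)
def integrate_block(pos, n_steps, dt_over_eta, mu, s, l, u, maxdisp, md_offset):
    """Advance ``n_steps`` mechanics-only steps in place.

    Writes the maximum per-cell Euler displacement of step k (before the
    boundary projection) to ``maxdisp[md_offset + k]``. Returns
    ``(steps_completed, status)``; on STATUS_COINCIDENT the positions are
    those *before* the offending step, which the caller must redo with the
    randomised-direction policy.
    """
    n = pos.shape[0]
    F = np.zeros((n, 3))
    for k in range(n_steps):
        for i in range(n):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
        ncoin = accumulate_grid(pos, mu, s, F)
        if ncoin > 0:
            return k, STATUS_COINCIDENT
        md = 0.0
        for i in range(n):
            for d in range(3):
                delta = dt_over_eta * F[i, d]
                pos[i, d] += delta
                a = abs(delta)
                if a > md:
                    md = a
            if pos[i, 2] < l:
                pos[i, 2] = l
            elif pos[i, 2] > u:
                pos[i, 2] = u
        maxdisp[md_offset + k] = md
    return n_steps, STATUS_OK
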