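"""Numba-compiled hot loops: Euler integration and pair-distance histograms.

The integration kernel advances the self-propelled-particle dynamics

    x_i(t+dt) = x_i(t) + dt v_i(t)
    v_i(t+dt) = v_i(t) + dt (F_int + F_sc) + noise

with the interaction network evaluated from the positions at every step
(metric rule) or frozen to a precomputed CSR neighbour list.  The
Gaussian noise increment has per-component variance ``2 T dt``, so the
stationary distribution of the frozen-network dynamics is the Boltzmann
weight exp(-H/T) of the model cost function.

Velocities enter the position update *before* they are themselves
updated, matching the explicit Euler scheme of the model definition.

The per-step metric adjacency (minimum-image distance < r_c) is exact;
for speed it is evaluated against a Verlet candidate list built with a
safety skin and refreshed whenever any particle has moved more than
half the skin since the last build, which guarantees the candidate list
always contains every pair within r_c.
"""

from __future__ import annotations

import numpy as np
from numba import njit

CONTROL_NONE = 0
CONTROL_LINEAR = 1
CONTROL_QUARTIC = 2
CONTROL_MARGINAL = 3

SKIN = 0.3  # Verlet skin (length units); candidates use cutoff r_c + SKIN

# failure codes returned by _advance
OK = 0
NONFINITE = 1
ZERO_SPEED = 2


@njit(cache=True)
def _count_or_fill_pairs(pos, L, rcut, ncx, ncy, ncz, start, order, cell_of,
                         pairs_i, pairs_j, fill):
    """Cell-list pass over unordered pairs within rcut; count or fill."""
    N = pos.shape[0]
    rcut2 = rcut * rcut
    use_cells = ncx >= 3 and ncy >= 3 and ncz >= 3
    n = 0
    if use_cells:
        for i in range(N):
            c = cell_of[i]
            iz = c % ncz
            iy = (c // ncz) % ncy
            ix = c // (ncz * ncy)
            for ox in range(-1, 2):
                jx = ix + ox
                if jx < 0:
                    jx += ncx
                elif jx >= ncx:
                    jx -= ncx
                for oy in range(-1, 2):
                    jy = iy + oy
                    if jy < 0:
                        jy += ncy
                    elif jy >= ncy:
                        jy -= ncy
                    for oz in range(-1, 2):
                        jz = iz + oz
                        if jz < 0:
                            jz += ncz
                        elif jz >= ncz:
                            jz -= ncz
                        cc = (jx * ncy + jy) * ncz + jz
                        for k in range(start[cc], start[cc + 1]):
                            j = order[k]
                            if j <= i:
                                continue
                            dx = pos[i, 0] - pos[j, 0]
                            if dx > 0.5 * L[0]:
                                dx -= L[0]
                            elif dx < -0.5 * L[0]:
                                dx += L[0]
                            dy = pos[i, 1] - pos[j, 1]
                            if dy > 0.5 * L[1]:
                                dy -= L[1]
                            elif dy < -0.5 * L[1]:
                                dy += L[1]
                            dz = pos[i, 2] - pos[j, 2]
                            if dz > 0.5 * L[2]:
                                dz -= L[2]
                            elif dz < -0.5 * L[2]:
                                dz += L[2]
                            if dx * dx + dy * dy + dz * dz < rcut2:
                                if fill:
                                    pairs_i[n] = i
                                    pairs_j[n] = j
                                n += 1
    else:
        for i in range(N):
            for j in range(i + 1, N):
                dx = pos[i, 0] - pos[j, 0]
                dx -= L[0] * np.round(dx / L[0])
                dy = pos[i, 1] - pos[j, 1]
                dy -= L[1] * np.round(dy / L[1])
                dz = pos[i, 2] - pos[j, 2]
                dz -= L[2] * np.round(dz / L[2])
                if dx * dx + dy * dy + dz * dz < rcut2:
                    if fill:
                        pairs_i[n] = i
                        pairs_j[n] = j
                    n += 1
    return n


@njit(cache=True)
def _bin_cells(pos, L, ncx, ncy, ncz, count, start, order, cell_of):
    """Counting sort of particles into cells; fills start/order/cell_of."""
    N = pos.shape[0]
    ncells = ncx * ncy * ncz
    csx = L[0] / ncx
    csy = L[1] / ncy
    csz = L[2] / ncz
    for c in range(ncells):
        count[c] = 0
    for i in range(N):
        ix = int(pos[i, 0] / csx)
        iy = int(pos[i, 1] / csy)
        iz = int(pos[i, 2] / csz)
        if ix >= ncx:
            ix = ncx - 1
        if iy >= ncy:
            iy = ncy - 1
        if iz >= ncz:
            iz = ncz - 1
        c = (ix * ncy + iy) * ncz + iz
        cell_of[i] = c
        count[c] += 1
    s = 0
    for c in range(ncells):
        start[c] = s
        s += count[c]
        count[c] = 0
    start[ncells] = s
    for i in range(N):
        c = cell_of[i]
        order[start[c] + count[c]] = i
        count[c] += 1


@njit(cache=True)
def _advance(pos, vel, L, J, g, lam, control, v0i, Ti, dt, rc,
             freeze, indptr, indices, nsteps, stride,
             out_t, out_pos, out_vel, t0, seed):
    """Advance ``nsteps`` Euler steps in place; sample every ``stride`` steps.

    Returns ``(step, agent, code)``; code 0 means success (step/agent -1),
    1 a non-finite velocity, 2 a zero speed under linear control.
    """
    np.random.seed(seed)
    N = pos.shape[0]
    F = np.zeros((N, 3))
    sig = np.sqrt(2.0 * Ti * dt)
    rc2 = rc * rc
    nsamp = 0
    # per-agent control coefficients (heterogeneous v0 allowed)
    v0sq = v0i * v0i
    c_quart = 4.0 * g / v0sq
    c_marg = 8.0 * lam / (v0sq * v0sq * v0sq)

    # Verlet candidate list machinery (rebuilt-network mode only)
    rcut = rc + SKIN
    ncx = max(int(L[0] / rcut), 1)
    ncy = max(int(L[1] / rcut), 1)
    ncz = max(int(L[2] / rcut), 1)
    ncells = ncx * ncy * ncz
    count = np.zeros(ncells, np.int64)
    start = np.zeros(ncells + 1, np.int64)
    order = np.zeros(N, np.int64)
    cell_of = np.zeros(N, np.int64)
    pairs_i = np.zeros(0, np.int64)
    pairs_j = np.zeros(0, np.int64)
    npairs = 0
    ref = pos.copy()
    trigger2 = 0.25 * SKIN * SKIN
    if not freeze:
        _bin_cells(pos, L, ncx, ncy, ncz, count, start, order, cell_of)
        npairs = _count_or_fill_pairs(pos, L, rcut, ncx, ncy, ncz, start, order,
                                      cell_of, pairs_i, pairs_j, False)
        pairs_i = np.zeros(npairs, np.int64)
        pairs_j = np.zeros(npairs, np.int64)
        _count_or_fill_pairs(pos, L, rcut, ncx, ncy, ncz, start, order,
                             cell_of, pairs_i, pairs_j, True)
        for i in range(N):
            for a in range(3):
                ref[i, a] = pos[i, a]

    for step in range(nsteps):
        # ---- alignment sums  F[i] = sum_j (v_j - v_i)  over neighbours at time t
        if freeze:
            for i in range(N):
                fx = 0.0
                fy = 0.0
                fz = 0.0
                for k in range(indptr[i], indptr[i + 1]):
                    j = indices[k]
                    fx += vel[j, 0] - vel[i, 0]
                    fy += vel[j, 1] - vel[i, 1]
                    fz += vel[j, 2] - vel[i, 2]
                F[i, 0] = fx
                F[i, 1] = fy
                F[i, 2] = fz
        else:
            # refresh the candidate list if any displacement exceeds skin/2
            maxd2 = 0.0
            for i in range(N):
                dx = pos[i, 0] - ref[i, 0]
                if dx > 0.5 * L[0]:
                    dx -= L[0]
                elif dx < -0.5 * L[0]:
                    dx += L[0]
                dy = pos[i, 1] - ref[i, 1]
                if dy > 0.5 * L[1]:
                    dy -= L[1]
                elif dy < -0.5 * L[1]:
                    dy += L[1]
                dz = pos[i, 2] - ref[i, 2]
                if dz > 0.5 * L[2]:
                    dz -= L[2]
                elif dz < -0.5 * L[2]:
                    dz += L[2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > maxd2:
                    maxd2 = d2
            if maxd2 > trigger2:
                _bin_cells(pos, L, ncx, ncy, ncz, count, start, order, cell_of)
                n = _count_or_fill_pairs(pos, L, rcut, ncx, ncy, ncz, start,
                                         order, cell_of, pairs_i, pairs_j, False)
                if n != npairs:
                    pairs_i = np.zeros(n, np.int64)
                    pairs_j = np.zeros(n, np.int64)
                    npairs = n
                _count_or_fill_pairs(pos, L, rcut, ncx, ncy, ncz, start, order,
                                     cell_of, pairs_i, pairs_j, True)
                for i in range(N):
                    for a in range(3):
                        ref[i, a] = pos[i, a]
            for i in range(N):
                F[i, 0] = 0.0
                F[i, 1] = 0.0
                F[i, 2] = 0.0
            for k in range(npairs):
                i = pairs_i[k]
                j = pairs_j[k]
                dx = pos[i, 0] - pos[j, 0]
                if dx > 0.5 * L[0]:
                    dx -= L[0]
                elif dx < -0.5 * L[0]:
                    dx += L[0]
                dy = pos[i, 1] - pos[j, 1]
                if dy > 0.5 * L[1]:
                    dy -= L[1]
                elif dy < -0.5 * L[1]:
                    dy += L[1]
                dz = pos[i, 2] - pos[j, 2]
                if dz > 0.5 * L[2]:
                    dz -= L[2]
                elif dz < -0.5 * L[2]:
                    dz += L[2]
                if dx * dx + dy * dy + dz * dz < rc2:
                    ex = vel[j, 0] - vel[i, 0]
                    ey = vel[j, 1] - vel[i, 1]
                    ez = vel[j, 2] - vel[i, 2]
                    F[i, 0] += ex
                    F[i, 1] += ey
                    F[i, 2] += ez
                    F[j, 0] -= ex
                    F[j, 1] -= ey
                    F[j, 2] -= ez

        # ---- positions advance with the pre-update velocities, then wrap
        # (per-step displacements are far below L, so one wrap suffices)
        for i in range(N):
            for a in range(3):
                x = pos[i, a] + dt * vel[i, a]
                if x >= L[a]:
                    x -= L[a]
                elif x < 0.0:
                    x += L[a]
                if x >= L[a] or x < 0.0:
                    x -= L[a] * np.floor(x / L[a])
                pos[i, a] = x

        # ---- velocity update: imitation + speed control + noise
        for i in range(N):
            v0_ = v0i[i]
            vx = vel[i, 0]
            vy = vel[i, 1]
            vz = vel[i, 2]
            v2 = vx * vx + vy * vy + vz * vz
            f = 0.0
            if control == CONTROL_LINEAR:
                sp = np.sqrt(v2)
                if sp < 1e-300:
                    return step, i, ZERO_SPEED
                f = 2.0 * g * (v0_ - sp) / sp
            elif control == CONTROL_QUARTIC:
                f = c_quart[i] * (v0sq[i] - v2)
            elif control == CONTROL_MARGINAL:
                q = v0sq[i] - v2
                f = c_marg[i] * q * q * q
            nvx = vx + dt * (J * F[i, 0] + f * vx) + sig[i] * np.random.standard_normal()
            nvy = vy + dt * (J * F[i, 1] + f * vy) + sig[i] * np.random.standard_normal()
            nvz = vz + dt * (J * F[i, 2] + f * vz) + sig[i] * np.random.standard_normal()
            if not (np.isfinite(nvx) and np.isfinite(nvy) and np.isfinite(nvz)):
                return step, i, NONFINITE
            vel[i, 0] = nvx
            vel[i, 1] = nvy
            vel[i, 2] = nvz

        if stride > 0 and (step + 1) % stride == 0:
            out_t[nsamp] = t0 + (step + 1) * dt
            for i in range(N):
                for a in range(3):
                    out_pos[nsamp, i, a] = pos[i, a]
                    out_vel[nsamp, i, a] = vel[i, a]
            nsamp += 1

    return -1, -1, OK


@njit(cache=True)
def _pair_histogram(pos, weights, L, periodic, edges):
    """Binned sums of ``w_i w_j`` and pair counts over unordered pairs.

    Distances are minimum-image when ``periodic`` is True.  Bins are
    half-open ``[lo, hi)`` on a uniform grid defined by ``edges``.
    Returns (weighted sums, counts), both per bin, counting each
    unordered pair once.
    """
    N = pos.shape[0]
    nb = edges.shape[0] - 1
    h = edges[1] - edges[0]
    rmax = edges[nb]
    sums = np.zeros(nb)
    counts = np.zeros(nb, np.int64)
    for i in range(N):
        for j in range(i + 1, N):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if periodic:
                dx -= L[0] * np.round(dx / L[0])
                dy -= L[1] * np.round(dy / L[1])
                dz -= L[2] * np.round(dz / L[2])
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r >= rmax:
                continue
            b = int(r / h)
            if b >= nb:
                b = nb - 1
            sums[b] += weights[i] * weights[j]
            counts[b] += 1
    return sums, counts
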