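"""Numba-compiled hot loops of the lattice engine.

Two kernels dominate run time and are compiled: the explicit diffusion
sub-stepping of the cytokine fields, and the sequential stochastic
agent-behavior phase (death, lysis, suppression, division with fate
choice, migration) executed in a shuffled agent order.  All randomness
flows through a single ``numpy.random.Generator`` passed in, so runs are
bit-reproducible for a fixed seed.

Agent-kind codes: 0 MIC, 1 MM, 2 CD8, 3 Treg.  Occupancy codes: the
agent's slot index, −1 free, −2 outside the cylindrical mask.
Event columns: 0 birth, 1 death, 2 lysis, 3 differentiation (an MIC
leaving its compartment by converting to two MM daughters).
"""

from __future__ import annotations

import numpy as np
from numba import njit

MIC, MM, CD8, TREG = 0, 1, 2, 3
EV_BIRTH, EV_DEATH, EV_LYSIS, EV_DIFF = 0, 1, 2, 3

# 26-site Moore neighborhood offsets
_OFFS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if not (dx == 0 and dy == 0 and dz == 0)
    ],
    dtype=np.int64,
)


@njit(cache=True)
def diffuse_steps(grid, D, h, nsub, boundary):
    """``nsub`` explicit 7-point-stencil substeps of step ``h`` in place.

    Dirichlet condition: the outer shell of the box is held at
    ``boundary`` throughout.  Caller is responsible for the stability
    bound D·h ≤ 1/6.
    """
    nx, ny, nz = grid.shape
    buf = np.empty_like(grid)
    a = grid
    b = buf
    for _ in range(nsub):
        # enforce boundary on the source array
        for j in range(ny):
            for k in range(nz):
                a[0, j, k] = boundary
                a[nx - 1, j, k] = boundary
        for i in range(nx):
            for k in range(nz):
                a[i, 0, k] = boundary
                a[i, ny - 1, k] = boundary
        for i in range(nx):
            for j in range(ny):
                a[i, j, 0] = boundary
                a[i, j, nz - 1] = boundary
        c = D * h
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                for k in range(1, nz - 1):
                    lap = (
                        a[i - 1, j, k]
                        + a[i + 1, j, k]
                        + a[i, j - 1, k]
                        + a[i, j + 1, k]
                        + a[i, j, k - 1]
                        + a[i, j, k + 1]
                        - 6.0 * a[i, j, k]
                    )
                    b[i, j, k] = a[i, j, k] + c * lap
        for j in range(ny):
            for k in range(nz):
                b[0, j, k] = boundary
                b[nx - 1, j, k] = boundary
        for i in range(nx):
            for k in range(nz):
                b[i, 0, k] = boundary
                b[i, ny - 1, k] = boundary
        for i in range(nx):
            for j in range(ny):
                b[i, j, 0] = boundary
                b[i, j, nz - 1] = boundary
        a, b = b, a
    if a is not grid:
        grid[:, :, :] = a
    return grid


@njit(cache=True)
def pick_free_neighbor(occ, x, y, z, rng):
    """Uniformly random free Moore neighbor; (-1,-1,-1) if none."""
    nx, ny, nz = occ.shape
    count = 0
    for m in range(26):
        i = x + _OFFS[m, 0]
        j = y + _OFFS[m, 1]
        k = z + _OFFS[m, 2]
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz and occ[i, j, k] == -1:
            count += 1
    if count == 0:
        return -1, -1, -1
    r = rng.integers(0, count)
    for m in range(26):
        i = x + _OFFS[m, 0]
        j = y + _OFFS[m, 1]
        k = z + _OFFS[m, 2]
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz and occ[i, j, k] == -1:
            if r == 0:
                return i, j, k
            r -= 1
    return -1, -1, -1


@njit(cache=True)
def pick_stiffest_neighbor(occ, stiff, x, y, z, rng):
    """Free Moore neighbor with maximal stiffness, ties uniform at random."""
    nx, ny, nz = occ.shape
    best = -1.0
    count = 0
    for m in range(26):
        i = x + _OFFS[m, 0]
        j = y + _OFFS[m, 1]
        k = z + _OFFS[m, 2]
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz and occ[i, j, k] == -1:
            s = stiff[i, j, k]
            if s > best + 1e-9:
                best = s
                count = 1
            elif s > best - 1e-9:
                count += 1
    if count == 0:
        return -1, -1, -1
    r = rng.integers(0, count)
    for m in range(26):
        i = x + _OFFS[m, 0]
        j = y + _OFFS[m, 1]
        k = z + _OFFS[m, 2]
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz and occ[i, j, k] == -1:
            if stiff[i, j, k] > best - 1e-9:
                if r == 0:
                    return i, j, k
                r -= 1
    return -1, -1, -1


@njit(cache=True)
def pick_toward(occ, x, y, z, tx, ty, tz, rng):
    """Free Moore neighbor strictly reducing squared distance to target.

    Ties broken uniformly; (-1,-1,-1) if no improving free site exists.
    """
    nx, ny, nz = occ.shape
    d0 = (x - tx) ** 2 + (y - ty) ** 2 + (z - tz) ** 2
    best = d0
    count = 0
    for m in range(26):
        i = x + _OFFS[m, 0]
        j = y + _OFFS[m, 1]
        k = z + _OFFS[m, 2]
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz and occ[i, j, k] == -1:
            d = (i - tx) ** 2 + (j - ty) ** 2 + (k - tz) ** 2
            if d < best:
                best = d
                count = 1
            elif d == best and best < d0:
                count += 1
    if count == 0:
        return -1, -1, -1
    r = rng.integers(0, count)
    for m in range(26):
        i = x + _OFFS[m, 0]
        j = y + _OFFS[m, 1]
        k = z + _OFFS[m, 2]
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz and occ[i, j, k] == -1:
            d = (i - tx) ** 2 + (j - ty) ** 2 + (k - tz) ** 2
            if d == best:
                if r == 0:
                    return i, j, k
                r -= 1
    return -1, -1, -1


@njit(cache=True)
def adjacent_of_kind(occ, kind, attached, x, y, z, want_a, want_b, prefer_unattached, rng):
    """Random Moore-adjacent agent of kind ``want_a`` or ``want_b``.

    With ``prefer_unattached`` the choice is restricted to unattached
    candidates whenever any exist (CTLs preferring stroma-free targets).
    Returns the slot index, or −1.
    """
    nx, ny, nz = occ.shape
    n_un = 0
    n_all = 0
    for m in range(26):
        i = x + _OFFS[m, 0]
        j = y + _OFFS[m, 1]
        k = z + _OFFS[m, 2]
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
            a = occ[i, j, k]
            if a >= 0 and (kind[a] == want_a or kind[a] == want_b):
                n_all += 1
                if not attached[a]:
                    n_un += 1
    if n_all == 0:
        return -1
    use_unattached = prefer_unattached and n_un > 0
    pool = n_un if use_unattached else n_all
    r = rng.integers(0, pool)
    for m in range(26):
        i = x + _OFFS[m, 0]
        j = y + _OFFS[m, 1]
        k = z + _OFFS[m, 2]
        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
            a = occ[i, j, k]
            if a >= 0 and (kind[a] == want_a or kind[a] == want_b):
                if use_unattached and attached[a]:
                    continue
                if r == 0:
                    return a
                r -= 1
    return -1


@njit(cache=True)
def nearest_of_kind(occ, kind, x, y, z, radius, want_a, want_b, rng):
    """Nearest agent of the wanted kind(s) within a cubic sensing window.

    Distance ties resolved by reservoir sampling so the choice is
    unbiased.  Returns the slot index, or −1 if none in range.
    """
    nx, ny, nz = occ.shape
    best_d = radius * radius * 3 + 1
    best_i = -1
    ties = 0
    for i in range(max(0, x - radius), min(nx, x + radius + 1)):
        for j in range(max(0, y - radius), min(ny, y + radius + 1)):
            for k in range(max(0, z - radius), min(nz, z + radius + 1)):
                a = occ[i, j, k]
                if a >= 0 and (kind[a] == want_a or kind[a] == want_b):
                    if i == x and j == y and k == z:
                        continue
                    d = (i - x) ** 2 + (j - y) ** 2 + (k - z) ** 2
                    if d < best_d:
                        best_d = d
                        best_i = a
                        ties = 1
                    elif d == best_d:
                        ties += 1
                        if rng.random() < 1.0 / ties:
                            best_i = a
    return best_i


@njit(cache=True)
def agent_phase(
    occ,
    kind,
    pos,
    alive,
    phase,
    m_phase,
    passage,
    attached,
    arrest,
    order,
    n_total,
    stiff,
    floor_pa,
    p_death,
    p_divide,
    p_migrate,
    p_selfrenew,
    p_adhesion,
    cycle_len,
    dt,
    lgn,
    p_lysis,
    protect_attached,
    p_suppress,
    arrest_frac,
    sense_radius,
    events,
    rng,
):
    """One 2-h behavior phase over all agents in shuffled ``order``.

    Sub-rules per agent, in sequence: stochastic death; CTL lysis of an
    adjacent tumor cell (attachment-protected); Treg suppression of an
    adjacent CTL (cycle arrest or apoptosis by a second roll); cycle
    progression with division (MIC fate choice self-renew/differentiate,
    MM passage-limit death, CD8 arrest consumption, deferral when no
    free neighbor exists); migration (MIC up the stiffness field, CD8
    toward the nearest tumor cell, Treg toward the nearest CTL, MM
    random walk); and MIC adhesion to an adjacent stromal site.

    Returns the updated total slot count; increments ``events`` (kind ×
    event) in place.
    """
    for oi in range(order.shape[0]):
        idx = order[oi]
        if not alive[idx]:
            continue
        k8 = kind[idx]
        x = pos[idx, 0]
        y = pos[idx, 1]
        z = pos[idx, 2]

        # --- stochastic death -------------------------------------------
        if p_death[idx] > 0.0 and rng.random() < p_death[idx]:
            alive[idx] = False
            occ[x, y, z] = -1
            events[k8, EV_DEATH] += 1
            continue

        # --- contact interactions ---------------------------------------
        if k8 == CD8:
            tgt = adjacent_of_kind(occ, kind, attached, x, y, z, MIC, MM, True, rng)
            if tgt >= 0:
                pk = p_lysis * (protect_attached if attached[tgt] else 1.0)
                if rng.random() < pk:
                    alive[tgt] = False
                    occ[pos[tgt, 0], pos[tgt, 1], pos[tgt, 2]] = -1
                    events[kind[tgt], EV_LYSIS] += 1
        elif k8 == TREG:
            tgt = adjacent_of_kind(occ, kind, attached, x, y, z, CD8, CD8, False, rng)
            if tgt >= 0 and rng.random() < p_suppress:
                if rng.random() < arrest_frac:
                    arrest[tgt] = True
                else:
                    alive[tgt] = False
                    occ[pos[tgt, 0], pos[tgt, 1], pos[tgt, 2]] = -1
                    events[CD8, EV_DEATH] += 1

        # --- cell cycle --------------------------------------------------
        phase[idx] += dt
        if not m_phase[idx] and phase[idx] >= cycle_len[idx]:
            if k8 == CD8 and arrest[idx]:
                arrest[idx] = False  # arrested: this opportunity is consumed
                phase[idx] = 0.0
            elif k8 == MM and passage[idx] >= lgn:
                alive[idx] = False  # maximum passage number reached
                occ[x, y, z] = -1
                events[MM, EV_DEATH] += 1
                continue
            elif rng.random() < p_divide[idx]:
                m_phase[idx] = True
            else:
                phase[idx] = 0.0

        if m_phase[idx]:
            i, j, kz = pick_free_neighbor(occ, x, y, z, rng)
            if i >= 0:
                d = n_total
                n_total += 1
                pos[d, 0] = i
                pos[d, 1] = j
                pos[d, 2] = kz
                occ[i, j, kz] = d
                alive[d] = True
                phase[d] = 0.0
                m_phase[d] = False
                attached[d] = False
                arrest[d] = False
                if k8 == MIC:
                    if rng.random() < p_selfrenew[idx]:
                        kind[d] = MIC
                        passage[d] = 0
                        events[MIC, EV_BIRTH] += 1
                    else:
                        # differentiation: both parent and daughter become MM
                        kind[idx] = MM
                        kind[d] = MM
                        passage[idx] = 0
                        passage[d] = 0
                        attached[idx] = False
                        events[MIC, EV_DIFF] += 1
                        events[MM, EV_BIRTH] += 2
                elif k8 == MM:
                    passage[idx] += 1
                    kind[d] = MM
                    passage[d] = passage[idx]
                    events[MM, EV_BIRTH] += 1
                else:
                    kind[d] = k8
                    passage[d] = 0
                    events[k8, EV_BIRTH] += 1
                phase[idx] = 0.0
                m_phase[idx] = False
            # no free site: stay in M-phase, retry next step
            continue

        # --- migration ----------------------------------------------------
        if p_migrate[idx] > 0.0 and rng.random() < p_migrate[idx]:
            ti, tj, tk = -1, -1, -1
            if k8 == MIC:
                if not attached[idx]:
                    ti, tj, tk = pick_stiffest_neighbor(occ, stiff, x, y, z, rng)
                    if ti >= 0 and stiff[ti, tj, tk] < stiff[x, y, z] - 1e-9:
                        ti = -1  # never migrate down the stiffness field
            elif k8 == MM:
                ti, tj, tk = pick_free_neighbor(occ, x, y, z, rng)
            elif k8 == CD8:
                tgt = nearest_of_kind(occ, kind, x, y, z, sense_radius, MIC, MM, rng)
                if tgt >= 0:
                    ti, tj, tk = pick_toward(
                        occ, x, y, z, pos[tgt, 0], pos[tgt, 1], pos[tgt, 2], rng
                    )
                else:
                    ti, tj, tk = pick_free_neighbor(occ, x, y, z, rng)
            else:  # TREG
                tgt = nearest_of_kind(occ, kind, x, y, z, sense_radius, CD8, CD8, rng)
                if tgt >= 0:
                    ti, tj, tk = pick_toward(
                        occ, x, y, z, pos[tgt, 0], pos[tgt, 1], pos[tgt, 2], rng
                    )
                else:
                    ti, tj, tk = pick_free_neighbor(occ, x, y, z, rng)
            if ti >= 0:
                occ[x, y, z] = -1
                occ[ti, tj, tk] = idx
                pos[idx, 0] = ti
                pos[idx, 1] = tj
                pos[idx, 2] = tk
                x, y, z = ti, tj, tk

        # --- MIC adhesion to an adjacent stromal site --------------------
        if k8 == MIC and not attached[idx] and stiff[x, y, z] > floor_pa:
            if rng.random() < p_adhesion[idx]:
                attached[idx] = True

    return n_total
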