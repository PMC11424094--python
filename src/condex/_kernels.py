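"""Numba kernels for the Langevin dynamics engine.

Positions are kept unwrapped (absolute coordinates); periodicity enters
only through minimum-image distances and the cell binning, so trajectories
can be analysed for diffusion without unwrapping bookkeeping.  Forces are
accumulated either by an O(N^2) loop (small systems) or a linked-cell
pass; both return the potential energy so energy conservation is testable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# force-field parameter vector layout
K, R0, U0, RA, EPS, SIG, RC = 0, 1, 2, 3, 4, 5, 6


@njit(cache=True, inline="always")
def _pair_nonbonded(r2, same_type, p):
    """(energy, dU/dr / r) for a non-bonded pair at squared distance r2."""
    if r2 < 1e-12:
        r2 = 1e-12  # coincident stickers: clamp instead of dividing by zero
    if same_type:
        rc = p[RC]
        if r2 >= rc * rc:
            return 0.0, 0.0
        sr6 = (p[SIG] * p[SIG] / r2) ** 3
        e = 4.0 * p[EPS] * (sr6 * sr6 - sr6) + p[EPS]
        dudr_over_r = -4.0 * p[EPS] * (12.0 * sr6 * sr6 - 6.0 * sr6) / r2
        return e, dudr_over_r
    else:
        ra = p[RA]
        if r2 >= ra * ra:
            return 0.0, 0.0
        r = np.sqrt(r2)
        e = -0.5 * p[U0] * (1.0 + np.cos(np.pi * r / ra))
        dudr = 0.5 * p[U0] * np.pi / ra * np.sin(np.pi * r / ra)
        return e, dudr / r


@njit(cache=True, inline="always")
def _min_image(d, box):
    for k in range(3):
        d[k] -= box[k] * np.round(d[k] / box[k])
    return d


@njit(cache=True)
def _forces_bruteforce(pos, types, bonds, box, p, forces):
    n = pos.shape[0]
    forces[:] = 0.0
    energy = 0.0
    d = np.empty(3)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(3):
                d[k] = pos[i, k] - pos[j, k]
            _min_image(d, box)
            r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
            if r2 > p[RC] * p[RC] and r2 > p[RA] * p[RA]:
                continue
            e, g = _pair_nonbonded(r2, types[i] == types[j], p)
            energy += e
            for k in range(3):
                forces[i, k] -= g * d[k]
                forces[j, k] += g * d[k]
    ok = _add_bond_forces(pos, bonds, box, p, forces)
    if not ok:
        return np.nan
    energy += _bond_energy_total(pos, bonds, box, p)
    return energy


@njit(cache=True)
def _add_bond_forces(pos, bonds, box, p, forces):
    d = np.empty(3)
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        for k in range(3):
            d[k] = pos[i, k] - pos[j, k]
        _min_image(d, box)
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        if r2 >= p[R0] * p[R0]:
            return False  # bond over-extended: FENE-like energy diverges
        g = p[K] / (1.0 - r2 / (p[R0] * p[R0]))  # dU/dr / r
        for k in range(3):
            forces[i, k] -= g * d[k]
            forces[j, k] += g * d[k]
    return True


@njit(cache=True)
def _bond_energy_total(pos, bonds, box, p):
    e = 0.0
    d = np.empty(3)
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        for k in range(3):
            d[k] = pos[i, k] - pos[j, k]
        _min_image(d, box)
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        e += -0.5 * p[K] * p[R0] * p[R0] * np.log(1.0 - r2 / (p[R0] * p[R0]))
    return e


@njit(cache=True)
def _forces_cells(pos, types, bonds, box, p, forces, ncell, head, nxt, cell_of):
    """Linked-cell non-bonded pass; requires >= 3 cells per dimension."""
    n = pos.shape[0]
    forces[:] = 0.0
    # bin wrapped coordinates
    for c in range(head.size):
        head[c] = -1
    for i in range(n):
        ix = int(((pos[i, 0] / box[0]) % 1.0) * ncell[0])
        iy = int(((pos[i, 1] / box[1]) % 1.0) * ncell[1])
        iz = int(((pos[i, 2] / box[2]) % 1.0) * ncell[2])
        if ix == ncell[0]:
            ix -= 1
        if iy == ncell[1]:
            iy -= 1
        if iz == ncell[2]:
            iz -= 1
        c = (ix * ncell[1] + iy) * ncell[2] + iz
        cell_of[i] = c
        nxt[i] = head[c]
        head[c] = i
    energy = 0.0
    d = np.empty(3)
    cut2 = max(p[RC], p[RA]) ** 2
    for i in range(n):
        ci = cell_of[i]
        cz0 = ci % ncell[2]
        cy0 = (ci // ncell[2]) % ncell[1]
        cx0 = ci // (ncell[1] * ncell[2])
        for ox in range(-1, 2):
            nx = (cx0 + ox) % ncell[0]
            for oy in range(-1, 2):
                ny = (cy0 + oy) % ncell[1]
                for oz in range(-1, 2):
                    nz = (cz0 + oz) % ncell[2]
                    c2 = (nx * ncell[1] + ny) * ncell[2] + nz
                    j = head[c2]
                    while j >= 0:
                        if j > i:  # each pair once, from the smaller index
                            for k in range(3):
                                d[k] = pos[i, k] - pos[j, k]
                            _min_image(d, box)
                            r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
                            if r2 < cut2:
                                e, g = _pair_nonbonded(
                                    r2, types[i] == types[j], p
                                )
                                energy += e
                                for k in range(3):
                                    forces[i, k] -= g * d[k]
                                    forces[j, k] += g * d[k]
                        j = nxt[j]
    ok = _add_bond_forces(pos, bonds, box, p, forces)
    if not ok:
        return np.nan
    energy += _bond_energy_total(pos, bonds, box, p)
    return energy


@njit(cache=True)
def _compute_forces(pos, types, bonds, box, p, forces, ncell, head, nxt, cell_of):
    if ncell[0] >= 3 and ncell[1] >= 3 and ncell[2] >= 3 and pos.shape[0] > 64:
        return _forces_cells(
            pos, types, bonds, box, p, forces, ncell, head, nxt, cell_of
        )
    return _forces_bruteforce(pos, types, bonds, box, p, forces)


@njit(cache=True)
def baoab_run(
    pos,
    vel,
    types,
    bonds,
    box,
    p,
    n_steps,
    dt,
    kT,
    gamma,
    seed,
    record_every,
    rec_pos,
    rec_pe,
    rec_ke,
):
    """BAOAB Langevin splitting with unit sticker mass.

    gamma = 0 and kT = 0 reduce to velocity Verlet (energy conserving).
    Records unwrapped positions every ``record_every`` steps, frame 0
    included.  Returns 0 on success, 1 on bond over-extension, 2 on
    non-finite coordinates (instability).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.empty((n, 3))
    cut = max(p[RC], p[RA])
    ncell = np.empty(3, dtype=np.int64)
    for k in range(3):
        ncell[k] = max(1, int(box[k] / cut))
    head = np.empty(ncell[0] * ncell[1] * ncell[2], dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)

    c1 = np.exp(-gamma * dt) if gamma > 0.0 else 1.0
    c2 = np.sqrt(kT * (1.0 - c1 * c1)) if gamma > 0.0 else 0.0

    pe = _compute_forces(pos, types, bonds, box, p, forces, ncell, head, nxt, cell_of)
    if np.isnan(pe):
        return 1
    frame = 0
    rec_pos[0] = pos
    rec_pe[0] = pe
    rec_ke[0] = 0.5 * np.sum(vel * vel)
    for step in range(1, n_steps + 1):
        # B: half kick
        vel += 0.5 * dt * forces
        # A: half drift
        pos += 0.5 * dt * vel
        # O: friction + noise
        if gamma > 0.0:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k] + c2 * np.random.normal()
        # A: half drift
        pos += 0.5 * dt * vel
        pe = _compute_forces(
            pos, types, bonds, box, p, forces, ncell, head, nxt, cell_of
        )
        if np.isnan(pe):
            return 1
        # B: half kick
        vel += 0.5 * dt * forces
        if step % record_every == 0:
            frame += 1
            if not np.isfinite(pos).all():
                return 2
            rec_pos[frame] = pos
            rec_pe[frame] = pe
            rec_ke[frame] = 0.5 * np.sum(vel * vel)
    return 0


@njit(cache=True)
def pair_lifetime_run(box_len, p, n_steps, dt, kT, gamma, seed, durations):
    """One A and one B sticker in a small periodic cube; returns the number
    of completed bonded intervals (r < r0) written into ``durations``
    (units of dt steps)."""
    np.random.seed(seed)
    box = np.full(3, box_len)
    pos = np.empty((2, 3))
    for i in range(2):
        for k in range(3):
            pos[i, k] = np.random.uniform(0.0, box_len)
    vel = np.random.normal(0.0, np.sqrt(kT), (2, 3))
    types = np.zeros(2, dtype=np.int8)
    types[1] = 1
    bonds = np.empty((0, 2), dtype=np.int64)
    forces = np.empty((2, 3))
    ncell = np.ones(3, dtype=np.int64)
    head = np.empty(1, dtype=np.int64)
    nxt = np.empty(2, dtype=np.int64)
    cell_of = np.empty(2, dtype=np.int64)
    _compute_forces(pos, types, bonds, box, p, forces, ncell, head, nxt, cell_of)
    c1 = np.exp(-gamma * dt) if gamma > 0.0 else 1.0
    c2 = np.sqrt(kT * (1.0 - c1 * c1)) if gamma > 0.0 else 0.0
    d = np.empty(3)
    bonded = False
    start = 0
    n_events = 0
    for step in range(1, n_steps + 1):
        vel += 0.5 * dt * forces
        pos += 0.5 * dt * vel
        if gamma > 0.0:
            for i in range(2):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k] + c2 * np.random.normal()
        pos += 0.5 * dt * vel
        _compute_forces(pos, types, bonds, box, p, forces, ncell, head, nxt, cell_of)
        vel += 0.5 * dt * forces
        for k in range(3):
            d[k] = pos[0, k] - pos[1, k]
        _min_image(d, box)
        r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
        now = r2 < p[RA] * p[RA]
        if now and not bonded:
            start = step
            bonded = True
        elif bonded and not now:
            if n_events < durations.size:
                durations[n_events] = step - start
            n_events += 1
            bonded = False
        if n_events >= durations.size:
            break
    return n_events
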