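"""Deterministic synthetic fixtures.

Generators for configurations, trajectories and curves whose target
properties are known by construction, so every analysis operation can be
tested without long simulations: slab and droplet configurations with
prescribed coexistence concentrations, Brownian trajectories with exact
D, finite-pool recovery curves with chosen (A, tau), and scripted
trajectories with hand-specified entry events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .continuum import RecoveryCurve
from .forcefield import ForceField
from .simulate import PolymerSpec, SimState, Trajectory, _relax_overlaps

__all__ = [
    "brownian_trajectory",
    "recovery_curve_fixture",
    "slab_configuration",
    "droplet_configuration",
    "scripted_exchange_trajectory",
    "generate_fixture",
]


def brownian_trajectory(
    n_particles: int,
    D: float,
    *,
    dt: float = 1.0,
    n_frames: int = 200,
    box: tuple[float, float, float] = (100.0, 100.0, 100.0),
    seed: int = 0,
) -> Trajectory:
    """Independent Brownian walkers with exact diffusion coefficient D.

    Each "polymer" is a single sticker; increments are Gaussian with
    variance 2 D dt per axis.
    """
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    start = rng.uniform(0.0, 1.0, (n_particles, 3)) * box
    steps = rng.normal(0.0, math.sqrt(2.0 * D * dt), (n_frames - 1, n_particles, 3))
    pos = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    return Trajectory(
        times=dt * np.arange(n_frames),
        positions=pos,
        types=np.zeros(n_particles, dtype=np.int8),
        mol=np.arange(n_particles),
        bonds=np.empty((0, 2), dtype=np.int64),
        box=box,
        sequence="A",
    )


def recovery_curve_fixture(
    A: float,
    tau: float,
    times: np.ndarray,
    *,
    noise: float = 0.0,
    seed: int = 0,
) -> RecoveryCurve:
    """Finite-pool recovery curve f(t) = A [1 - exp(-t/(A tau))] with
    optional additive Gaussian noise."""
    t = np.asarray(times, dtype=float)
    f = A * (1.0 - np.exp(-t / (A * tau)))
    if noise > 0:
        f = f + np.random.default_rng(seed).normal(0.0, noise, f.shape)
    return RecoveryCurve(t, f)


def slab_configuration(
    c_den: float,
    c_dil: float,
    *,
    box: tuple[float, float, float] = (500.0, 40.0, 40.0),
    slab_width: float = 80.0,
    sequence: str = "AAAAAABBBBBB",
    seed: int = 0,
    ff: ForceField | None = None,
    relax: bool = False,
) -> SimState:
    """Phase-separated slab with prescribed coexistence concentrations.

    Polymer counts are rounded from the target concentrations (polymers
    per nm^3) times the region volumes; dense-slab chains are placed in
    the central window [-slab_width/2, slab_width/2) along x, dilute
    chains outside it.  Dense-phase stickers are paired A-B so that the
    slab forms one connected cluster under the clustering rule.
    """
    ff = ff or ForceField()
    box = np.asarray(box, dtype=float)
    x0 = box[0] / 2.0
    v_den = slab_width * box[1] * box[2]
    v_dil = (box[0] - slab_width) * box[1] * box[2]
    n_den = int(round(c_den * v_den))
    n_dil = int(round(c_dil * v_dil))
    if n_den < 1:
        raise ValueError("dense slab would hold no polymers")
    m = len(sequence)
    # sanity: stickers at hard-sphere diameter sigma must fit
    if c_den * m * (4.0 / 3.0) * math.pi * (ff.sigma / 2.0) ** 3 > 0.5:
        raise ValueError("target c_den beyond close packing of stickers")

    spec = PolymerSpec(sequence, n_den + n_dil, tuple(box))
    rng = np.random.default_rng(seed)
    types, mol, bonds = spec.topology()
    pos = np.empty((spec.n_stickers, 3))

    def _walk(step: float) -> np.ndarray:
        w = np.zeros((m, 3))
        for k in range(1, m):
            v = rng.normal(size=3)
            w[k] = w[k - 1] + v * (step / np.linalg.norm(v))
        return w - w.mean(axis=0)

    # center each chain's walk on a uniformly sampled COM target, so the
    # center-of-mass density equals the target concentration exactly
    for p in range(n_den):
        target = np.array(
            [
                rng.uniform(x0 - slab_width / 2.0, x0 + slab_width / 2.0),
                rng.uniform(0, box[1]),
                rng.uniform(0, box[2]),
            ]
        )
        pos[p * m : (p + 1) * m] = _walk(2.2) + target
    for p in range(n_den, n_den + n_dil):
        x = rng.uniform(0.0, box[0] - slab_width)
        x = x if x < x0 - slab_width / 2.0 else x + slab_width
        target = np.array([x, rng.uniform(0, box[1]), rng.uniform(0, box[2])])
        pos[p * m : (p + 1) * m] = _walk(3.9) + target

    state = SimState(
        positions=pos,
        velocities=np.zeros_like(pos),
        types=types,
        mol=mol,
        bonds=bonds,
        box=box,
        sequence=sequence,
    )
    _connect_dense(state, n_den, m, rng)
    if relax:
        _relax_overlaps(state.positions, types, bonds, box, ff, 300)
    state.velocities = rng.normal(0.0, 1.0, pos.shape)
    return state


def droplet_configuration(
    c_den: float,
    c_dil: float,
    *,
    box_len: float = 286.0,
    R: float = 37.0,
    sequence: str = "AAAAAABBBBBB",
    seed: int = 0,
    ff: ForceField | None = None,
    relax: bool = False,
) -> SimState:
    """Spherical droplet of prescribed concentrations in a cubic box.

    ``relax`` runs a short soft-push minimization (use before dynamics;
    leave off when the configuration serves as an exact analysis oracle).
    """
    ff = ff or ForceField()
    box = np.full(3, float(box_len))
    center = box / 2.0
    v_den = 4.0 / 3.0 * math.pi * R**3
    v_dil = box_len**3 - v_den
    n_den = int(round(c_den * v_den))
    n_dil = int(round(c_dil * v_dil))
    m = len(sequence)
    spec = PolymerSpec(sequence, n_den + n_dil, tuple(box), geometry="cubic")
    rng = np.random.default_rng(seed)
    types, mol, bonds = spec.topology()
    pos = np.empty((spec.n_stickers, 3))

    def _walk(step: float) -> np.ndarray:
        w = np.zeros((m, 3))
        for k in range(1, m):
            v = rng.normal(size=3)
            w[k] = w[k - 1] + v * (step / np.linalg.norm(v))
        return w - w.mean(axis=0)

    for p in range(n_den):
        # uniform COM target in the sphere
        while True:
            cand = rng.uniform(-R, R, 3)
            if np.dot(cand, cand) <= R * R:
                break
        pos[p * m : (p + 1) * m] = _walk(2.2) + center + cand
    for p in range(n_den, n_den + n_dil):
        while True:
            start = rng.uniform(0.0, box_len, 3)
            if np.linalg.norm(start - center) > R + 5.0:
                break
        pos[p * m : (p + 1) * m] = _walk(3.9) + start

    state = SimState(
        positions=pos,
        velocities=np.zeros_like(pos),
        types=types,
        mol=mol,
        bonds=bonds,
        box=box,
        sequence=sequence,
    )
    _connect_dense(state, n_den, m, rng)
    if relax:
        _relax_overlaps(state.positions, types, bonds, box, ff, 300)
    state.velocities = rng.normal(0.0, 1.0, pos.shape)
    return state


def _connect_dense(state: SimState, n_den: int, m: int, rng) -> None:
    """Dock each dense chain to its nearest already-placed opposite-type
    sticker by moving a single sticker into the attraction well, so the
    dense region is one cluster under the clustering rule (and stays one
    under relaxation) without disturbing its density."""
    from scipy.spatial import cKDTree

    pos = state.positions
    types = state.types
    placed = list(range(m))  # sticker indices of chains already connected
    dock_r = 0.5  # inside the A-B well, clear of same-type repulsion cores
    for p in range(1, n_den):
        cur = np.arange(p * m, (p + 1) * m)
        placed_arr = np.asarray(placed)
        best = None
        for t_cur in (0, 1):
            mine = cur[types[cur] == t_cur]
            theirs = placed_arr[types[placed_arr] != t_cur]
            if len(mine) == 0 or len(theirs) == 0:
                continue
            tree = cKDTree(pos[theirs])
            dists, nbr = tree.query(pos[mine])
            k = int(np.argmin(dists))
            if best is None or dists[k] < best[2]:
                best = (int(mine[k]), int(theirs[int(nbr[k])]), float(dists[k]))
        if best is not None:
            i, j, dist = best
            if dist > dock_r + 1e-9:
                direction = (pos[j] - pos[i]) / dist
                if dist - dock_r <= 4.0:
                    # short hop: move one sticker (bonds stay well below R0)
                    pos[i] += direction * (dist - dock_r)
                else:
                    # rare distant chain: translate it whole
                    pos[p * m : (p + 1) * m] += direction * (dist - dock_r)
        placed.extend(cur.tolist())


def scripted_exchange_trajectory(
    entry_frames: dict[int, int],
    *,
    n_dense: int = 12,
    n_dilute: int = 8,
    n_frames: int = 60,
    dt: float = 1.0,
    box_len: float = 200.0,
    seed: int = 0,
) -> Trajectory:
    """Hand-scripted trajectory of AB dimers with prescribed entry events.

    A chain of ``n_dense`` AB dimers sits bonded at the box center (the
    largest cluster).  Dilute dimers idle far away; dimer ``i`` (dilute
    index, 0-based) listed in ``entry_frames`` moves at the given frame
    into permanent A-B contact with a dense dimer and stays.  Everything
    else is static, so survival/flux bookkeeping can be checked against
    the event list exactly.
    """
    if n_dilute < max(entry_frames.keys(), default=-1) + 1:
        raise ValueError("entry_frames refers to a dilute polymer out of range")
    n_poly = n_dense + n_dilute
    m = 2
    types = np.tile(np.array([0, 1], dtype=np.int8), n_poly)
    mol = np.repeat(np.arange(n_poly), m)
    bonds = np.array([[2 * p, 2 * p + 1] for p in range(n_poly)], dtype=np.int64)
    box = np.full(3, float(box_len))
    center = box / 2.0

    base = np.zeros((n_poly * m, 3))
    # dense chain along x: dimer p at x = p * 2.6, A and B 0.8 nm apart so
    # consecutive dimers are within r0 of each other (B_p .. A_{p+1} at 1.0... )
    for p in range(n_dense):
        base[2 * p] = center + np.array([p * 1.6, 0.0, 0.0])
        base[2 * p + 1] = center + np.array([p * 1.6 + 0.8, 0.0, 0.0])
    rng = np.random.default_rng(seed)
    for i in range(n_dilute):
        p = n_dense + i
        far = center + np.array([0.0, box_len / 2.0 - 10.0 - 3.0 * i, 0.0])
        base[2 * p] = far
        base[2 * p + 1] = far + np.array([0.8, 0.0, 0.0])

    pos = np.tile(base, (n_frames, 1, 1))
    for i, f_entry in entry_frames.items():
        p = n_dense + i
        # dock the dimer's A sticker 0.7 nm from the last dense B sticker
        anchor = base[2 * (n_dense - 1) + 1]
        dock = anchor + np.array([0.0, 0.7 + 0.02 * i, 0.0])
        for f in range(f_entry, n_frames):
            pos[f, 2 * p] = dock
            pos[f, 2 * p + 1] = dock + np.array([0.0, 0.8, 0.0])

    return Trajectory(
        times=dt * np.arange(n_frames),
        positions=pos,
        types=types,
        mol=mol,
        bonds=bonds,
        box=box,
        sequence="AB",
    )


def generate_fixture(kind: str, *, seed: int = 0, **params):
    """Dispatch to a fixture generator by kind.

    Kinds: "slab-config", "droplet-config", "brownian-traj",
    "recovery-curve", "scripted-exchange-traj".  Keyword parameters are
    forwarded to the corresponding generator.
    """
    table = {
        "slab-config": slab_configuration,
        "droplet-config": droplet_configuration,
        "brownian-traj": brownian_trajectory,
        "recovery-curve": recovery_curve_fixture,
        "scripted-exchange-traj": scripted_exchange_trajectory,
    }
    if kind not in table:
        raise ValueError(f"unknown fixture kind {kind!r}; one of {sorted(table)}")
    return table[kind](seed=seed, **params)
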