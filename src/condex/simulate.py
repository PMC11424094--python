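"""Langevin dynamics of sticker-spacer polymers.

Reduced units: length in nm, energy in kBT, sticker mass m = 1 and
friction gamma per sticker, so that a free sticker diffuses with
D = kBT/gamma.  At the defaults (kBT = 1, gamma = 1) the time unit is
gamma nm^2/kBT.  Physical times are attached only through an optional
user-supplied unit map; ratios of measured quantities (e.g. conductances
at two binding strengths) are unit-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forcefield import ForceField

__all__ = [
    "PolymerSpec",
    "SimState",
    "Trajectory",
    "build_system",
    "run_langevin",
    "isolated_pair_bond_lifetime",
]


@dataclass(frozen=True)
class PolymerSpec:
    """A homogeneous collection of sticker-spacer polymers in a periodic box.

    ``sequence`` is a string over {A, B}, e.g. ``"AAAAAABBBBBB"`` (A6B6);
    ``box`` is the three box lengths in nm.  ``geometry`` is a tag only
    ("slab" for elongated boxes with a planar dense phase, "cubic" for
    droplet runs).
    """

    sequence: str
    n_polymers: int
    box: tuple[float, float, float]
    geometry: str = "slab"

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - {"A", "B"}:
            raise ValueError("sequence must be a non-empty string over {A, B}")
        if self.n_polymers <= 0:
            raise ValueError("n_polymers must be positive")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        if self.geometry not in ("slab", "cubic"):
            raise ValueError("geometry must be 'slab' or 'cubic'")

    @property
    def n_monomers(self) -> int:
        return len(self.sequence)

    @property
    def n_stickers(self) -> int:
        return self.n_monomers * self.n_polymers

    def topology(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(types, mol, bonds): sticker types (0=A, 1=B), polymer index per
        sticker, and the chain bond list."""
        seq = np.array([0 if ch == "A" else 1 for ch in self.sequence], dtype=np.int8)
        types = np.tile(seq, self.n_polymers)
        mol = np.repeat(np.arange(self.n_polymers), self.n_monomers)
        nb = self.n_monomers - 1
        bonds = np.empty((self.n_polymers * nb, 2), dtype=np.int64)
        for p in range(self.n_polymers):
            off = p * self.n_monomers
            for k in range(nb):
                bonds[p * nb + k] = (off + k, off + k + 1)
        return types, mol, bonds


@dataclass
class SimState:
    """Instantaneous simulation state (positions unwrapped, nm)."""

    positions: np.ndarray
    velocities: np.ndarray
    types: np.ndarray
    mol: np.ndarray
    bonds: np.ndarray
    box: np.ndarray
    time: float = 0.0
    sequence: str = ""

    @property
    def n_polymers(self) -> int:
        return int(self.mol.max()) + 1 if len(self.mol) else 0

    def wrapped(self) -> np.ndarray:
        return self.positions - np.floor(self.positions / self.box) * self.box


@dataclass
class Trajectory:
    """Recorded snapshots of a Langevin run (positions unwrapped, nm)."""

    times: np.ndarray          # (F,) reduced time
    positions: np.ndarray      # (F, N, 3)
    types: np.ndarray
    mol: np.ndarray
    bonds: np.ndarray
    box: np.ndarray
    sequence: str = ""
    potential_energy: np.ndarray | None = None
    kinetic_energy: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_polymers(self) -> int:
        return int(self.mol.max()) + 1

    @property
    def recording_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def state(self, frame: int) -> SimState:
        return SimState(
            positions=self.positions[frame].copy(),
            velocities=np.zeros_like(self.positions[frame]),
            types=self.types,
            mol=self.mol,
            bonds=self.bonds,
            box=self.box,
            time=float(self.times[frame]),
            sequence=self.sequence,
        )


def build_system(
    spec: PolymerSpec,
    ff: ForceField | None = None,
    seed: int = 0,
    *,
    bond_length: float = 3.9,
    region: tuple[np.ndarray, np.ndarray] | None = None,
    relax_steps: int = 200,
) -> SimState:
    """Place polymers as compact random walks and relax overlaps.

    Each chain starts at a uniform random point (inside ``region``
    bounds if given, else the whole box) and grows with fixed-length
    randomly oriented steps near the thermal bond length.  A short
    force-capped steepest-descent pass then pushes overlapping stickers
    apart; deterministic for a given seed.
    """
    ff = ff or ForceField()
    rng = np.random.default_rng(seed)
    types, mol, bonds = spec.topology()
    box = np.asarray(spec.box, dtype=float)
    lo = np.zeros(3) if region is None else np.asarray(region[0], dtype=float)
    hi = box if region is None else np.asarray(region[1], dtype=float)

    n = spec.n_stickers
    pos = np.empty((n, 3))
    m = spec.n_monomers
    for pidx in range(spec.n_polymers):
        start = rng.uniform(lo, hi)
        pos[pidx * m] = start
        for k in range(1, m):
            v = rng.normal(size=3)
            v *= bond_length / np.linalg.norm(v)
            cand = pos[pidx * m + k - 1] + v
            # keep the chain's walk loosely inside its placement region
            cand = np.clip(cand, lo - bond_length, hi + bond_length)
            pos[pidx * m + k] = cand

    _relax_overlaps(pos, types, bonds, box, ff, relax_steps)
    vel = rng.normal(0.0, 1.0, (n, 3))
    return SimState(
        positions=pos, velocities=vel, types=types, mol=mol, bonds=bonds,
        box=box, sequence=spec.sequence,
    )


def _relax_overlaps(
    pos: np.ndarray,
    types: np.ndarray,
    bonds: np.ndarray,
    box: np.ndarray,
    ff: ForceField,
    n_steps: int,
    max_move: float = 0.2,
) -> None:
    """Steepest descent with per-step displacement cap (soft push)."""
    p = np.asarray(ff.as_tuple())
    n = len(pos)
    forces = np.empty((n, 3))
    cut = ff.cutoff
    ncell = np.maximum(1, (box / cut).astype(np.int64))
    head = np.empty(int(np.prod(ncell)), dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    for _ in range(n_steps):
        e = _kernels._compute_forces(
            pos, types, bonds, box, p, forces, ncell, head, nxt, cell_of
        )
        step = forces * 0.01
        norm = np.linalg.norm(step, axis=1)
        big = norm > max_move
        if np.any(big):
            step[big] *= (max_move / norm[big])[:, None]
        pos += step
        if not np.isnan(e) and np.max(norm) < 1e-3:
            break
    # final sanity: no over-extended bonds
    d = pos[bonds[:, 0]] - pos[bonds[:, 1]]
    d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    if np.any(r >= ff.R0):
        raise RuntimeError("packing failed: over-extended bond after relaxation")


def run_langevin(
    state: SimState,
    ff: ForceField | None = None,
    n_steps: int = 10000,
    dt: float = 0.005,
    *,
    kT: float = 1.0,
    gamma: float = 1.0,
    seed: int = 0,
    record_every: int = 100,
) -> Trajectory:
    """Integrate underdamped Langevin dynamics (BAOAB splitting).

    With gamma = 0 and kT = 0 this is plain velocity Verlet and conserves
    energy; with interactions off each sticker diffuses with
    MSD = 6 (kT/gamma) t.  The trajectory is bitwise reproducible for a
    fixed seed.  Raises on bond over-extension or numerical blow-up
    (reduce dt).
    """
    ff = ff or ForceField()
    if n_steps % record_every != 0:
        raise ValueError("n_steps must be a multiple of record_every")
    n_frames = n_steps // record_every + 1
    n = len(state.positions)
    rec_pos = np.empty((n_frames, n, 3))
    rec_pe = np.empty(n_frames)
    rec_ke = np.empty(n_frames)
    pos = state.positions.copy()
    vel = state.velocities * math.sqrt(kT) if kT > 0 else np.zeros_like(state.velocities)
    status = _kernels.baoab_run(
        pos,
        vel,
        state.types,
        state.bonds,
        np.asarray(state.box, dtype=float),
        np.asarray(ff.as_tuple()),
        n_steps,
        dt,
        kT,
        gamma,
        seed & 0x7FFFFFFF,
        record_every,
        rec_pos,
        rec_pe,
        rec_ke,
    )
    if status == 1:
        raise RuntimeError(
            "bond over-extension (r >= R0): the bond energy diverges; use a "
            "smaller dt or relax the initial configuration"
        )
    if status == 2:
        raise RuntimeError("integration blew up (non-finite positions); reduce dt")
    state.positions = pos
    state.velocities = vel
    state.time += n_steps * dt
    times = state.time - n_steps * dt + dt * record_every * np.arange(n_frames)
    # frame 0 is the initial state; shift so times[0] is its timestamp
    return Trajectory(
        times=times,
        positions=rec_pos,
        types=state.types,
        mol=state.mol,
        bonds=state.bonds,
        box=np.asarray(state.box, dtype=float),
        sequence=state.sequence,
        potential_energy=rec_pe,
        kinetic_energy=rec_ke,
    )


def isolated_pair_bond_lifetime(
    ff: ForceField | None = None,
    *,
    box_len: float = 10.0,
    dt: float = 0.005,
    kT: float = 1.0,
    gamma: float = 1.0,
    seed: int = 0,
    n_events: int = 200,
    max_steps: int = 50_000_000,
) -> tuple[float, float]:
    """Mean lifetime of an isolated A-B bond (reduced time).

    One A and one B sticker diffuse in a small periodic cube; a bond
    exists while their separation is below the attraction range r0.
    Returns (mean, SEM) over completed bonded intervals.  The mean grows
    roughly exponentially with the well depth U0, so deep wells need
    correspondingly long runs.
    """
    ff = ff or ForceField()
    if n_events < 100:
        raise ValueError("need at least 100 events for a stable mean")
    durations = np.empty(n_events, dtype=np.int64)
    found = _kernels.pair_lifetime_run(
        box_len,
        np.asarray(ff.as_tuple()),
        max_steps,
        dt,
        kT,
        gamma,
        seed & 0x7FFFFFFF,
        durations,
    )
    if found == 0:
        raise RuntimeError("no bonding events observed; increase max_steps")
    got = min(found, n_events)
    lt = durations[:got] * dt
    return float(lt.mean()), float(lt.std(ddof=1) / math.sqrt(got))
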