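"""Phase properties measured from trajectories.

The dense phase is identified through a clustering rule: two stickers are
connected if they belong to the same chain or lie within the attraction
distance r0 of each other; connected stickers are grouped into clusters
and the largest cluster is the condensate.  Everything else — coexisting
concentrations, interface width, diffusion coefficients, unbound-sticker
fractions — is computed relative to that assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .params import per_nm3_to_millimolar
from .simulate import SimState, Trajectory

__all__ = [
    "PhaseMeasurement",
    "DensityProfile",
    "cluster_polymers",
    "largest_cluster_mask",
    "density_profile",
    "msd_diffusion",
    "unbound_fractions",
    "equilibration_check",
]


@dataclass
class PhaseMeasurement:
    """Bundle of phase quantities from one trajectory (concentrations in
    polymers/nm^3; D in reduced units unless a unit map was applied)."""

    c_den: float
    c_dil: float
    delta: float | None = None      # interface width, nm
    d_half: float | None = None     # dilute-phase half-width, nm
    D_den: float | None = None
    D_dil: float | None = None
    f_dil_A: float | None = None
    f_dil_B: float | None = None
    f_den_A: float | None = None
    f_den_B: float | None = None
    sem: dict = field(default_factory=dict)

    @property
    def c_den_mM(self) -> float:
        return per_nm3_to_millimolar(self.c_den)

    @property
    def c_dil_mM(self) -> float:
        return per_nm3_to_millimolar(self.c_dil)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _sticker_contacts(state: SimState, cutoff: float) -> np.ndarray:
    """Pairs of stickers within cutoff under periodic minimum image."""
    wrapped = state.wrapped()
    # cKDTree with boxsize implements periodic distances
    tree = cKDTree(np.mod(wrapped, state.box), boxsize=state.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs


def cluster_polymers(state: SimState, cutoff: float = 1.0) -> np.ndarray:
    """Cluster label per polymer; labels sorted by descending cluster size.

    Stickers are connected if they share a chain or sit within ``cutoff``
    (default: the attraction distance r0 = 1 nm); polymers inherit the
    connectivity of their stickers.  Label 0 is the largest cluster.
    """
    n_poly = state.n_polymers
    parent = np.arange(n_poly)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pairs = _sticker_contacts(state, cutoff)
    mol = state.mol
    for a, b in pairs:
        pa, pb = mol[a], mol[b]
        if pa == pb:
            continue
        ra, rb = find(pa), find(pb)
        if ra != rb:
            parent[ra] = rb

    roots = np.array([find(i) for i in range(n_poly)])
    uniq, inverse, counts = np.unique(roots, return_inverse=True, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return rank[inverse]


def largest_cluster_mask(state: SimState, cutoff: float = 1.0) -> np.ndarray:
    """Boolean mask over polymers: membership in the largest cluster."""
    return cluster_polymers(state, cutoff) == 0


# ---------------------------------------------------------------------------
# Density profiles
# ---------------------------------------------------------------------------


def _periodic_com(x: np.ndarray, L: float) -> float:
    """Center of mass of positions on a ring of circumference L
    (circular mean), mapped to [0, L)."""
    ang = x * (2.0 * math.pi / L)
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    return (math.atan2(s, c) % (2.0 * math.pi)) * L / (2.0 * math.pi)


def polymer_com(state: SimState) -> np.ndarray:
    """Per-polymer center of mass from unwrapped coordinates."""
    n_poly = state.n_polymers
    com = np.zeros((n_poly, 3))
    np.add.at(com, state.mol, state.positions)
    counts = np.bincount(state.mol, minlength=n_poly).astype(float)
    return com / counts[:, None]


@dataclass
class DensityProfile:
    """Time-averaged polymer concentration profile after recentering."""

    coords: np.ndarray          # bin centers (nm); axis position or radius
    concentration: np.ndarray   # polymers / nm^3
    kind: str                   # "axis" or "radial"
    c_den: float | None = None
    c_dil: float | None = None
    delta: float | None = None
    d_half: float | None = None
    phase_separated: bool = True


def _tanh_profile(x, c_dil, c_den, half_width, delta):
    # symmetric slab: dense plateau |x| < half_width, tanh shoulders of
    # 10-90 width ~ 2.2 * delta/2
    return c_dil + (c_den - c_dil) * 0.5 * (
        np.tanh((x + half_width) / (delta / 2.0))
        - np.tanh((x - half_width) / (delta / 2.0))
    )


def density_profile(
    traj: Trajectory,
    *,
    kind: str = "axis",
    axis: int = 0,
    bin_width: float = 2.0,
    cutoff: float = 1.0,
    plateau_tol: float = 0.10,
) -> DensityProfile:
    """Recentered, time-averaged polymer concentration profile.

    Each snapshot is recentered on the periodic (circular-mean) center of
    mass of the largest cluster; polymer centers of mass are then binned
    along ``axis`` ("axis" mode, slab geometry) or radially from the
    cluster center ("radial" mode, droplet geometry).  The dense plateau
    level gives c_den (bins within ``plateau_tol`` of the central level),
    the outer plateau c_dil; in axis mode a tanh fit of the shoulders
    yields the interface width delta and the dilute half-width d.
    """
    box = traj.box
    n_poly = traj.n_polymers
    frames = range(traj.n_frames)
    L = box[axis]

    if kind == "axis":
        nbins = max(10, int(round(L / bin_width)))
        edges = np.linspace(-L / 2, L / 2, nbins + 1)
        hist = np.zeros(nbins)
        slab_area = float(np.prod(np.delete(box, axis)))
        largest_frac = 0.0
        for fidx in frames:
            st = traj.state(fidx)
            labels = cluster_polymers(st, cutoff)
            com = polymer_com(st)
            comw = np.mod(com, box)
            center = _periodic_com(comw[labels == 0, axis], L)
            largest_frac += np.mean(labels == 0)
            x = np.mod(comw[:, axis] - center + L / 2, L) - L / 2
            hist += np.histogram(x, bins=edges)[0]
        largest_frac /= traj.n_frames
        conc = hist / (traj.n_frames * slab_area * np.diff(edges))
        centers = 0.5 * (edges[:-1] + edges[1:])
        prof = DensityProfile(centers, conc, "axis")
    elif kind == "radial":
        r_max = float(box.min()) / 2.0
        nbins = max(10, int(round(r_max / bin_width)))
        edges = np.linspace(0.0, r_max, nbins + 1)
        hist = np.zeros(nbins)
        largest_frac = 0.0
        for fidx in frames:
            st = traj.state(fidx)
            labels = cluster_polymers(st, cutoff)
            com = polymer_com(st)
            comw = np.mod(com, box)
            center = np.array(
                [_periodic_com(comw[labels == 0, k], box[k]) for k in range(3)]
            )
            largest_frac += np.mean(labels == 0)
            d = comw - center
            d -= box * np.round(d / box)
            r = np.linalg.norm(d, axis=1)
            hist += np.histogram(r, bins=edges)[0]
        largest_frac /= traj.n_frames
        shell = 4.0 / 3.0 * math.pi * np.diff(edges**3)
        conc = hist / (traj.n_frames * shell)
        centers = 0.5 * (edges[:-1] + edges[1:])
        prof = DensityProfile(centers, conc, "radial")
    else:
        raise ValueError("kind must be 'axis' or 'radial'")

    if largest_frac < 0.20:
        import warnings

        warnings.warn(
            "no phase-separated cluster (largest cluster holds "
            f"{largest_frac:.0%} of polymers); reporting dilute-only output"
        )
        prof.phase_separated = False
        prof.c_dil = float(n_poly / np.prod(box))
        return prof

    _extract_plateaus(prof, plateau_tol)
    return prof


def _extract_plateaus(prof: DensityProfile, tol: float) -> None:
    x, c = prof.coords, prof.concentration
    if prof.kind == "axis":
        mid = c[np.abs(x) < 0.15 * (x[-1] - x[0])]
    else:
        mid = c[: max(2, len(c) // 8)]
    level_den = float(np.median(mid))
    den_mask = c > (1 - tol) * level_den
    prof.c_den = float(c[den_mask].mean())
    # outer plateau: beyond the dense region, take the outer third
    if prof.kind == "axis":
        outer = np.abs(x) > 0.75 * np.abs(x).max()
    else:
        outer = x > 0.75 * x.max()
    prof.c_dil = float(max(c[outer].mean(), 0.0))

    if prof.kind == "axis" and prof.c_den > prof.c_dil:
        # tanh fit for interface width and slab half-width, then refine
        # the plateau windows from the fitted interface position
        w0 = 0.5 * np.sum(den_mask) * (x[1] - x[0])
        try:
            popt, _ = curve_fit(
                _tanh_profile,
                x,
                c,
                p0=[prof.c_dil, prof.c_den, max(w0, x[1] - x[0]), 4.0],
                maxfev=20000,
            )
        except RuntimeError:
            prof.delta = None
            prof.d_half = None
            return
        prof.delta = abs(float(popt[3]))
        half_width = abs(float(popt[2]))
        L = x[-1] - x[0]
        prof.d_half = (L - 2.0 * half_width) / 2.0
        bin_w = float(x[1] - x[0])
        margin = max(2.0 * prof.delta, 3.0 * bin_w)
        inner = np.abs(x) <= half_width - margin
        far = np.abs(x) >= half_width + margin
        if inner.sum() >= 3:
            prof.c_den = float(c[inner].mean())
        if far.sum() >= 3:
            prof.c_dil = float(max(c[far].mean(), 0.0))


# ---------------------------------------------------------------------------
# Diffusion
# ---------------------------------------------------------------------------


def msd_diffusion(
    traj: Trajectory,
    *,
    molecule_mask: np.ndarray | None = None,
    max_lag_frac: float = 0.25,
    fit_lag_frac: tuple[float, float] = (0.0, 1.0),
    return_msd: bool = False,
):
    """Diffusion coefficient from the time-averaged center-of-mass MSD.

    The MSD of each polymer's (unwrapped) center of mass is averaged over
    time origins and polymers, then fit through the origin with
    MSD = 6 D t_lag over lags up to ``max_lag_frac`` of the trajectory.
    """
    n_frames = traj.n_frames
    max_lag = int(n_frames * max_lag_frac)
    if max_lag < 3:
        raise ValueError("trajectory too short for an MSD fit")
    n_poly = traj.n_polymers
    counts = np.bincount(traj.mol, minlength=n_poly).astype(float)
    com = np.zeros((n_frames, n_poly, 3))
    for f in range(n_frames):
        np.add.at(com[f], traj.mol, traj.positions[f])
    com /= counts[None, :, None]
    if molecule_mask is not None:
        com = com[:, molecule_mask]

    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    for i, lag in enumerate(lags):
        diff = com[lag:] - com[:-lag]
        msd[i] = np.mean(np.sum(diff**2, axis=-1))
    t_lag = lags * traj.recording_interval
    lo = int(len(lags) * fit_lag_frac[0])
    hi = max(lo + 2, int(len(lags) * fit_lag_frac[1]))
    # least squares through the origin
    tt, mm = t_lag[lo:hi], msd[lo:hi]
    D = float(np.dot(tt, mm) / np.dot(tt, tt) / 6.0)
    if return_msd:
        return D, t_lag, msd
    return D


# ---------------------------------------------------------------------------
# Unbound fractions
# ---------------------------------------------------------------------------


def unbound_fractions(
    state: SimState, cutoff: float = 1.0
) -> dict[str, float]:
    """Fractions of A/B stickers without an opposite-type partner within
    the attraction range, split by phase (dense = largest cluster).

    Returns keys f_dil_A, f_dil_B, f_den_A, f_den_B (NaN when a phase has
    no stickers of that type).
    """
    labels = cluster_polymers(state, cutoff)
    dense_polymers = labels == 0
    dense_sticker = dense_polymers[state.mol]

    pairs = _sticker_contacts(state, cutoff)
    bound = np.zeros(len(state.positions), dtype=bool)
    if len(pairs):
        tA, tB = state.types[pairs[:, 0]], state.types[pairs[:, 1]]
        hetero = tA != tB
        bound[pairs[hetero, 0]] = True
        bound[pairs[hetero, 1]] = True

    out = {}
    for phase, pmask in (("den", dense_sticker), ("dil", ~dense_sticker)):
        for tname, tval in (("A", 0), ("B", 1)):
            m = pmask & (state.types == tval)
            out[f"f_{phase}_{tname}"] = (
                float(np.mean(~bound[m])) if m.any() else float("nan")
            )
    return out


def equilibration_check(
    traj: Trajectory, measure, *, n_blocks: int = 2
) -> tuple[float, float]:
    """First-half vs second-half diagnostic for a scalar measurement.

    ``measure(traj_slice)`` is applied to the two halves; returns the two
    values so the caller can compare them against the sampling error.
    """
    mid = traj.n_frames // 2
    halves = []
    for sl in (slice(0, mid), slice(mid, traj.n_frames)):
        sub = Trajectory(
            times=traj.times[sl],
            positions=traj.positions[sl],
            types=traj.types,
            mol=traj.mol,
            bonds=traj.bonds,
            box=traj.box,
            sequence=traj.sequence,
        )
        halves.append(measure(sub))
    return tuple(halves)
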