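"""In-silico measurement protocols for exchange dynamics.

Two routes to the interface conductance from a phase-separated
trajectory: (i) survival labeling — dilute-phase polymers start
"labeled" and are permanently unlabeled once they hold a lasting A-B
bond to a dense-phase polymer; the exponential decay time of the labeled
fraction feeds the slab inversion formula — and (ii) the flux method,
which divides the measured entry rate per unit interface area by c_den.
Also here: the droplet-radius mass balance, direct in-silico FRAP of a
droplet, and detection of "bounce" events (interface touches that fail
to convert into entries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .analysis import cluster_polymers, _sticker_contacts
from .continuum import RecoveryCurve, fit_finite_recovery
from .simulate import Trajectory

__all__ = [
    "SurvivalRecord",
    "BleachRecord",
    "TouchEvent",
    "survival_protocol",
    "flux_kappa",
    "droplet_radius",
    "insilico_frap",
    "bounce_events",
]


@dataclass
class SurvivalRecord:
    """Survival probability S(t) of initially-dilute polymers."""

    times: np.ndarray
    S: np.ndarray
    entry_times: dict[int, float]   # polymer id -> unlabeling time
    bond_times: dict[int, float]    # polymer id -> formation time of the lasting bond
    n_labeled0: int
    decay_tau: float | None = None

    def fit_decay(self) -> float:
        """Exponential fit S(t) = exp(-t/tau) over the sampled window."""
        t = self.times - self.times[0]
        mask = self.S > 0
        popt, _ = curve_fit(
            lambda tt, tau: np.exp(-tt / tau),
            t[mask],
            self.S[mask],
            p0=[max(t[-1] / 2.0, t[1] if len(t) > 1 else 1.0)],
            maxfev=10000,
        )
        self.decay_tau = float(popt[0])
        return self.decay_tau


def _hetero_partner_map(state, cutoff: float) -> dict[int, set[int]]:
    """polymer -> set of partner polymers holding an A-B sticker contact."""
    pairs = _sticker_contacts(state, cutoff)
    out: dict[int, set[int]] = {}
    if len(pairs) == 0:
        return out
    tA = state.types[pairs[:, 0]]
    tB = state.types[pairs[:, 1]]
    hetero = pairs[tA != tB]
    mol = state.mol
    for a, b in hetero:
        pa, pb = int(mol[a]), int(mol[b])
        if pa == pb:
            continue
        out.setdefault(pa, set()).add(pb)
        out.setdefault(pb, set()).add(pa)
    return out


def survival_protocol(
    traj: Trajectory,
    pair_lifetime: float,
    *,
    entry_multiple: float = 10.0,
    cutoff: float = 1.0,
    min_labeled: int = 10,
    fit: bool = True,
) -> SurvivalRecord:
    """Survival labeling of dilute-phase polymers.

    Polymers outside the largest cluster at the first frame are labeled.
    A labeled polymer is permanently unlabeled the moment it has held an
    A-B bond to some dense-phase polymer (dense at bond formation)
    continuously for longer than ``entry_multiple`` times the isolated
    A-B pair lifetime.  Bond continuity is judged between consecutive
    recorded frames, so the recording interval must be at most
    ``pair_lifetime / 5``.
    """
    dt_rec = traj.recording_interval
    if dt_rec > pair_lifetime / 5.0:
        raise ValueError(
            f"recording interval {dt_rec} too coarse to track bond continuity; "
            f"need <= pair_lifetime/5 = {pair_lifetime / 5.0}"
        )
    threshold = entry_multiple * pair_lifetime

    st0 = traj.state(0)
    labels0 = cluster_polymers(st0, cutoff)
    labeled = set(np.nonzero(labels0 != 0)[0].tolist())
    n0 = len(labeled)
    if n0 < min_labeled:
        raise ValueError(
            f"only {n0} labeled (dilute) polymers; need >= {min_labeled}"
        )

    # per labeled polymer: partner -> (formation_time, partner_was_dense)
    open_bonds: dict[int, dict[int, tuple[float, bool]]] = {p: {} for p in labeled}
    entry_times: dict[int, float] = {}
    bond_times: dict[int, float] = {}
    S = np.empty(traj.n_frames)
    S[0] = 1.0

    for fidx in range(1, traj.n_frames):
        st = traj.state(fidx)
        t = float(traj.times[fidx])
        clabels = cluster_polymers(st, cutoff)
        dense = clabels == 0
        partners = _hetero_partner_map(st, cutoff)
        for p in list(labeled):
            cur = partners.get(p, set())
            ob = open_bonds[p]
            # close bonds that broke
            for q in list(ob):
                if q not in cur:
                    del ob[q]
            # open new bonds, tagging the partner's phase at formation
            for q in cur:
                if q not in ob:
                    ob[q] = (t, bool(dense[q]))
            # check the lasting-bond entry criterion
            for q, (t_form, was_dense) in ob.items():
                if was_dense and (t - t_form) > threshold:
                    labeled.discard(p)
                    entry_times[p] = t
                    bond_times[p] = t_form
                    break
        S[fidx] = len(labeled) / n0

    rec = SurvivalRecord(
        times=traj.times.copy(),
        S=S,
        entry_times=entry_times,
        bond_times=bond_times,
        n_labeled0=n0,
    )
    if fit and len(entry_times) >= 3:
        rec.fit_decay()
    return rec


def flux_kappa(
    n_entries: int,
    t_obs: float,
    area: float,
    c_den: float,
) -> float:
    """Interface conductance from the measured entry flux.

    At equilibrium the flux of molecules entering the dense phase per
    unit interface area is k+ c_dil = kappa c_den, so
    kappa = (n_entries / t_obs) / (area * c_den).  ``area`` is the total
    interface area crossed (two cross-sections for a slab, the sphere
    surface for a droplet); c_den in molecules per volume with length
    units matching ``area``.
    """
    if t_obs <= 0 or area <= 0 or c_den <= 0:
        raise ValueError("t_obs, area and c_den must be positive")
    if n_entries == 0:
        return 0.0
    return n_entries / (t_obs * area * c_den)


def flux_kappa_from_survival(
    rec: SurvivalRecord,
    area: float,
    c_den: float,
    n_dilute: float | None = None,
) -> float:
    """Flux-method conductance from survival-labeling entry events.

    The per-polymer entry rate is estimated with exposure correction,
    nu = n_entries / integral N_labeled(t) dt, and scaled to the full
    dilute pool (``n_dilute``, default: the initially labeled count), so
    kappa = nu * n_dilute / (area * c_den) estimates the equilibrium
    entry flux per area over c_den even though only first entries of
    labeled polymers are counted.
    """
    exposure = rec.n_labeled0 * float(np.trapezoid(rec.S, rec.times))
    if exposure <= 0:
        raise ValueError("no labeled exposure in the record")
    n_dil = rec.n_labeled0 if n_dilute is None else n_dilute
    return len(rec.entry_times) / exposure * n_dil / (area * c_den)


def droplet_radius(
    c_den_d: float, c_dil_d: float, V_box: float, N_total: float
) -> float:
    """Effective droplet radius from the two-phase mass balance.

    Solves 4 pi R^3 c_den/3 + (V_box - 4 pi R^3/3) c_dil = N_total in
    closed form.  Concentrations in molecules per volume; R in the same
    length unit as V_box^(1/3).
    """
    if c_den_d <= c_dil_d:
        raise ValueError("c_den must exceed c_dil")
    excess = N_total - V_box * c_dil_d
    if excess < 0:
        raise ValueError("no droplet: N_total below the dilute-phase capacity")
    vol = excess / (c_den_d - c_dil_d)
    R = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)
    R_max = 0.5 * V_box ** (1.0 / 3.0)
    if R > V_box ** (1.0 / 3.0):
        raise ValueError("mass balance gives a droplet larger than the box")
    return R


@dataclass
class BleachRecord:
    """In-silico FRAP of a droplet: lag-averaged recovery curve."""

    times: np.ndarray           # lag since bleach
    f: np.ndarray               # unbleached fraction among droplet residents
    n_origins: int
    fit_A: float | None = None
    fit_tau: float | None = None

    def as_curve(self) -> RecoveryCurve:
        return RecoveryCurve(self.times, self.f)

    def fit(self) -> tuple[float, float]:
        A, tau = fit_finite_recovery(self.as_curve())
        self.fit_A, self.fit_tau = A, tau
        return A, tau


def insilico_frap(
    traj: Trajectory,
    *,
    cutoff: float = 1.0,
    equilibration_frames: int = 0,
    t0_stride: int = 1,
    max_lag_frames: int | None = None,
) -> BleachRecord:
    """Droplet FRAP by label bookkeeping.

    For each bleach origin t0 (every ``t0_stride``-th recorded frame
    after the equilibration cut) all polymers in the droplet — the
    largest cluster — are flagged bleached; at lag t the recovery
    f(t) is the fraction of current droplet residents that are
    unbleached.  Curves are averaged over all origins.
    """
    n_frames = traj.n_frames
    members = []
    for fidx in range(n_frames):
        st = traj.state(fidx)
        members.append(cluster_polymers(st, cutoff) == 0)
    members = np.asarray(members)  # (F, n_poly)
    if not members.any():
        raise ValueError("droplet not identifiable in trajectory")

    origins = list(range(equilibration_frames, n_frames - 2, t0_stride))
    if not origins:
        raise ValueError("no usable bleach origins after the equilibration cut")
    if max_lag_frames is None:
        max_lag_frames = n_frames - origins[0] - 1
    acc = np.zeros(max_lag_frames + 1)
    cnt = np.zeros(max_lag_frames + 1, dtype=int)
    for t0 in origins:
        bleached = members[t0]
        top = min(n_frames - t0 - 1, max_lag_frames)
        for lag in range(top + 1):
            cur = members[t0 + lag]
            n_in = cur.sum()
            if n_in == 0:
                continue
            acc[lag] += np.sum(cur & ~bleached) / n_in
            cnt[lag] += 1
    valid = cnt > 0
    lags = np.arange(max_lag_frames + 1)[valid] * traj.recording_interval
    f = acc[valid] / cnt[valid]
    return BleachRecord(times=lags, f=f, n_origins=len(origins))


@dataclass
class TouchEvent:
    """A maximal interval during which a polymer touches the dense cluster."""

    t_start: float
    t_end: float
    entered: bool


def bounce_events(
    traj: Trajectory,
    polymer: int,
    *,
    pair_lifetime: float | None = None,
    entry_multiple: float = 10.0,
    cutoff: float = 1.0,
) -> list[TouchEvent]:
    """Touch intervals of one polymer against the dense cluster.

    A "touch" is a maximal run of frames in which any sticker of the
    polymer lies within ``cutoff`` of a sticker of the largest cluster
    (the polymer itself excluded).  If ``pair_lifetime`` is given, a
    touch is flagged ``entered`` when an A-B bond to a dense polymer
    persisted longer than ``entry_multiple * pair_lifetime`` within it;
    otherwise a touch is ``entered`` if the polymer ends it inside the
    largest cluster.  Touches without entry are "bounces".
    """
    touching = np.zeros(traj.n_frames, dtype=bool)
    bonded_dense = np.zeros(traj.n_frames, dtype=bool)
    for fidx in range(traj.n_frames):
        st = traj.state(fidx)
        clabels = cluster_polymers(st, cutoff)
        partners = _hetero_partner_map(st, cutoff)
        # touching: any sticker contact (hetero or not) with a largest-cluster polymer
        pairs = _sticker_contacts(st, cutoff)
        if len(pairs):
            mol = st.mol
            pa, pb = mol[pairs[:, 0]], mol[pairs[:, 1]]
            mine = (pa == polymer) ^ (pb == polymer)
            other = np.where(pa == polymer, pb, pa)[mine]
            touching[fidx] = np.any(clabels[other] == 0) if len(other) else False
        bonded_dense[fidx] = any(
            clabels[q] == 0 for q in partners.get(polymer, set())
        )
        if clabels[polymer] == 0 and not touching[fidx]:
            # the polymer is itself the seed of the largest cluster; count as touch
            touching[fidx] = bonded_dense[fidx]

    events: list[TouchEvent] = []
    fidx = 0
    dt_rec = traj.recording_interval
    while fidx < traj.n_frames:
        if not touching[fidx]:
            fidx += 1
            continue
        start = fidx
        while fidx < traj.n_frames and touching[fidx]:
            fidx += 1
        end = fidx - 1
        if pair_lifetime is not None:
            # longest continuous bonded-to-dense run inside the touch
            run = best = 0
            for k in range(start, end + 1):
                run = run + 1 if bonded_dense[k] else 0
                best = max(best, run)
            entered = (best - 1) * dt_rec > entry_multiple * pair_lifetime
        else:
            st = traj.state(end)
            entered = cluster_polymers(st, cutoff)[polymer] == 0
        events.append(
            TouchEvent(float(traj.times[start]), float(traj.times[end]), entered)
        )
    return events
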