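"""Closed-form theory of the interface conductance κ.

κ (units µm/s) sets the net flux through the condensate surface,
κ [c(R-) - (c_den/c_dil) c(R+)], and is the inverse of the interface
resistance.  This module collects every analytic route to it:

* the mean-field value from an equilibrium concentration profile,
  κ⁻¹ = ∫ c_eq(x) / (c_den D(x)) dx over the interface region;
* its sharp-interface limit κ0 = c_dil D_dil / (δ c_den);
* the sticker-availability prediction, which multiplies the free-sticker
  encounter rate into κ and collapses κ/κ0 onto a single dimensionless
  availability parameter u;
* the inversion of a measured slab-geometry decay time into κ; and
* the droplet-size crossover radius beyond which diffusion, not the
  interface, limits recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import TwoPhaseParams

__all__ = [
    "InterfaceProfile",
    "StickerAvailability",
    "mean_field_kappa",
    "kappa0",
    "kappa_sticker_theory",
    "u_parameter",
    "slab_kappa_from_decay",
    "crossover_radius",
]

#: nm -> µm
_NM = 1e-3


@dataclass(frozen=True)
class InterfaceProfile:
    """Equilibrium profile across the interface.

    x_grid in nm, c_eq in any concentration unit consistent with c_den,
    D_local in µm²/s.  c_eq is expected to run monotonically between the
    dilute and dense plateau values over the window.
    """

    x_grid: np.ndarray
    c_eq: np.ndarray
    D_local: np.ndarray
    delta: float  # interface width (nm), informational

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_grid", np.asarray(self.x_grid, dtype=float))
        object.__setattr__(self, "c_eq", np.asarray(self.c_eq, dtype=float))
        object.__setattr__(self, "D_local", np.asarray(self.D_local, dtype=float))
        if not (len(self.x_grid) == len(self.c_eq) == len(self.D_local)):
            raise ValueError("profile arrays must have equal length")
        if np.any(np.diff(self.x_grid) <= 0):
            raise ValueError("x_grid must be strictly increasing")


def mean_field_kappa(profile: InterfaceProfile, c_den: float) -> float:
    """Mean-field interface conductance from an equilibrium profile.

    κ⁻¹ = ∫ c_den / (c_eq(x) D(x)) dx, integrated across the interface
    window; a molecule crossing the interface simply diffuses through the
    local concentration landscape, and regions of low equilibrium
    concentration and low mobility dominate the resistance.  For a
    dilute-like window of width δ this reduces to κ0 = c_dil D_dil/(δ c_den).
    Returns κ in µm/s for x in nm and D in µm²/s.
    """
    if np.any(profile.D_local <= 0):
        raise ValueError("D_local must be positive everywhere")
    if np.any(profile.c_eq <= 0):
        raise ValueError("c_eq must be positive everywhere")
    integrand = c_den / (profile.c_eq * profile.D_local)
    inv_kappa = np.trapezoid(integrand, profile.x_grid * _NM)
    if inv_kappa <= 0:
        return math.inf
    return float(1.0 / inv_kappa)


def kappa0(c_dil: float, D_dil: float, delta: float, c_den: float) -> float:
    """Sharp-interface mean-field conductance κ0 = c_dil D_dil / (δ c_den).

    delta in nm, D_dil in µm²/s, κ0 in µm/s.  This is the mean-field
    integral evaluated for a dilute-like interface region of width δ and
    serves as the no-bouncing reference against which measured κ is
    compared.
    """
    for name, v in (("c_dil", c_dil), ("D_dil", D_dil), ("delta", delta),
                    ("c_den", c_den)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    return c_dil * D_dil / (delta * _NM * c_den)


@dataclass(frozen=True)
class StickerAvailability:
    """Inputs of the sticker-availability κ prediction.

    r0 : sticker capture radius (nm); delta : interface width (nm);
    n : monomers (stickers) per polymer; s : global stoichiometry c_A/c_B;
    f_dil_A .. f_den_B : fractions of unbound A/B stickers per phase;
    c_dil, c_den : polymer number densities (nm⁻³); D_dil in µm²/s.
    """

    r0: float
    delta: float
    n: int
    s: float
    f_dil_A: float
    f_dil_B: float
    f_den_A: float
    f_den_B: float
    c_dil: float
    c_den: float
    D_dil: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("stoichiometry s must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("f_dil_A", "f_dil_B", "f_den_A", "f_den_B"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def _availability(self) -> float:
        return self.f_dil_A * self.f_den_B + self.f_dil_B * self.f_den_A

    @property
    def _stoich(self) -> float:
        return 2.0 + self.s + 1.0 / self.s


def kappa_sticker_theory(sa: StickerAvailability) -> float:
    """Interface conductance set by unbound-sticker encounters.

    κ = 4π r0 δ D_dil n² c_dil / (2 + s + s⁻¹) · (f^A_dil f^B_den + f^B_dil f^A_den)

    A polymer incident from the dilute phase joins the dense phase only if
    one of its free stickers meets a free sticker of the opposite type at
    the surface; when free stickers are scarce it bounces instead, and κ
    collapses well below κ0.  Returns µm/s.
    """
    geom = 4.0 * math.pi * (sa.r0 * _NM) * (sa.delta * _NM)
    c_dil_um3 = sa.c_dil / _NM**3
    return geom * sa.D_dil * sa.n**2 * c_dil_um3 / sa._stoich * sa._availability


def u_parameter(sa: StickerAvailability) -> float:
    """Dimensionless free-sticker availability

    u = 4π r0 δ² n² c_den / (2 + s + s⁻¹) · (f^A_dil f^B_den + f^B_dil f^A_den),

    which satisfies κ/κ0 = u exactly with κ0 = c_dil D_dil/(δ c_den):
    the suppression of κ below the mean-field value is precisely the
    scarcity of bonding opportunities at the surface.
    """
    return (
        4.0 * math.pi * sa.r0 * sa.delta**2 * sa.n**2 * sa.c_den
        / sa._stoich * sa._availability
    )


class DiffusionLimitedError(ValueError):
    """The measured decay is faster than pure dilute-phase diffusion allows,
    so no finite interface conductance can reproduce it."""


def slab_kappa_from_decay(
    tau: float, d: float, D_dil: float, c_dil: float, c_den: float
) -> float:
    """Invert a slab-geometry labeled-population decay time into κ.

    κ = (c_dil/c_den) sqrt(D_dil/τ) tan(d / sqrt(τ D_dil)),

    where d is the half-width of the dilute phase and τ the exponential
    decay time of the fraction of labeled dilute-phase polymers.  This is
    the exact inversion of the slowest eigenmode of 1D diffusion toward an
    interface that absorbs at rate k+ = κ c_den/c_dil.  Units are free as
    long as d² / (τ D_dil) is consistent; κ comes out in d-units per
    τ-unit scaled by c_dil/c_den.
    """
    if tau <= 0 or d <= 0 or D_dil <= 0:
        raise ValueError("tau, d and D_dil must be positive")
    arg = d / math.sqrt(tau * D_dil)
    if arg >= math.pi / 2:
        raise DiffusionLimitedError(
            f"decay time {tau} is at or below the pure-diffusion limit "
            f"(2d/pi)^2/D_dil = {(2 * d / math.pi) ** 2 / D_dil:.6g}; "
            "the interface is not rate-limiting"
        )
    return c_dil / c_den * math.sqrt(D_dil / tau) * math.tan(arg)


def crossover_radius(params: TwoPhaseParams) -> float:
    """Droplet radius at which interface resistance stops dominating.

    The interface term of the recovery time grows linearly with R while
    the two diffusive terms grow as R²; R_x equates them:

        R_x = (1/(3κ)) / (1/(π² D_den) + c_den/(3 c_dil D_dil)).

    Below R_x droplets recover uniformly (interface-limited); above it a
    diffusive recovery front appears.  κ = inf gives R_x = 0.
    """
    if math.isinf(params.kappa):
        return 0.0
    denom = 1.0 / (math.pi**2 * params.D_den) + params.partition / (3.0 * params.D_dil)
    return (1.0 / (3.0 * params.kappa)) / denom
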