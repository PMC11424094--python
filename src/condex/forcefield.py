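"""Sticker-spacer force field: stretchable bonds, saturable heterotypic
attraction, and same-type repulsion.

Polymers are linear chains of spherical "stickers" of type A or B.
Consecutive stickers are joined by a finitely extensible bond

    Ub(r) = -1/2 K R0^2 ln[1 - (r/R0)^2],      r < R0,

representing an implicit flexible spacer.  A and B stickers attract via a
short-ranged cosine well

    Ua(r) = -1/2 U0 [1 + cos(pi r / r0)],      r < r0,

deep enough (default 14 kBT) that an A-B pair behaves as a transient
one-to-one bond, while same-type stickers repel through the WCA potential

    Ur(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps,   r <= rc = 2^(1/6) sigma,

whose excluded volume prevents many-to-one binding.  Lengths are in nm
and energies in kBT throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "ForceField",
    "bond_energy",
    "bond_force",
    "attract_energy",
    "attract_force",
    "repulse_energy",
    "repulse_force",
    "mean_bond_length",
]


@dataclass(frozen=True)
class ForceField:
    """Force-field constants (nm, kBT)."""

    K: float = 0.15       # bond stiffness, kBT/nm^2
    R0: float = 10.0      # maximum bond extension, nm
    U0: float = 14.0      # heterotypic well depth, kBT
    r0: float = 1.0       # attraction range, nm
    epsilon: float = 1.0  # repulsion strength, kBT
    sigma: float = 2.0    # repulsion diameter, nm
    rc: float = 2.0 * 2.0 ** (1.0 / 6.0)  # repulsion cutoff, nm

    def __post_init__(self) -> None:
        for name in ("K", "R0", "U0", "r0", "epsilon", "sigma", "rc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def cutoff(self) -> float:
        """Largest non-bonded interaction range."""
        return max(self.r0, self.rc)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.K, self.R0, self.U0, self.r0, self.epsilon, self.sigma, self.rc)


def bond_energy(r, ff: ForceField):
    """Stretchable-bond energy; diverges (+inf) at r >= R0."""
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(
            r < ff.R0,
            -0.5 * ff.K * ff.R0**2 * np.log(np.maximum(1.0 - (r / ff.R0) ** 2, 0.0)),
            np.inf,
        )
    return u if u.ndim else float(u)


def bond_force(r, ff: ForceField):
    """Radial bond force -dUb/dr (negative: pulls the pair together)."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        f = np.where(r < ff.R0, -ff.K * r / (1.0 - (r / ff.R0) ** 2), -np.inf)
    return f if f.ndim else float(f)


def attract_energy(r, ff: ForceField):
    """Heterotypic A-B attraction; -U0 at contact, 0 at and beyond r0."""
    r = np.asarray(r, dtype=float)
    u = np.where(r < ff.r0, -0.5 * ff.U0 * (1.0 + np.cos(np.pi * r / ff.r0)), 0.0)
    return u if u.ndim else float(u)


def attract_force(r, ff: ForceField):
    """-dUa/dr."""
    r = np.asarray(r, dtype=float)
    f = np.where(
        r < ff.r0, -0.5 * ff.U0 * np.pi / ff.r0 * np.sin(np.pi * r / ff.r0), 0.0
    )
    return f if f.ndim else float(f)


def repulse_energy(r, ff: ForceField):
    """Same-type WCA repulsion, cut and shifted to zero at rc."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        sr6 = (ff.sigma / r) ** 6
        u = np.where(r <= ff.rc, 4.0 * ff.epsilon * (sr6**2 - sr6) + ff.epsilon, 0.0)
    return u if u.ndim else float(u)


def repulse_force(r, ff: ForceField):
    """-dUr/dr."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        sr6 = (ff.sigma / r) ** 6
        f = np.where(r <= ff.rc, 4.0 * ff.epsilon * (12.0 * sr6**2 - 6.0 * sr6) / r, 0.0)
    return f if f.ndim else float(f)


def mean_bond_length(ff: ForceField, kT: float = 1.0, same_type: bool = True) -> float:
    """Thermal mean length of a single bond by radial quadrature.

    <r> = int r^3 exp(-U(r)/kT) dr / int r^2 exp(-U(r)/kT) dr over (0, R0),
    with U = Ub + Ur for a same-type neighbor pair (the default chain
    neighbor within a sticker block) or U = Ub + Ua across a block
    boundary.  At the default parameters the same-type value is ~3.9 nm.
    """

    def u(r: float) -> float:
        ub = float(bond_energy(r, ff))
        other = repulse_energy(r, ff) if same_type else attract_energy(r, ff)
        return ub + float(other)

    umin = min(u(x) for x in np.linspace(1e-3, ff.R0 * 0.999, 400))

    def w(r: float) -> float:
        return math.exp(-(u(r) - umin) / kT)

    num, _ = quad(lambda r: r**3 * w(r), 0.0, ff.R0, limit=200)
    den, _ = quad(lambda r: r**2 * w(r), 0.0, ff.R0, limit=200)
    return num / den
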