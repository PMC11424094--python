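"""Physical parameter bundles and unit conversions.

Internal conventions: lengths in µm for continuum quantities, nm for
molecular ones; times in s; a single (arbitrary but consistent)
concentration unit per run — only the ratio ``c_den / c_dil`` enters the
recovery-time formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

__all__ = [
    "TwoPhaseParams",
    "NM3_TO_MOLAR",
    "per_nm3_to_millimolar",
    "millimolar_to_per_nm3",
]

#: 1 molecule/nm^3 expressed in mol/L: 1e24 / N_A = 1.661 M.
NM3_TO_MOLAR = 1e24 / 6.02214076e23


def per_nm3_to_millimolar(c: float) -> float:
    """Convert a number density in nm^-3 to a molar concentration in mM."""
    return c * NM3_TO_MOLAR * 1e3


def millimolar_to_per_nm3(c_mm: float) -> float:
    """Convert a molar concentration in mM to a number density in nm^-3."""
    return c_mm * 1e-3 / NM3_TO_MOLAR


@dataclass(frozen=True)
class TwoPhaseParams:
    """Parameters of the two-phase droplet exchange problem.

    Attributes
    ----------
    R : float
        Droplet radius (µm).
    D_den, D_dil : float
        Diffusion coefficients in the dense and dilute phase (µm²/s).
    c_den, c_dil : float
        Equilibrium concentrations in the dense and dilute phase, in any
        consistent unit (only the ratio matters for the timescales).
    kappa : float
        Interface conductance (µm/s).  ``math.inf`` means no interface
        resistance (the concentration jump is pinned to its equilibrium
        ratio at the interface).
    """

    R: float
    D_den: float
    D_dil: float
    c_den: float
    c_dil: float
    kappa: float = math.inf

    def __post_init__(self) -> None:
        for name in ("R", "D_den", "D_dil", "c_den", "c_dil", "kappa"):
            v = getattr(self, name)
            if not np.isfinite(v) and not (name == "kappa" and v == math.inf):
                raise ValueError(f"{name} must be finite (kappa may be inf), got {v}")
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.c_den < self.c_dil:
            raise ValueError(
                f"c_den ({self.c_den}) must be >= c_dil ({self.c_dil})"
            )

    @property
    def partition(self) -> float:
        """Equilibrium partition coefficient c_den / c_dil."""
        return self.c_den / self.c_dil

    def with_(self, **kwargs: Any) -> "TwoPhaseParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, m: Mapping[str, Any]) -> "TwoPhaseParams":
        """Build from a dict (e.g. a parsed TOML/YAML/JSON parameter file).

        Unknown keys are rejected so that typos in parameter files fail
        loudly.  The string ``"inf"`` is accepted for ``kappa``.
        """
        allowed = {"R", "D_den", "D_dil", "c_den", "c_dil", "kappa"}
        unknown = set(m) - allowed
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        d = dict(m)
        if isinstance(d.get("kappa"), str):
            if d["kappa"].lower() in ("inf", "infinity"):
                d["kappa"] = math.inf
            else:
                d["kappa"] = float(d["kappa"])
        return cls(**{k: float(v) for k, v in d.items()})


#: The LAF-1 droplet worked example: R = 1 µm droplet with
#: D_den = 0.0017 µm²/s, D_dil = 94 µm²/s and c_den/c_dil = 1190.
LAF1_PARAMS = TwoPhaseParams(
    R=1.0, D_den=0.0017, D_dil=94.0, c_den=1190.0, c_dil=1.0, kappa=math.inf
)
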