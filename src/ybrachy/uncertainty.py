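"""Quadrature propagation of the statistical and systematic uncertainty
components attached to every TG-43 quantity.

All inputs and outputs are *relative* (dimensionless) standard uncertainties.
Components are treated as independent, so every combination is a plain
quadrature sum; the cross-section database contribution sigma_CS enters the
ratio quantities (g, F, Lambda) twice because numerator and denominator each
carry it.  The fixed default sigma_CS = 2% reflects the stated uncertainty of
the interaction-coefficient database; it is a parameter everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

__all__ = [
    "UncertaintyBudget",
    "quadrature",
    "sk_rel_uncertainty",
    "lambda_rel_uncertainty",
    "g_rel_uncertainty",
    "f_rel_uncertainty",
    "dose_rate_rel_uncertainty",
    "shell_average_inverse_square",
    "shell_average_deviation",
    "round_value_with_uncertainty",
]

SIGMA_CS_DEFAULT = 0.02


@dataclass
class UncertaintyBudget:
    """Named relative components (type A statistical / type B systematic)."""

    components: List[Tuple[str, float, str]] = field(default_factory=list)

    def add(self, name: str, value: float, kind: str = "A") -> "UncertaintyBudget":
        if value < 0:
            raise ValueError(f"component {name!r} must be non-negative")
        if kind not in ("A", "B"):
            raise ValueError("component type must be 'A' or 'B'")
        self.components.append((name, float(value), kind))
        return self

    @property
    def combined(self) -> float:
        return float(np.sqrt(sum(v * v for _, v, _ in self.components)))

    def as_dict(self) -> dict:
        return {"components": [{"name": n, "rel_value": v, "type": k}
                               for n, v, k in self.components],
                "combined_rel": self.combined}


def quadrature(*components) -> np.ndarray | float:
    comps = [np.asarray(c, float) for c in components]
    if any(np.any(c < 0) for c in comps):
        raise ValueError("uncertainty components must be non-negative")
    out = np.sqrt(sum(c * c for c in comps))
    return float(out) if np.isscalar(components[0]) or np.ndim(out) == 0 else out


def sk_rel_uncertainty(sigma_mc, sigma_cs=SIGMA_CS_DEFAULT, sigma_igamma=0.0):
    """Air-kerma strength: MC statistics + cross-section database + photon yield."""
    return quadrature(sigma_mc, sigma_cs, sigma_igamma)


def lambda_rel_uncertainty(sigma_mc_ref, sigma_airkerma, sigma_cs=SIGMA_CS_DEFAULT):
    """Dose-rate constant: the cross-section term enters both the water-phantom
    reference dose rate and the air-kerma rate, hence twice in quadrature."""
    return quadrature(sigma_mc_ref, sigma_airkerma, sigma_cs, sigma_cs)


def g_rel_uncertainty(sigma_mc_r, sigma_mc_ref, sigma_cs=SIGMA_CS_DEFAULT,
                      at_reference=False):
    """Radial dose function: exactly zero at the reference radius (the ratio
    is 1 by construction there), quadrature of both voxels' statistics plus
    the doubled cross-section term elsewhere."""
    out = quadrature(sigma_mc_r, sigma_mc_ref, sigma_cs, sigma_cs)
    return np.where(at_reference, 0.0, out) if np.ndim(out) else (0.0 if at_reference else out)


def f_rel_uncertainty(sigma_mc_rtheta, sigma_mc_rtheta0, sigma_cs=SIGMA_CS_DEFAULT,
                      at_reference=False):
    """2-D anisotropy function; same structure as the radial dose function."""
    return g_rel_uncertainty(sigma_mc_rtheta, sigma_mc_rtheta0, sigma_cs, at_reference)


def dose_rate_rel_uncertainty(sigma_mc, sigma_cs=SIGMA_CS_DEFAULT, sigma_igamma=0.0):
    """Absolute dose rate: MC statistics + cross sections + photon yield."""
    return quadrature(sigma_mc, sigma_cs, sigma_igamma)


def shell_average_inverse_square(a_cm: float, b_cm: float) -> float:
    """Radial average of 1/r^2 over a shell [a, b]:

        (1/(b-a)) * integral_a^b dr/r^2  =  (1/(b-a)) (1/a - 1/b)  =  1/(a b)

    Used to refer a finite-thickness shell tally back to its nominal
    distance d = (a + b)/2.
    """
    a, b = float(a_cm), float(b_cm)
    if not 0 < a < b:
        raise ValueError(f"require 0 < a < b, got a={a}, b={b}")
    return 1.0 / (a * b)


def shell_average_deviation(d_cm: float, half_width_cm: float = 2.5) -> float:
    """Relative deviation of the shell average of 1/r^2 from 1/d^2."""
    avg = shell_average_inverse_square(d_cm - half_width_cm, d_cm + half_width_cm)
    return avg * d_cm**2 - 1.0


def round_value_with_uncertainty(value: float, uncertainty: float) -> tuple:
    """Display convention: uncertainty to one significant figure, value to
    matching precision (e.g. 1.2136 +- 0.0292 -> (1.21, 0.03))."""
    if uncertainty <= 0:
        return value, 0.0
    exp = int(np.floor(np.log10(uncertainty)))
    u = round(uncertainty, -exp)
    if u >= 10 ** (exp + 1):   # 0.096 -> 0.1 style carry
        exp += 1
        u = round(uncertainty, -exp)
    return round(value, -exp), u
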