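"""Model parameters.

The carbon budget of an individual jellyfish is controlled by 17 parameters.
Eleven are fixed from published laboratory regressions (predation and
respiration allometries, conversion factors, egg mass); six are unknown and
calibrated by the statistical model checking engine (k_p, a_max, k_a, c_re,
spn, c_e), together with the laboratory prey concentration F_lab.

Units follow each process equation:

* predation: ``p_max`` gC.ind-1.d-1 for a 1 gC individual at 0 degC with
  unlimited food; ``k_p`` gC.L-1.
* respiration: ``R_o`` umolO2.d-1 for a 1 g wet-mass individual at 0 degC.
* reproduction: egg count power law on body mass, ``W_e`` gC per egg,
  ``c_re`` the mucus carbon cost as a multiple of egg carbon, ``spn``
  spawns per day; active only above the maturity bell diameter (4 cm).
* shared temperature response: rate ∝ t_10^T with t_10 the tenth root of
  Q10 (1.066, i.e. Q10 ≈ 1.9).

``p_max`` and ``k_p`` are coupled through the food-saturation reference
F_sat: p_max = 0.1399 * (1 + k_p / F_sat).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParameterSet",
    "p_max_from_kp",
    "SEARCHED_PARAMETERS",
    "DEFAULT_PSEUDO_STD",
    "TABLE_SEARCH_VECTORS",
    "LAB_BEST",
    "INSITU_BEST",
]

P_MAX_BASE = 0.1399

#: parameters the calibration engine searches, in canonical order.
SEARCHED_PARAMETERS = ("k_p", "a_max", "k_a", "c_re", "spn", "c_e", "F_lab")

#: default pseudo standard deviations used to build the uncertainty interval
#: around a candidate's central values (reported alongside the best fits).
DEFAULT_PSEUDO_STD = {
    "k_p": 1e-5,
    "a_max": 0.05,
    "k_a": 5e-6,
    "c_re": 0.05,
    "spn": 0.05,
    "c_e": 0.025,
    "F_lab": 0.05e-5,  # half the search-grid step; not reported with the fits
}

#: published search brackets (lo, step, hi) in each parameter's native units.
TABLE_SEARCH_VECTORS = {
    "k_p": (3e-5, 2e-5, 2e-4),
    "a_max": (0.5, 0.1, 1.0),
    "k_a": (1.5e-5, 0.5e-5, 5e-5),
    "c_re": (1.0, 0.1, 3.0),
    "spn": (0.4, 0.1, 1.0),
    "c_e": (0.0, 0.2, 2.0),
    "F_lab": (0.7e-5, 0.1e-5, 1.2e-5),
}

#: best central values under laboratory-only calibration.
LAB_BEST = {
    "k_p": 1.9e-4,
    "a_max": 0.8,
    "k_a": 5e-5,
    "c_re": 2.7,
    "spn": 0.7,
    "c_e": 0.0,
    "F_lab": 0.9e-5,
}

#: best central values under in-situ-only calibration.
INSITU_BEST = {
    "k_p": 1.9e-4,
    "a_max": 1.0,
    "k_a": 4e-5,
    "c_re": 2.5,
    "spn": 0.8,
    "c_e": 0.0,
    "F_lab": 0.9e-5,
}


def p_max_from_kp(k_p: float, F_sat: float = 1.2e-4) -> float:
    """Maximum predation rate coupled to the half-saturation constant.

    p_max = 0.1399 * (1 + k_p / F_sat), with F_sat the food-saturation
    reference concentration (gC.L-1) at which the source feeding
    observations were made.
    """
    if F_sat <= 0:
        raise ValueError("F_sat must be strictly positive")
    if np.any(np.asarray(k_p) < 0):
        raise ValueError("k_p must be non-negative")
    return P_MAX_BASE * (1.0 + k_p / F_sat)


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter vector of the individual carbon-budget model.

    Defaults are the fixed literature values plus the best laboratory
    central values for the six calibrated parameters.
    """

    # predation
    p_max: float = p_max_from_kp(1.9e-4)  # gC.ind-1.d-1
    b_p: float = 0.8856
    k_p: float = 1.9e-4  # gC.L-1
    # respiration
    R_o: float = 2.80  # umolO2.d-1 per 1 g WM at 0 degC
    b_r: float = 0.934
    # temperature response (tenth root of Q10); optional per-process overrides
    t_10: float = 1.066
    t_10_predation: float | None = None
    t_10_respiration: float | None = None
    # unit conversions
    beta: float = 0.447  # J per umolO2
    alpha: float = 2.28e-5  # gC per J
    # reproduction
    a_re: float = 0.07
    b_re: float = 4.66
    W_e: float = 1.52e-6  # gC per egg
    c_re: float = 2.7
    spn: float = 0.7  # spawns per day
    maturity_bd: float = 4.0  # cm
    # assimilation
    a_max: float = 0.8
    k_a: float = 5e-5  # gC.L-1
    # excretion
    c_e: float = 0.0
    # p_max / k_p coupling reference
    F_sat: float = 1.2e-4  # gC.L-1
    # unit conventions (see docs/methods.md)
    respiration_mass_basis: str = "wm"  # 'wm' (default) or 'cm'
    reproduction_mass_basis: str = "wm"  # 'wm', 'cm_g' or 'cm_mg'

    def __post_init__(self):
        nonneg = (
            "p_max b_p k_p R_o b_r beta alpha a_re b_re W_e c_re spn "
            "a_max k_a c_e F_sat"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.a_max <= 1.0:
            raise ValueError("a_max must lie in [0, 1]")
        if self.t_10 <= 1.0:
            raise ValueError("t_10 must exceed 1 (rates rise with temperature)")
        if self.maturity_bd <= 0:
            raise ValueError("maturity_bd must be positive")
        if self.respiration_mass_basis not in ("wm", "cm"):
            raise ValueError("respiration_mass_basis must be 'wm' or 'cm'")
        if self.reproduction_mass_basis not in ("wm", "cm_g", "cm_mg"):
            raise ValueError(
                "reproduction_mass_basis must be 'wm', 'cm_g' or 'cm_mg'"
            )

    @property
    def t10_predation(self) -> float:
        return self.t_10 if self.t_10_predation is None else self.t_10_predation

    @property
    def t10_respiration(self) -> float:
        return self.t_10 if self.t_10_respiration is None else self.t_10_respiration

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def with_kp(self, k_p: float) -> "ParameterSet":
        """Set k_p and recompute the coupled p_max."""
        return self.replace(k_p=k_p, p_max=p_max_from_kp(k_p, self.F_sat))

    def with_central(self, central: dict) -> "ParameterSet":
        """Apply calibrated central values (ignoring F_lab, a forcing input)."""
        changes = {k: v for k, v in central.items() if k != "F_lab"}
        out = self.replace(**changes)
        if "k_p" in changes:
            out = out.with_kp(changes["k_p"])
        return out
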