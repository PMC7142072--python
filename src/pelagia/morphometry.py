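"""Morphometric conversions for *Pelagia noctiluca*.

Bell diameter (BD, cm, measured over the lappets), wet mass (WM, g) and
carbon mass (CM) are linked by two allometric power laws fitted on
Mediterranean specimens:

    WM = 0.075 * BD^2.993        (WM in g)
    CM = 0.26  * BD^3.017        (CM in mg)

so carbon mass is ~0.36% of wet mass across the adult size range.  All
functions accept scalars or numpy arrays and return carbon mass in grams.
"""

from __future__ import annotations

import numpy as np

WM_COEF = 0.075
WM_EXP = 2.993
CM_COEF_MG = 0.26
CM_EXP = 3.017

__all__ = ["wm_from_bd", "cm_from_bd", "bd_from_cm", "wm_from_cm"]


def _check_positive(x, name: str):
    if np.any(np.asarray(x) <= 0):
        raise ValueError(f"{name} must be strictly positive")


def wm_from_bd(bd):
    """Wet mass (g) from bell diameter (cm)."""
    _check_positive(bd, "bell diameter")
    return WM_COEF * np.asarray(bd, dtype=float) ** WM_EXP


def cm_from_bd(bd):
    """Carbon mass (g C) from bell diameter (cm).

    The underlying regression yields milligrams; the result is converted
    to grams so every carbon flux in the model shares one unit.
    """
    _check_positive(bd, "bell diameter")
    return CM_COEF_MG * np.asarray(bd, dtype=float) ** CM_EXP * 1e-3


def bd_from_cm(cm):
    """Bell diameter (cm) from carbon mass (g C) — closed-form inverse."""
    _check_positive(cm, "carbon mass")
    return (np.asarray(cm, dtype=float) * 1e3 / CM_COEF_MG) ** (1.0 / CM_EXP)


def wm_from_cm(cm):
    """Wet mass (g) from carbon mass (g C), via the bell diameter."""
    return wm_from_bd(bd_from_cm(cm))
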