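"""Individual carbon-budget model of *Pelagia noctiluca*.

A zero-dimensional bioenergetic model tracks the carbon mass CM (g C) of a
single jellyfish forced by temperature T (degC) and prey concentration F
(gC.L-1).  Seven processes are resolved, all in gC.d-1 unless noted:

* predation     P  = p_max * CM^b_p * t_10^T / (F + k_p)
* ingestion     I  = P * F
* assimilation  A  = I * (1 - a_max * F / (F + k_a))
* respiration   R  = R_o * M^b_r * t_10^T   (umolO2.d-1; M is wet mass by
                     default), converted to carbon via beta (J/umolO2) and
                     alpha (gC/J)
* excretion     Ex = R_C * c_e
* reproduction  Re = (a_re * M^b_re) * W_e * c_re * spn, gated on sexual
                     maturity (bell diameter >= 4 cm); the power law counts
                     eggs per spawn
* egestion      Eg = I - A

Net growth dG = A - (R_C + Ex + Re) closes the budget; egested carbon is
the mucus/fecal vector of downstream particulate export.  Diel vertical
migration between the warm surface and the cold deep layer is represented
by evaluating every rate at both temperatures and averaging (equal 12 h
weighting).  Integration is forward Euler at the forcing resolution
(daily by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcing import ForcingSeries
from .morphometry import bd_from_cm, cm_from_bd, wm_from_cm
from .params import ParameterSet

__all__ = [
    "JellyfishState",
    "FluxBreakdown",
    "Trajectory",
    "predation",
    "ingestion",
    "assimilation",
    "respiration",
    "excretion",
    "reproduction",
    "flux_breakdown",
    "step",
    "simulate",
    "simulate_ensemble",
]

FLUX_NAMES = ("P", "I", "A", "R_O2", "R_C", "Ex", "Re", "Eg", "dG")


@dataclass(frozen=True)
class JellyfishState:
    """Instantaneous organism state; bd and wm are derived from cm."""

    cm: float  # g C
    bd: float  # cm
    wm: float  # g

    @classmethod
    def from_bd(cls, bd: float) -> "JellyfishState":
        cm = float(cm_from_bd(bd))
        return cls(cm=cm, bd=float(bd), wm=float(wm_from_cm(cm)))

    @classmethod
    def from_cm(cls, cm: float) -> "JellyfishState":
        return cls(cm=float(cm), bd=float(bd_from_cm(cm)), wm=float(wm_from_cm(cm)))


@dataclass(frozen=True)
class FluxBreakdown:
    """Per-process carbon fluxes for one model step (daily rates)."""

    P: float  # predation, d-1 scaling (per unit prey concentration)
    I: float  # ingestion, gC.d-1
    A: float  # assimilation, gC.d-1
    R_O2: float  # respiration, umolO2.d-1
    R_C: float  # respiration, gC.d-1
    Ex: float  # excretion, gC.d-1
    Re: float  # reproduction, gC.d-1
    Eg: float  # egestion, gC.d-1
    dG: float  # net growth, gC.d-1


# ---------------------------------------------------------------------------
# process rates (scalar- and array-compatible)
# ---------------------------------------------------------------------------

def predation(cm, T, F, params: ParameterSet, *, p_max=None, k_p=None):
    """Predation scaling P (Michaelis-Menten in F; ingestion is P*F)."""
    p_max = params.p_max if p_max is None else p_max
    k_p = params.k_p if k_p is None else k_p
    denom = np.asarray(F, dtype=float) + k_p
    if np.any(denom <= 0):
        raise ValueError("F + k_p must be strictly positive")
    return p_max * np.asarray(cm, dtype=float) ** params.b_p \
        * params.t10_predation ** np.asarray(T, dtype=float) / denom


def ingestion(P, F):
    """Ingestion I = P * F (gC.d-1)."""
    return np.asarray(P, dtype=float) * np.asarray(F, dtype=float)


def assimilation(I, F, params: ParameterSet, *, a_max=None, k_a=None):
    """Assimilated fraction of ingestion; the fraction declines with F."""
    a_max = params.a_max if a_max is None else a_max
    k_a = params.k_a if k_a is None else k_a
    F = np.asarray(F, dtype=float)
    frac = np.where(F > 0, a_max * F / (F + k_a), 0.0)
    return np.asarray(I, dtype=float) * (1.0 - frac)


def respiration(mass, T, params: ParameterSet):
    """Respiration on the configured mass basis.

    Returns ``(R_O2, R_C)``: the oxygen consumption (umolO2.d-1) and its
    carbon equivalent (gC.d-1) obtained by chaining the oxygen->energy
    (beta) and energy->carbon (alpha) conversion factors.
    """
    if np.any(np.asarray(mass) <= 0):
        raise ValueError("mass must be strictly positive")
    R_O2 = params.R_o * np.asarray(mass, dtype=float) ** params.b_r \
        * params.t10_respiration ** np.asarray(T, dtype=float)
    return R_O2, R_O2 * params.beta * params.alpha


def excretion(R_C, c_e):
    """Excretion as a proportion of the carbon respiration rate."""
    return np.asarray(R_C, dtype=float) * c_e


def reproduction(cm, bd, params: ParameterSet, *, c_re=None, spn=None, wm=None):
    """Reproductive carbon loss (eggs plus mucus), zero below maturity.

    The egg-count power law a_re * M^b_re is evaluated on the configured
    mass basis (wet mass in g by default; see docs/methods.md).
    """
    c_re = params.c_re if c_re is None else c_re
    spn = params.spn if spn is None else spn
    cm = np.asarray(cm, dtype=float)
    bd = np.asarray(bd, dtype=float)
    if params.reproduction_mass_basis == "wm":
        mass = wm_from_cm(cm) if wm is None else np.asarray(wm, dtype=float)
    elif params.reproduction_mass_basis == "cm_mg":
        mass = cm * 1e3
    else:  # 'cm_g'
        mass = cm
    eggs = params.a_re * mass ** params.b_re
    mature = bd >= params.maturity_bd
    return np.where(mature, eggs * params.W_e * c_re * spn, 0.0)


def _fluxes_at_T(cm, bd, wm, T, F, params: ParameterSet, ov: dict):
    """All process rates at a single temperature (dict of arrays)."""
    P = predation(cm, T, F, params,
                  p_max=ov.get("p_max"), k_p=ov.get("k_p"))
    I = ingestion(P, F)
    A = assimilation(I, F, params, a_max=ov.get("a_max"), k_a=ov.get("k_a"))
    resp_mass = wm if params.respiration_mass_basis == "wm" else cm
    R_O2, R_C = respiration(resp_mass, T, params)
    c_e = ov.get("c_e", params.c_e)
    Ex = excretion(R_C, c_e)
    Re = reproduction(cm, bd, params, c_re=ov.get("c_re"), spn=ov.get("spn"),
                      wm=wm)
    Eg = I - A
    dG = A - (R_C + Ex + Re)
    return {"P": P, "I": I, "A": A, "R_O2": R_O2, "R_C": R_C,
            "Ex": Ex, "Re": Re, "Eg": Eg, "dG": dG}


def flux_breakdown(cm, T_surface, T_deep, F, params: ParameterSet,
                   overrides: dict | None = None) -> dict:
    """Daily fluxes, averaging each rate over the day/night temperatures.

    ``T_deep`` may be NaN (no vertical migration), in which case rates are
    evaluated at the surface temperature only.  ``overrides`` optionally
    replaces searched parameters with per-draw arrays (ensemble use).
    """
    ov = overrides or {}
    bd = bd_from_cm(cm)
    wm = wm_from_cm(cm)
    day = _fluxes_at_T(cm, bd, wm, T_surface, F, params, ov)
    T_deep_arr = np.asarray(T_deep, dtype=float)
    if np.all(np.isnan(T_deep_arr)):
        return day
    night = _fluxes_at_T(cm, bd, wm, np.where(np.isnan(T_deep_arr), T_surface,
                                              T_deep_arr), F, params, ov)
    return {k: 0.5 * (day[k] + night[k]) for k in day}


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def step(state: JellyfishState, t_surface: float, F: float,
         params: ParameterSet, dt: float,
         t_deep: float = float("nan")):
    """One forward-Euler step of length ``dt`` (days).

    Returns ``(new_state, fluxes)``; ``new_state`` is None when the update
    would exhaust the organism (cm' <= 0), which callers must treat as an
    explicit trajectory termination.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    fx = flux_breakdown(state.cm, t_surface, t_deep, F, params)
    fluxes = FluxBreakdown(**{k: float(np.asarray(v)) for k, v in fx.items()})
    cm_next = state.cm + fluxes.dG * dt
    if cm_next <= 0:
        return None, fluxes
    return JellyfishState.from_cm(cm_next), fluxes


@dataclass
class Trajectory:
    """Simulated daily organism states plus the per-process flux breakdown.

    ``status`` is 'complete' when the forcing was integrated to its end and
    'exhausted' when carbon mass would have gone non-positive, in which
    case the trajectory is truncated at the last viable record.
    """

    t: np.ndarray
    cm: np.ndarray
    bd: np.ndarray
    wm: np.ndarray
    fluxes: dict
    status: str = "complete"

    def __len__(self) -> int:
        return len(self.t)

    def variable(self, name: str) -> np.ndarray:
        if name not in ("cm", "bd", "wm"):
            raise ValueError(f"unknown trajectory variable {name!r}")
        return getattr(self, name)

    def values_at(self, times, variable: str = "bd") -> np.ndarray:
        """Linear interpolation of a state variable at arbitrary times.

        Times beyond the (possibly truncated) trajectory end yield NaN.
        """
        times = np.asarray(times, dtype=float)
        vals = np.interp(times, self.t, self.variable(variable))
        vals = np.where(
            (times < self.t[0] - 1e-9) | (times > self.t[-1] + 1e-9),
            np.nan, vals)
        return vals

    def to_frame(self) -> pd.DataFrame:
        data = {"t_day": self.t, "cm_gC": self.cm, "bd_cm": self.bd,
                "wm_g": self.wm}
        for k in FLUX_NAMES:
            data[k] = self.fluxes[k]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(initial_bd: float, forcing: ForcingSeries, params: ParameterSet,
             ) -> Trajectory:
    """Integrate the carbon budget over a forcing series.

    One record is produced per forcing time; fluxes at record k are the
    daily rates evaluated at state k, and carbon mass obeys
    cm[k+1] = cm[k] + dG[k] * (t[k+1] - t[k]).
    """
    n = len(forcing)
    state = JellyfishState.from_bd(initial_bd)
    t_out, cm, bd, wm = [], [], [], []
    fx_out = {k: [] for k in FLUX_NAMES}
    status = "complete"
    for k in range(n):
        fx = flux_breakdown(state.cm, forcing.T_surface[k], forcing.T_deep[k],
                            forcing.F[k], params)
        t_out.append(forcing.t[k])
        cm.append(state.cm)
        bd.append(state.bd)
        wm.append(state.wm)
        for name in FLUX_NAMES:
            fx_out[name].append(float(np.asarray(fx[name])))
        if k < n - 1:
            dt = forcing.t[k + 1] - forcing.t[k]
            cm_next = state.cm + fx_out["dG"][-1] * dt
            if cm_next <= 0:
                status = "exhausted"
                break
            state = JellyfishState.from_cm(cm_next)
    return Trajectory(
        t=np.asarray(t_out), cm=np.asarray(cm), bd=np.asarray(bd),
        wm=np.asarray(wm), fluxes={k: np.asarray(v) for k, v in fx_out.items()},
        status=status)


def simulate_ensemble(initial_cm, forcing: ForcingSeries,
                      params: ParameterSet, overrides: dict | None = None,
                      F_draws=None):
    """Vectorized integration of many parameter draws at once.

    Parameters
    ----------
    initial_cm : array (m,)
        Initial carbon mass per draw.
    overrides : dict of array (m,), optional
        Per-draw values for searched parameters (p_max, k_p, a_max, k_a,
        c_re, spn, c_e).
    F_draws : array (m,), optional
        Per-draw constant prey concentration replacing the forcing's F
        column (laboratory feeding scenarios where F_lab is calibrated).

    Returns
    -------
    cm : array (m, n)
        Carbon mass per draw and forcing time; NaN after exhaustion.
    alive : array (m, n) of bool
        False from the first time the draw's carbon mass went non-positive.

    Elementwise identical to :func:`simulate` run per draw.
    """
    initial_cm = np.asarray(initial_cm, dtype=float)
    m, n = len(initial_cm), len(forcing)
    ov = overrides or {}
    cm = np.full((m, n), np.nan)
    alive = np.zeros((m, n), dtype=bool)
    cur = initial_cm.copy()
    ok = cur > 0
    for k in range(n):
        cm[ok, k] = cur[ok]
        alive[:, k] = ok
        if k == n - 1 or not ok.any():
            break
        F_k = F_draws if F_draws is not None else forcing.F[k]
        with np.errstate(invalid="ignore"):
            fx = flux_breakdown(np.where(ok, cur, 1.0), forcing.T_surface[k],
                                forcing.T_deep[k], F_k, params, ov)
            dt = forcing.t[k + 1] - forcing.t[k]
            nxt = cur + np.asarray(fx["dG"]) * dt
        ok = ok & (nxt > 0)
        cur = nxt
    return cm, alive
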