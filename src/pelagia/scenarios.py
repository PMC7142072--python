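"""Calibration scenarios: laboratory degrowth/growth and in-situ climatology.

The model is confronted with three settings at once:

* **lab degrowth** — starved animals at a constant 18 degC (no prey);
* **lab growth** — animals fed ad libitum at 18 degC, the effective prey
  concentration F_lab being itself a calibrated quantity;
* **in situ** — an annual climatology of sea surface temperature and
  zooplankton carbon, with rates averaged between the surface and the
  13 degC bathypelagic layer visited during the nightly vertical
  migration, compared against adult bell-diameter observations.

A candidate's combined error sums, over scenarios, the fraction of its
random simulations outside the tunnel plus the mean per-observation-time
normalized distance to the tunnel — both per-point quantities, so a
densely sampled condition cannot dominate the compromise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcing import ForcingSeries
from .tunnels import TunnelSet

__all__ = [
    "Scenario",
    "make_lab_degrowth",
    "make_lab_growth",
    "make_insitu",
    "combined_error",
    "rank_by_combined_error",
    "LAB_TEMPERATURE_C",
    "DEEP_TEMPERATURE_C",
]

LAB_TEMPERATURE_C = 18.0
DEEP_TEMPERATURE_C = 13.0


@dataclass
class Scenario:
    """One calibration setting: forcing, observation tunnel, and weight."""

    name: str
    forcing: ForcingSeries
    tunnel: TunnelSet | None
    variable: str = "bd"
    weight: float = 1.0
    initial_bd: float = 4.5  # cm; surrogate value, not an observed one
    f_lab_driven: bool = False  # replace forcing F with each draw's F_lab

    def __post_init__(self):
        if self.initial_bd <= 0:
            raise ValueError("initial_bd must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.tunnel is not None:
            lo, hi = self.forcing.t[0], self.forcing.t[-1]
            if self.tunnel.times[0] < lo - 1e-9 or \
                    self.tunnel.times[-1] > hi + 1e-9:
                raise ValueError("forcing does not span the tunnel times")

    def with_tunnel(self, tunnel: TunnelSet) -> "Scenario":
        return Scenario(self.name, self.forcing, tunnel, self.variable,
                        self.weight, self.initial_bd, self.f_lab_driven)


def make_lab_degrowth(duration: float = 30.0, initial_bd: float = 4.5,
                      tunnels: TunnelSet | None = None,
                      weight: float = 1.0) -> Scenario:
    """Starved laboratory scenario: constant 18 degC, zero prey."""
    forcing = ForcingSeries.constant(duration, LAB_TEMPERATURE_C, 0.0)
    return Scenario("degrowth", forcing, tunnels, "bd", weight, initial_bd)


def make_lab_growth(duration: float = 30.0, initial_bd: float = 1.0,
                    F_lab: float = 0.9e-5,
                    tunnels: TunnelSet | None = None,
                    weight: float = 1.0) -> Scenario:
    """Fed laboratory scenario: constant 18 degC at prey level F_lab.

    F_lab is a searched quantity: during calibration each draw's F_lab
    replaces the forcing's constant prey column.
    """
    if F_lab < 0:
        raise ValueError("F_lab must be non-negative")
    forcing = ForcingSeries.constant(duration, LAB_TEMPERATURE_C, F_lab)
    return Scenario("growth", forcing, tunnels, "bd", weight, initial_bd,
                    f_lab_driven=True)


def make_insitu(climatology: ForcingSeries,
                tunnels: TunnelSet | None = None,
                initial_bd: float = 3.0,
                weight: float = 1.0) -> Scenario:
    """Annual in-situ scenario with diel-migration temperature averaging.

    The climatology is interpolated to daily resolution if coarser, and
    the deep temperature is pinned at the 13 degC bathypelagic value.
    """
    t = climatology.t
    if np.any(np.diff(t) > 1.0 + 1e-9):
        daily = np.arange(t[0], t[-1] + 0.5)
        climatology = ForcingSeries(
            daily,
            np.interp(daily, t, climatology.T_surface),
            np.interp(daily, t, climatology.F),
        )
    forcing = ForcingSeries(
        climatology.t, climatology.T_surface, climatology.F,
        np.full_like(climatology.t, DEEP_TEMPERATURE_C))
    return Scenario("insitu", forcing, tunnels, "bd", weight, initial_bd)


def combined_error(scores: dict, dists: dict, weights: dict | None = None
                   ) -> float:
    """Weighted lab + in-situ error for one candidate.

    ``scores[s]`` is the fraction of that candidate's simulations outside
    scenario s's tunnel and ``dists[s]`` the mean normalized distance to
    it (a mean over observation times, i.e. already per-point normalized).
    Equal weights by default.
    """
    err = 0.0
    for name in scores:
        w = 1.0 if weights is None else weights.get(name, 1.0)
        err += w * (scores[name] + dists[name])
    return err


def rank_by_combined_error(results, weights: dict | None = None):
    """Sort retained evaluation results by ascending combined error."""
    retained = [r for r in results if r.retained]
    return sorted(retained,
                  key=lambda r: combined_error(r.score, r.dist, weights))
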