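"""Particulate organic carbon (POC) export from jellyfish egestion.

Egested mucus sinks fast (median 751 m.d-1) and is remineralized slowly
(0.034 d-1), so only a small fraction of its carbon is lost before
reaching the 200 m export horizon — about 1% at the measured rates.
Scaling the per-individual egestion flux by areal abundance and the
surviving fraction gives the jellyfish contribution to the POC flux at
depth, expressed as a percentage of a reference sediment-trap flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MucusProperties",
    "AbundanceStats",
    "POC_REFERENCE_MG_M2_D",
    "loss_fraction",
    "areal_export",
    "percent_poc",
    "export_table",
]

EXPORT_DEPTH_M = 200.0


@dataclass(frozen=True)
class MucusProperties:
    """Sinking speed w (m.d-1) and remineralization rate k (d-1)."""

    w: float = 751.0
    k: float = 0.034

    def __post_init__(self):
        if self.w <= 0:
            raise ValueError("sinking speed must be positive")
        if self.k < 0:
            raise ValueError("remineralization rate must be non-negative")


@dataclass(frozen=True)
class AbundanceStats:
    """Areal abundance quantiles (individuals.m-2).

    Defaults are the 2013 ship-transect summary for the Ligurian Sea.
    """

    median: float = 0.018
    q1: float = 0.003
    q3: float = 0.1
    min: float = 0.0
    max: float = 3.45

    def __post_init__(self):
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValueError("abundance quantiles must be ordered")

    def as_dict(self) -> dict:
        return {"min": self.min, "q1": self.q1, "median": self.median,
                "q3": self.q3, "max": self.max}


#: reference monthly total POC flux at 200 m (mgC.m-2.d-1), DYFAMED
#: sediment-trap climatology extremes.
POC_REFERENCE_MG_M2_D = {"February": 14.01, "April": 13.55, "July": 1.53}


def loss_fraction(w: float, k: float, z: float = EXPORT_DEPTH_M,
                  mode: str = "exponential") -> float:
    """Fraction of mucus carbon remineralized while sinking to depth z.

    The default exponential attenuation 1 - exp(-k*z/w) treats the
    remineralization as first-order over the transit time z/w; the linear
    variant k*z/w is the same quantity to first order.  Both are ~0.9% at
    the measured w, k and the 200 m horizon.
    """
    if w <= 0:
        raise ValueError("sinking speed must be positive")
    if z < 0:
        raise ValueError("depth must be non-negative")
    if k < 0:
        raise ValueError("remineralization rate must be non-negative")
    transit_losses = k * z / w
    if mode == "exponential":
        return float(1.0 - np.exp(-transit_losses))
    if mode == "linear":
        return float(min(transit_losses, 1.0))
    raise ValueError("mode must be 'exponential' or 'linear'")


def areal_export(Eg, abundance, w: float = 751.0, k: float = 0.034,
                 z: float = EXPORT_DEPTH_M, mode: str = "exponential"):
    """Areal mucus carbon flux surviving to depth z (mgC.m-2.d-1).

    ``Eg`` is the per-individual egestion (gC.ind-1.d-1, scalar or
    series); ``abundance`` in ind.m-2.  Jointly linear in both.
    """
    Eg = np.asarray(Eg, dtype=float)
    if np.any(Eg < 0) or np.any(np.asarray(abundance) < 0):
        raise ValueError("egestion and abundance must be non-negative")
    surviving = 1.0 - loss_fraction(w, k, z, mode)
    return Eg * np.asarray(abundance, dtype=float) * surviving * 1e3


def percent_poc(flux_jelly, reference: float):
    """Jellyfish share of the total POC flux at depth, in percent."""
    if reference <= 0:
        raise ValueError("reference POC flux must be positive")
    return 100.0 * np.asarray(flux_jelly, dtype=float) / reference


def export_table(t_days, Eg_series, abundance: AbundanceStats | None = None,
                 mucus: MucusProperties | None = None,
                 z: float = EXPORT_DEPTH_M,
                 poc_reference: dict | None = None) -> pd.DataFrame:
    """Monthly export flux and %POC per abundance quantile.

    ``Eg_series`` is a daily per-individual egestion series (gC.ind-1.d-1)
    over ``t_days`` (day of year); it is averaged per calendar month and
    combined with each abundance quantile.  Where a month has a reference
    total POC flux, the jellyfish percentage contribution is added.
    """
    abundance = abundance or AbundanceStats()
    mucus = mucus or MucusProperties()
    month_edges = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    month_names = ["January", "February", "March", "April", "May", "June",
                   "July", "August", "September", "October", "November",
                   "December"]
    t_days = np.asarray(t_days, dtype=float)
    Eg_series = np.asarray(Eg_series, dtype=float)
    poc_reference = POC_REFERENCE_MG_M2_D if poc_reference is None \
        else poc_reference
    rows = []
    for i, name in enumerate(month_names):
        sel = (t_days >= month_edges[i]) & (t_days < month_edges[i + 1])
        if not sel.any():
            continue
        eg = float(Eg_series[sel].mean())
        row = {"month": name, "Eg_gC_ind_d": eg}
        for q, a in abundance.as_dict().items():
            flux = float(areal_export(eg, a, mucus.w, mucus.k, z))
            row[f"flux_{q}_mgC_m2_d"] = flux
            if name in poc_reference:
                row[f"pct_poc_{q}"] = float(
                    percent_poc(flux, poc_reference[name]))
        rows.append(row)
    return pd.DataFrame(rows)
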