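#!/usr/bin/env python
"""Spearman correlogram of the accepted parameter vectors.

Loads the full calibration table (step 03), augments each accepted
candidate with its median-abundance annual POC export from an in-situ
simulation at the candidate's central values, and writes the Spearman
rank-correlation matrix between parameters, Match, per-scenario scores
and the export.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pelagia import ParameterSet, simulate
from pelagia.export import areal_export
from pelagia.scenarios import make_insitu
from pelagia.smce import correlogram
from pelagia.synthetic import SyntheticSpec, synth_climatology

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

COLUMNS = ["k_p", "a_max", "k_a", "c_re", "spn", "c_e", "F_lab",
           "theta_hat", "score_growth", "score_insitu", "median_export"]


def median_export_for(row, forcing) -> float:
    params = ParameterSet().with_central(
        {k: row[k] for k in ("k_p", "a_max", "k_a", "c_re", "spn", "c_e")})
    traj = simulate(3.0, forcing, params)
    eg = np.clip(traj.fluxes["Eg"], 0.0, None)
    return float(np.median(areal_export(eg, 0.018)))


def main() -> None:
    table = pd.read_csv(SCRATCH / "calibration_full.tsv", sep="\t")
    accepted = table[table["retained"]].copy()
    if len(accepted) < 3:
        raise SystemExit("fewer than 3 accepted vectors; rerun step 03")
    forcing = make_insitu(synth_climatology(SyntheticSpec())).forcing
    accepted["median_export"] = [median_export_for(row, forcing)
                                 for _, row in accepted.iterrows()]
    corr = correlogram(accepted, [c for c in COLUMNS
                                  if c in accepted.columns])
    out = RESULTS / "correlogram.csv"
    corr.to_csv(out)
    print(f"correlogram over {len(accepted)} accepted vectors")
    with pd.option_context("display.width", 120):
        print(corr.round(2).to_string())
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
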