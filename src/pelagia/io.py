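"""Shared file I/O: study directories, results tables, run manifests.

Everything on disk is plain CSV/TSV (UTF-8, '.' decimal, headers
mandatory) plus small JSON manifests recording the configuration, seeds
and produced files, so deterministic stages reproduce bit-for-bit.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd

from .forcing import ForcingSeries
from .scenarios import Scenario
from .tunnels import TunnelSet

__all__ = [
    "write_study",
    "read_study",
    "write_results_tsv",
    "RunManifest",
]


class RunManifest:
    """Record of one pipeline run: config snapshot, seeds, outputs."""

    def __init__(self, command: str, config: dict | None = None,
                 seed: int | None = None):
        self.data = {
            "command": command,
            "config": config or {},
            "seed": seed,
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "timings_s": {},
            "outputs": [],
        }
        self._t0 = time.perf_counter()

    def add_output(self, path) -> None:
        self.data["outputs"].append(str(path))

    def time_stage(self, name: str) -> None:
        self.data["timings_s"][name] = round(time.perf_counter() - self._t0, 3)
        self._t0 = time.perf_counter()

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.data, indent=2) + "\n")


def write_study(directory, scenarios: list[Scenario],
                extra_manifest: dict | None = None) -> None:
    """Materialize a study directory: per-scenario forcing + tunnel CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"scenarios": []}
    for sc in scenarios:
        fpath = directory / f"{sc.name}_forcing.csv"
        sc.forcing.to_csv(fpath)
        entry = {
            "name": sc.name,
            "forcing": fpath.name,
            "variable": sc.variable,
            "weight": sc.weight,
            "initial_bd_cm": sc.initial_bd,
            "f_lab_driven": sc.f_lab_driven,
        }
        if sc.tunnel is not None:
            tpath = directory / f"{sc.name}_tunnel.csv"
            sc.tunnel.to_csv(tpath)
            entry["tunnel"] = tpath.name
        manifest["scenarios"].append(entry)
    if extra_manifest:
        manifest.update(extra_manifest)
    (directory / "study.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_study(directory) -> list[Scenario]:
    """Load a study directory written by :func:`write_study`."""
    directory = Path(directory)
    manifest = json.loads((directory / "study.json").read_text())
    scenarios = []
    for entry in manifest["scenarios"]:
        forcing = ForcingSeries.from_csv(directory / entry["forcing"])
        tunnel = TunnelSet.from_csv(directory / entry["tunnel"]) \
            if "tunnel" in entry else None
        scenarios.append(Scenario(
            name=entry["name"], forcing=forcing, tunnel=tunnel,
            variable=entry["variable"], weight=entry["weight"],
            initial_bd=entry["initial_bd_cm"],
            f_lab_driven=entry["f_lab_driven"]))
    return scenarios


def write_results_tsv(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
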