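"""Observation tunnels: time-indexed acceptance bands on model output.

A tunnel encodes, at each observation time, the range of acceptable values
of one trajectory variable (bell diameter or carbon mass), built from
observation replicates as mean +/- k * std.  A simulation "matches" the
data when it stays inside the band at every observation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TunnelSet"]


@dataclass
class TunnelSet:
    """Acceptance bands over time for one trajectory variable."""

    times: np.ndarray  # days, sorted
    lower: np.ndarray
    upper: np.ndarray
    variable: str = "bd"  # 'bd' (cm) or 'cm' (g C)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.times) == len(self.lower) == len(self.upper)):
            raise ValueError("tunnel arrays must have equal length")
        if len(self.times) == 0:
            raise ValueError("tunnel is empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("tunnel times must be strictly increasing")
        if np.any(self.lower > self.upper):
            raise ValueError("tunnel lower bound exceeds upper bound")
        if self.variable not in ("bd", "cm"):
            raise ValueError("tunnel variable must be 'bd' or 'cm'")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def midline(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    @property
    def half_width(self) -> np.ndarray:
        return 0.5 * (self.upper - self.lower)

    def widen(self, factor: float) -> "TunnelSet":
        """Scale the band half-width about the midline by ``factor``."""
        mid, hw = self.midline, self.half_width
        return TunnelSet(self.times.copy(), mid - factor * hw,
                         mid + factor * hw, self.variable)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_day": self.times, "lower": self.lower, "upper": self.upper,
            "variable": self.variable})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TunnelSet":
        df = pd.read_csv(path)
        for col in ("t_day", "lower", "upper", "variable"):
            if col not in df.columns:
                raise ValueError(f"tunnel CSV is missing column {col!r}")
        var = df["variable"].iloc[0]
        return cls(df["t_day"].to_numpy(), df["lower"].to_numpy(),
                   df["upper"].to_numpy(), str(var))
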