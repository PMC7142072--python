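"""Environmental forcing: daily temperature and prey concentration series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ForcingSeries"]

FORCING_COLUMNS = ["t_day", "T_surface_C", "T_deep_C", "F_gC_per_L"]


@dataclass
class ForcingSeries:
    """Daily model forcing.

    ``T_deep`` is the temperature experienced at depth during the night
    phase of the diel vertical migration; where it is NaN the model uses
    the surface temperature alone.  Prey concentration ``F`` is in gC.L-1.
    """

    t: np.ndarray
    T_surface: np.ndarray
    F: np.ndarray
    T_deep: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.T_surface = np.asarray(self.T_surface, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.T_deep is None:
            self.T_deep = np.full_like(self.t, np.nan)
        else:
            self.T_deep = np.asarray(self.T_deep, dtype=float)
        n = len(self.t)
        if n == 0:
            raise ValueError("forcing series is empty")
        for arr, name in (
            (self.T_surface, "T_surface"),
            (self.F, "F"),
            (self.T_deep, "T_deep"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length does not match t")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("forcing times must be strictly increasing")
        if np.any(self.F < 0):
            raise ValueError("prey concentration must be non-negative")

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def constant(
        cls,
        duration: float,
        T: float,
        F: float,
        T_deep: float | None = None,
        dt: float = 1.0,
    ) -> "ForcingSeries":
        """Constant-condition forcing covering [0, duration] at step dt."""
        t = np.arange(0.0, duration + 0.5 * dt, dt)
        deep = None if T_deep is None else np.full_like(t, float(T_deep))
        return cls(t, np.full_like(t, float(T)), np.full_like(t, float(F)), deep)

    def refine(self, substeps: int) -> "ForcingSeries":
        """Linearly interpolated copy with ``substeps`` steps per interval.

        Used for integrator-convergence checks.
        """
        if substeps < 1:
            raise ValueError("substeps must be >= 1")
        t = np.linspace(self.t[0], self.t[-1], (len(self.t) - 1) * substeps + 1)
        interp = lambda y: np.interp(t, self.t, y)  # noqa: E731
        deep = interp(self.T_deep) if not np.all(np.isnan(self.T_deep)) else None
        return ForcingSeries(t, interp(self.T_surface), interp(self.F), deep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_day": self.t,
                "T_surface_C": self.T_surface,
                "T_deep_C": self.T_deep,
                "F_gC_per_L": self.F,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ForcingSeries":
        df = pd.read_csv(path)
        missing = [c for c in FORCING_COLUMNS if c not in df.columns and c != "T_deep_C"]
        if missing:
            raise ValueError(f"forcing CSV is missing columns: {missing}")
        deep = df["T_deep_C"].to_numpy() if "T_deep_C" in df.columns else None
        return cls(
            df["t_day"].to_numpy(),
            df["T_surface_C"].to_numpy(),
            df["F_gC_per_L"].to_numpy(),
            deep,
        )
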