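"""Time-course containers: measured signal and gadolinium concentration.

Times are stored in seconds at the I/O boundary; tracer-kinetic code works
in minutes (K^trans in min⁻¹).  :data:`SECONDS_PER_MINUTE` is the single
conversion constant used across the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SECONDS_PER_MINUTE", "SignalCurve", "ConcentrationCurve"]

SECONDS_PER_MINUTE = 60.0


def _validated_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t


@dataclass
class SignalCurve:
    """Measured signal intensity vs time for one voxel or ROI.

    ``n_baseline`` counts the leading pre-injection dynamics used to fix
    the signal scale when converting to concentration.
    """

    times: np.ndarray  # seconds
    signal: np.ndarray  # arbitrary units
    n_baseline: int = 1

    def __post_init__(self) -> None:
        self.times = _validated_times(self.times)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != self.times.shape:
            raise ValueError("signal and times must have the same length")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if not (1 <= self.n_baseline <= len(self.times)):
            raise ValueError("n_baseline must be in [1, len(times)]")

    def baseline_mean(self) -> float:
        return float(np.mean(self.signal[: self.n_baseline]))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.signal}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, n_baseline: int = 1) -> "SignalCurve":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["value"].to_numpy(), n_baseline=n_baseline)


@dataclass
class ConcentrationCurve:
    """Gadolinium concentration (mM) vs time (s) for a voxel, ROI or lumen.

    ``clipped`` flags samples whose signal fell outside the invertible
    range of the signal equation and was clamped to the bracket edge.
    """

    times: np.ndarray  # seconds
    concentration: np.ndarray  # mmol/L
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = _validated_times(self.times)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.concentration.shape != self.times.shape:
            raise ValueError("concentration and times must have the same length")
        if not np.all(np.isfinite(self.concentration)):
            raise ValueError("concentration must be finite")
        if self.clipped is None:
            self.clipped = np.zeros(self.times.shape, dtype=bool)
        else:
            self.clipped = np.asarray(self.clipped, dtype=bool)

    @property
    def times_min(self) -> np.ndarray:
        """Sample times in minutes (kinetics units)."""
        return self.times / SECONDS_PER_MINUTE

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.concentration}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConcentrationCurve":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["value"].to_numpy())
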