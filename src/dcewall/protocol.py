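"""Acquisition protocol for the dynamic spoiled-gradient-echo series.

The protocol bundles everything needed to map gadolinium concentration to
signal and back: sequence timing (TR, TE, flip angle), the dynamic sampling
scheme (number of dynamics, nominal inter-dynamic interval, injection
dynamic), fixed pre-contrast relaxation times, and contrast-agent
relaxivities.  Defaults reproduce a 1.5 T abdominal vessel-wall protocol:
25 dynamics at ~18 s, TR/TE = 13/1.5 ms, flip 35°, contrast injected at the
start of the sixth dynamic, pre-contrast T1/T2 = 900/30 ms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

__all__ = ["AcquisitionProtocol", "baseline_window"]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Dynamic SPGR acquisition parameters.

    Parameters
    ----------
    tr, te : float
        Repetition and echo time in seconds.
    flip_angle : float
        Excitation flip angle in degrees, in (0, 90).
    n_dynamics : int
        Number of dynamic phases acquired.
    nominal_interval : float
        Nominal time between consecutive dynamics in seconds.  Cardiac
        gating makes the realised interval vary; see ``timing_jitter_sd``.
    injection_dynamic : int
        1-based index of the dynamic at whose start the contrast injection
        begins.  Dynamics before it form the pre-contrast baseline.
    t1_pre, t2_pre : float
        Fixed pre-contrast tissue relaxation times in seconds.
    r1, r2 : float
        Longitudinal / transverse contrast-agent relaxivities in
        L·mmol⁻¹·s⁻¹.
    timing_jitter_sd : float
        Standard deviation (seconds) of the zero-mean Gaussian jitter on
        each inter-dynamic interval.
    """

    tr: float = 0.013
    te: float = 0.0015
    flip_angle: float = 35.0
    n_dynamics: int = 25
    nominal_interval: float = 18.0
    injection_dynamic: int = 6
    t1_pre: float = 0.900
    t2_pre: float = 0.030
    r1: float = 5.2
    r2: float = 6.1
    timing_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tr > self.te > 0):
            raise ValueError(f"require tr > te > 0, got tr={self.tr}, te={self.te}")
        if not (0 < self.flip_angle < 90):
            raise ValueError(f"flip_angle must be in (0, 90) degrees, got {self.flip_angle}")
        if not (self.n_dynamics >= self.injection_dynamic >= 2):
            raise ValueError(
                "require n_dynamics >= injection_dynamic >= 2, got "
                f"n_dynamics={self.n_dynamics}, injection_dynamic={self.injection_dynamic}"
            )
        if not (self.t1_pre > self.t2_pre > 0):
            raise ValueError(
                f"require t1_pre > t2_pre > 0, got t1_pre={self.t1_pre}, t2_pre={self.t2_pre}"
            )
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("relaxivities r1, r2 must be positive")
        if self.nominal_interval <= 0:
            raise ValueError("nominal_interval must be positive")
        if self.timing_jitter_sd < 0:
            raise ValueError("timing_jitter_sd must be non-negative")

    def baseline_window(self) -> tuple[int, int]:
        """Pre-contrast dynamic range as a 1-based inclusive ``(first, last)``."""
        return baseline_window(self)

    @property
    def n_baseline(self) -> int:
        return self.injection_dynamic - 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionProtocol":
        return cls(**json.loads(Path(path).read_text()))


def baseline_window(protocol: AcquisitionProtocol) -> tuple[int, int]:
    """Pre-contrast window: dynamics 1 .. injection_dynamic-1 (1-based, inclusive).

    With injection at the start of the sixth dynamic the baseline is
    dynamics 1–5.  A protocol with ``injection_dynamic < 2`` has no
    baseline and is rejected at construction time.
    """
    if protocol.injection_dynamic < 2:
        raise ValueError("no pre-contrast baseline: injection_dynamic must be >= 2")
    return (1, protocol.injection_dynamic - 1)
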