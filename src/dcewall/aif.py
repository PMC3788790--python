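"""Arterial input function (AIF) in the Parker functional form.

The blood-plasma concentration is modelled as two Gaussians plus a
sigmoid-modulated exponential washout, all shifted by a bolus-arrival
(onset) time t0:

    C_p(t) = Σ_{n=1,2} A_n/(σ_n√(2π)) · exp(−(t−t0−T_n)²/(2σ_n²))
             + α · exp(−β(t−t0)) / (1 + exp(−s(t−t0−τ))),         t ≥ t0
    C_p(t) = 0,                                                   t < t0

with amplitudes A_n in mM·min, centres T_n and widths σ_n in minutes, α in
mM, washout rate β and sigmoid steepness s in min⁻¹, and sigmoid centre τ
in minutes.

A population AIF for a slow (0.5 mL/s) injection ships as
:meth:`ParkerAif.population_slow_injection`: its Gaussians are broad
(σ ≥ 0.5 min) and low, giving the weak-to-absent first-pass peak seen with
slow injections; the parameter values are a documented stand-in, fully
overridable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .curves import SECONDS_PER_MINUTE, ConcentrationCurve
from .protocol import AcquisitionProtocol

__all__ = ["ParkerAif", "evaluate_aif", "fit_aif", "lumen_roi_curve"]

logger = logging.getLogger(__name__)

# Order of the free parameters during fitting (t0 is held fixed: the onset
# is a designed discontinuity and carries no useful least-squares gradient).
_FIT_FIELDS = ("a1", "t1", "sigma1", "a2", "t2", "sigma2", "alpha", "beta", "s", "tau")
_LOWER = np.array([0.0, 0.0, 0.01, 0.0, 0.0, 0.01, 0.0, 0.0, 0.05, 0.0])
_UPPER = np.array([20.0, 20.0, 10.0, 20.0, 20.0, 10.0, 10.0, 5.0, 1e4, 20.0])


@dataclass(frozen=True)
class ParkerAif:
    """Parker-form AIF parameters; evaluable at arbitrary times (minutes)."""

    a1: float = 0.40  # mM·min
    t1: float = 0.80  # min
    sigma1: float = 0.55  # min
    a2: float = 0.30
    t2: float = 1.80
    sigma2: float = 0.85
    alpha: float = 0.90  # mM
    beta: float = 0.16  # min^-1
    s: float = 3.5  # min^-1
    tau: float = 0.65  # min
    t0: float = 0.0  # min

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("Gaussian widths must be positive")
        if self.beta < 0:
            raise ValueError("washout rate beta must be non-negative")

    @classmethod
    def population_slow_injection(cls, t0: float = 0.0) -> "ParkerAif":
        """Default population AIF for a 0.5 mL/s venous injection."""
        return cls(t0=t0)

    def __call__(self, times_min) -> np.ndarray:
        return evaluate_aif(self, times_min)

    def as_curve(self, times_s) -> ConcentrationCurve:
        """Evaluate on a seconds grid, returning an I/O curve."""
        times_s = np.asarray(times_s, dtype=float)
        return ConcentrationCurve(times_s, evaluate_aif(self, times_s / SECONDS_PER_MINUTE))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParkerAif":
        return cls(**json.loads(Path(path).read_text()))


def evaluate_aif(model: ParkerAif, times_min) -> np.ndarray:
    """Evaluate C_p(t) in mM at times given in minutes; 0 before onset."""
    t = np.asarray(times_min, dtype=float)
    u = t - model.t0
    out = np.zeros_like(u)
    on = u >= 0.0
    uu = u[on]
    g1 = model.a1 / (model.sigma1 * np.sqrt(2 * np.pi)) * np.exp(
        -((uu - model.t1) ** 2) / (2 * model.sigma1**2)
    )
    g2 = model.a2 / (model.sigma2 * np.sqrt(2 * np.pi)) * np.exp(
        -((uu - model.t2) ** 2) / (2 * model.sigma2**2)
    )
    # sigmoid argument clipped to keep exp() finite for very steep s
    z = np.clip(-model.s * (uu - model.tau), -700.0, 700.0)
    washout = model.alpha * np.exp(-model.beta * uu) / (1.0 + np.exp(z))
    out[on] = g1 + g2 + washout
    return out


def _from_vector(x: np.ndarray, t0: float) -> ParkerAif:
    return ParkerAif(**dict(zip(_FIT_FIELDS, (float(v) for v in x))), t0=t0)


def _fit_single(
    curve: ConcentrationCurve, init: ParkerAif, max_nfev: int = 2000
) -> tuple[ParkerAif, float, bool]:
    """Nonlinear least squares of the Parker form to one curve."""
    t_min = curve.times_min
    y = curve.concentration
    x0 = np.array([getattr(init, f) for f in _FIT_FIELDS], dtype=float)
    x0 = np.clip(x0, _LOWER, _UPPER)

    def resid(x):
        return evaluate_aif(_from_vector(x, init.t0), t_min) - y

    res = least_squares(
        resid,
        x0,
        bounds=(_LOWER, _UPPER),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return _from_vector(res.x, init.t0), rms, bool(res.status > 0)


def fit_aif(
    lumen_curves: list[ConcentrationCurve],
    init: ParkerAif | None = None,
    grid_interval_s: float = 1.0,
    rms_tolerance: float | None = None,
) -> tuple[ParkerAif, list[dict]]:
    """Build a generalized AIF from one or more lumen concentration curves.

    Each curve is fitted individually in the Parker form; curves that fail
    to converge (or exceed ``rms_tolerance``, when given) are excluded with
    a warning.  The generalized AIF is the Parker form re-fitted to the
    pointwise mean of the individual fitted curves on a common
    ``grid_interval_s`` grid spanning the longest curve.

    Returns the generalized model and per-curve diagnostics
    (``{"rms_mm", "converged", "excluded", "model"}``).
    """
    if not lumen_curves:
        raise ValueError("need at least one lumen curve")
    init = init or ParkerAif.population_slow_injection()
    n_post = [int(np.sum(c.times_min >= init.t0)) for c in lumen_curves]
    if min(n_post) < 10:
        raise ValueError("each curve needs at least 10 post-onset samples")

    diagnostics: list[dict] = []
    kept: list[ParkerAif] = []
    for i, curve in enumerate(lumen_curves):
        model, rms, converged = _fit_single(curve, init)
        excluded = (not converged) or (rms_tolerance is not None and rms > rms_tolerance)
        if excluded:
            warnings.warn(
                f"AIF curve {i} excluded (converged={converged}, rms={rms:.4g} mM)",
                stacklevel=2,
            )
        else:
            kept.append(model)
        diagnostics.append(
            {"rms_mm": rms, "converged": converged, "excluded": excluded, "model": model}
        )
    if not kept:
        raise RuntimeError("no AIF curve could be fitted")

    if len(kept) == 1:
        return kept[0], diagnostics

    t_max_s = max(float(c.times[-1]) for c in lumen_curves)
    grid_s = np.arange(0.0, t_max_s + grid_interval_s, grid_interval_s)
    grid_min = grid_s / SECONDS_PER_MINUTE
    mean_curve = np.mean([evaluate_aif(m, grid_min) for m in kept], axis=0)
    pooled = ConcentrationCurve(grid_s, mean_curve)
    # warm-start the pooled fit from the mean of the kept parameter vectors
    mean_x = np.mean([[getattr(m, f) for f in _FIT_FIELDS] for m in kept], axis=0)
    pooled_init = _from_vector(mean_x, init.t0)
    generalized, rms, converged = _fit_single(pooled, pooled_init)
    logger.info("generalized AIF pooled-fit rms=%.4g mM (converged=%s)", rms, converged)
    return generalized, diagnostics


def lumen_roi_curve(series, roi_mask, protocol: AcquisitionProtocol) -> ConcentrationCurve:
    """Mean lumen signal over a circular ROI, converted to concentration.

    ``series`` is a :class:`~dcewall.synthetic.DynamicSeries`; ``roi_mask``
    a boolean mask on its spatial grid.
    """
    from .signal_model import signal_to_concentration
    from .curves import SignalCurve

    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != series.data.shape[:3]:
        raise ValueError("roi_mask shape must match the series spatial grid")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    mean_signal = series.data[roi_mask].mean(axis=0)
    curve = SignalCurve(series.times_s, mean_signal, n_baseline=protocol.n_baseline)
    return signal_to_concentration(curve, protocol)
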