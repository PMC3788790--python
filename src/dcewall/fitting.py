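"""Least-squares fitting of tracer-kinetic models to concentration curves.

The central object is :class:`PkCurveFit`, a scikit-learn style estimator:
``fit(X, y)`` takes sample times (minutes) and tissue concentration (mM)
and estimates the model parameters by bounded least squares; fitted
attributes carry the estimates, the relative fit error, and covariance
based relative parameter uncertainties.  The Patlak model is linear in its
parameters and is solved in closed form; Tofts and Extended Tofts use a
damped Gauss–Newton (Levenberg–Marquardt-type trust region) with analytic
Jacobians, with an undamped Gauss–Newton loop available for fidelity.

Module-level helpers (:func:`fit_curve`, :func:`fit_voxelwise`,
:func:`fit_roibased`) wrap the estimator for curve containers and 4-D
dynamic series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, lsq_linear
from sklearn.base import BaseEstimator, RegressorMixin

from .curves import ConcentrationCurve, SignalCurve
from .pk_models import (
    DEFAULT_GRID_INTERVAL_S,
    MODEL_PARAMS,
    MODELS,
    PkParams,
    forward_model,
    model_jacobian,
)
from .signal_model import signal_to_concentration

__all__ = [
    "PkCurveFit",
    "PkFitResult",
    "WallRoi",
    "fit_curve",
    "fit_voxelwise",
    "fit_roibased",
    "relative_fit_error",
    "parameter_uncertainty",
]

logger = logging.getLogger(__name__)

# Box constraints per parameter (fitting space)
_BOUNDS = {"ktrans": (0.0, 5.0), "vp": (0.0, 1.0), "ve": (1e-3, 1.0)}
_INIT = {"ktrans": 0.01, "vp": 0.01, "ve": 0.2}

#: threshold below which a parameter's relative uncertainty is undefined
_TINY_PARAM = 1e-12


def relative_fit_error(ct, ct_fit, normalization: str = "max") -> float:
    """Relative fit error in percent: 100·RMS(C_t − C_tfit)/N.

    ``normalization`` N is the peak measured concentration max|C_t|
    (default) or the mean of |C_t| (``"mean"``).  A curve that is zero
    everywhere has fit error 0 by convention.
    """
    ct = np.asarray(ct, dtype=float)
    ct_fit = np.asarray(ct_fit, dtype=float)
    if ct.shape != ct_fit.shape:
        raise ValueError("measured and fitted curves must have equal length")
    if normalization == "max":
        norm = np.max(np.abs(ct))
    elif normalization == "mean":
        norm = np.mean(np.abs(ct))
    else:
        raise ValueError("normalization must be 'max' or 'mean'")
    if norm == 0.0:
        return 0.0
    return float(100.0 * np.sqrt(np.mean((ct - ct_fit) ** 2)) / norm)


def parameter_uncertainty(
    theta, jacobian, residuals, scale_by_residual: bool = True
) -> np.ndarray:
    """Covariance-based relative parameter uncertainty, percent per parameter.

    Cov = s²·(JᵀJ)⁻¹ with s² = SSR/(n−p) (or s² = 1 when
    ``scale_by_residual`` is off); u_i = 100·√Cov_ii / |θ_i|.  Parameters
    with |θ_i| below 1e−12 get u_i = inf rather than raising.
    """
    theta = np.asarray(theta, dtype=float)
    jac = np.asarray(jacobian, dtype=float)
    r = np.asarray(residuals, dtype=float)
    n, p = jac.shape
    if n <= p:
        raise ValueError("need more points than parameters for a covariance estimate")
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
    if scale_by_residual:
        cov = cov * (float(r @ r) / (n - p))
    sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    denom = np.abs(theta)
    u = np.full_like(sd, np.inf)
    ok = denom >= _TINY_PARAM
    u[ok] = 100.0 * sd[ok] / denom[ok]
    return u


@dataclass
class PkFitResult:
    """Outcome of one model fit to one concentration curve."""

    params: PkParams
    rel_fit_error: float  # percent
    rel_uncertainty: dict  # parameter name -> percent (may be inf)
    ssr: float  # mM^2
    n_points: int
    converged: bool
    n_iterations: int
    fitted: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


class PkCurveFit(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for one tracer-kinetic model.

    Parameters
    ----------
    model : {'patlak', 'tofts', 'extended_tofts'}
    aif : callable
        Blood-plasma concentration C_p as a function of time in minutes
        (e.g. a :class:`~dcewall.aif.ParkerAif`).
    optimizer : {'lm', 'gauss_newton'}
        'lm' is the damped Gauss–Newton (trust-region least squares);
        'gauss_newton' an undamped projected Gauss–Newton iteration.
    error_normalization : {'max', 'mean'}
        Normalization of the relative fit error.
    scale_covariance : bool
        Scale the covariance by s² = SSR/(n−p) (on by default).
    multi_start : int
        Number of additional deterministic jittered starts (0 = single
        fixed initialization).
    n_baseline : int
        Leading samples treated as pre-injection when a SignalCurve is
        converted upstream; kept for metadata only.

    Attributes (after ``fit``)
    --------------------------
    params_ : PkParams — point estimates.
    ktrans_, vp_, ve_ : float or None.
    rel_fit_error_ : float, percent.
    rel_uncertainty_ : dict, percent per free parameter.
    ssr_, n_points_, converged_, n_iter_ : fit diagnostics.
    """

    def __init__(
        self,
        model: str = "patlak",
        aif=None,
        optimizer: str = "lm",
        error_normalization: str = "max",
        grid_interval_s: float = DEFAULT_GRID_INTERVAL_S,
        xtol: float = 1e-8,
        max_iter: int = 200,
        scale_covariance: bool = True,
        multi_start: int = 0,
        ktrans_init: float = _INIT["ktrans"],
        vp_init: float = _INIT["vp"],
        ve_init: float = _INIT["ve"],
    ):
        self.model = model
        self.aif = aif
        self.optimizer = optimizer
        self.error_normalization = error_normalization
        self.grid_interval_s = grid_interval_s
        self.xtol = xtol
        self.max_iter = max_iter
        self.scale_covariance = scale_covariance
        self.multi_start = multi_start
        self.ktrans_init = ktrans_init
        self.vp_init = vp_init
        self.ve_init = ve_init

    # -- internals ---------------------------------------------------------

    def _validate(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be 1-D times (minutes) or a column vector")
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("y must match X in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.aif is None:
            raise ValueError("an AIF callable is required")
        p = len(MODEL_PARAMS[self.model])
        if t.size < p + 2:
            raise ValueError(f"need at least {p + 2} time points for {self.model}")
        return t, y

    def _x0(self) -> np.ndarray:
        init = {"ktrans": self.ktrans_init, "vp": self.vp_init, "ve": self.ve_init}
        return np.array([init[n] for n in MODEL_PARAMS[self.model]], dtype=float)

    def _bounds(self):
        names = MODEL_PARAMS[self.model]
        lo = np.array([_BOUNDS[n][0] for n in names])
        hi = np.array([_BOUNDS[n][1] for n in names])
        return lo, hi

    def _forward(self, x, t):
        return forward_model(
            PkParams.from_vector(self.model, x), self.aif, t, self.grid_interval_s
        )

    def _jac(self, x, t):
        return model_jacobian(
            PkParams.from_vector(self.model, x), self.aif, t, self.grid_interval_s
        )

    def _solve_patlak(self, t, y):
        a = self._jac(self._x0(), t)  # Patlak Jacobian is parameter-independent
        lo, hi = self._bounds()
        x, *_ = np.linalg.lstsq(a, y, rcond=None)
        if np.any(x < lo) or np.any(x > hi):
            x = lsq_linear(a, y, bounds=(lo, hi)).x
        return x, True, 1

    def _solve_gauss_newton(self, t, y, x0):
        lo, hi = self._bounds()
        x = x0.copy()
        for it in range(1, self.max_iter + 1):
            r = self._forward(x, t) - y
            j = self._jac(x, t)
            try:
                step = np.linalg.solve(j.T @ j, -j.T @ r)
            except np.linalg.LinAlgError:
                return x, False, it
            x_new = np.clip(x + step, lo, hi)
            rel = np.max(np.abs(x_new - x) / np.maximum(np.abs(x), 1e-12))
            x = x_new
            if rel < self.xtol:
                return x, True, it
        return x, False, self.max_iter

    def _solve_lm(self, t, y, x0):
        lo, hi = self._bounds()
        res = least_squares(
            lambda x: self._forward(x, t) - y,
            np.clip(x0, lo, hi),
            jac=lambda x: self._jac(x, t),
            bounds=(lo, hi),
            method="trf",
            xtol=self.xtol,
            ftol=None,
            gtol=None,
            max_nfev=self.max_iter,
        )
        return res.x, bool(res.status > 0), int(res.nfev)

    def _solve_nls(self, t, y):
        starts = [self._x0()]
        if self.multi_start:
            # deterministic geometric jitter around the fixed initialization
            factors = np.geomspace(0.25, 4.0, self.multi_start)
            starts += [self._x0() * f for f in factors]
        best = None
        for x0 in starts:
            solver = self._solve_gauss_newton if self.optimizer == "gauss_newton" else self._solve_lm
            x, ok, nit = solver(t, y, x0)
            ssr = float(np.sum((self._forward(x, t) - y) ** 2))
            if best is None or (ok and not best[1]) or (ok == best[1] and ssr < best[3]):
                best = (x, ok, nit, ssr)
        return best[0], best[1], best[2]

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        t, y = self._validate(X, y)
        names = MODEL_PARAMS[self.model]

        if not np.any(y != 0.0):
            # degenerate all-zero curve: rate/volume terms are zero by definition
            zero = {"ktrans": 0.0, "vp": 0.0, "ve": self.ve_init}
            x = np.array([zero[n] for n in names])
            converged, n_iter = True, 0
        elif self.model == "patlak":
            x, converged, n_iter = self._solve_patlak(t, y)
        else:
            x, converged, n_iter = self._solve_nls(t, y)

        # Patlak's zero lower bound conflicts with PkParams ve>0; fits keep ve>=1e-3
        params = PkParams.from_vector(self.model, x)
        fitted = self._forward(x, t)
        residuals = fitted - y
        ssr = float(residuals @ residuals)

        jac = self._jac(x, t)
        if t.size > len(names):
            u = parameter_uncertainty(x, jac, residuals, self.scale_covariance)
        else:
            u = np.full(len(names), np.nan)

        self.params_ = params
        self.ktrans_ = params.ktrans
        self.vp_ = params.vp
        self.ve_ = params.ve
        self.fitted_ = fitted
        self.rel_fit_error_ = relative_fit_error(y, fitted, self.error_normalization)
        self.rel_uncertainty_ = dict(zip(names, (float(v) for v in u)))
        self.ssr_ = ssr
        self.n_points_ = int(t.size)
        self.converged_ = bool(converged)
        self.n_iter_ = int(n_iter)
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        return self._forward(self.params_.as_vector(), t)

    def result(self) -> PkFitResult:
        return PkFitResult(
            params=self.params_,
            rel_fit_error=self.rel_fit_error_,
            rel_uncertainty=self.rel_uncertainty_,
            ssr=self.ssr_,
            n_points=self.n_points_,
            converged=self.converged_,
            n_iterations=self.n_iter_,
            fitted=self.fitted_,
        )


def fit_curve(ct: ConcentrationCurve, aif, model: str, **options) -> PkFitResult:
    """Fit one model to one tissue concentration curve (times in seconds)."""
    est = PkCurveFit(model=model, aif=aif, **options)
    est.fit(ct.times_min, ct.concentration)
    return est.result()


@dataclass
class WallRoi:
    """Vessel-wall region of interest as a boolean membership mask.

    Typically a closed ring between the inner and outer wall contour on
    each slice; :meth:`from_rings` builds one from circular contours.
    """

    mask: np.ndarray  # bool, spatial grid (nx, ny, n_slices)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D (nx, ny, n_slices)")
        if not self.mask.any():
            raise ValueError("ROI membership is empty")

    @classmethod
    def from_rings(
        cls,
        grid_shape: tuple[int, int, int],
        center: tuple[float, float],
        r_inner: float,
        r_outer: float,
        slices=None,
    ) -> "WallRoi":
        """Ring r_inner ≤ r < r_outer around ``center`` on the given slices."""
        if not (0 <= r_inner < r_outer):
            raise ValueError("require 0 <= r_inner < r_outer")
        nx, ny, nz = grid_shape
        x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        r = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2)
        ring = (r >= r_inner) & (r < r_outer)
        mask = np.zeros(grid_shape, dtype=bool)
        for z in range(nz) if slices is None else slices:
            mask[:, :, z] = ring
        return cls(mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _roi_mask(roi) -> np.ndarray:
    return roi.mask if isinstance(roi, WallRoi) else np.asarray(roi, dtype=bool)


def _voxel_concentrations(series, mask, protocol):
    """Convert every masked voxel's signal course to concentration (mM)."""
    protocol = protocol or series.protocol
    courses = series.data[mask]  # (n_voxels, n_dynamics)
    out = np.empty_like(courses)
    for i, sig in enumerate(courses):
        curve = SignalCurve(series.times_s, sig, n_baseline=protocol.n_baseline)
        out[i] = signal_to_concentration(curve, protocol).concentration
    return out


@dataclass
class VoxelwiseResult:
    """Per-voxel fits plus parameter maps and the ROI-mean summary."""

    maps: dict  # parameter name -> 3-D array (NaN outside ROI / non-converged)
    results: list  # per-voxel PkFitResult, ROI order
    roi_mean: dict  # parameter name -> mean over converged voxels
    mean_rel_fit_error: float
    mean_rel_uncertainty: dict
    n_converged: int
    n_voxels: int


def fit_voxelwise(series, roi, aif, model: str, protocol=None, **options) -> VoxelwiseResult:
    """Fit each vessel-wall voxel separately; average parameters over voxels.

    Every voxel signal course is converted to concentration and fitted
    independently; parameter maps carry the estimates (NaN outside the ROI
    and for non-converged voxels) and the summary is the mean over
    converged voxels.
    """
    mask = _roi_mask(roi)
    protocol = protocol or series.protocol
    if mask.shape != series.data.shape[:3]:
        raise ValueError("ROI mask shape must match the series spatial grid")
    if not mask.any():
        raise ValueError("ROI is empty")

    conc = _voxel_concentrations(series, mask, protocol)
    t_min = series.times_s / 60.0
    est = PkCurveFit(model=model, aif=aif, **options)
    names = MODEL_PARAMS[model]

    results = []
    values = np.full((conc.shape[0], len(names)), np.nan)
    for i in range(conc.shape[0]):
        est.fit(t_min, conc[i])
        res = est.result()
        results.append(res)
        if res.converged:
            values[i] = res.params.as_vector()

    conv = np.array([r.converged for r in results])
    if not conv.any():
        raise RuntimeError("no vessel-wall voxel converged")

    maps = {}
    for j, name in enumerate(names):
        vol = np.full(mask.shape, np.nan)
        vol[mask] = values[:, j]
        maps[name] = vol

    roi_mean = {n: float(np.nanmean(values[:, j])) for j, n in enumerate(names)}
    mean_err = float(np.mean([r.rel_fit_error for r in results if r.converged]))
    mean_u = {
        n: float(
            np.mean(
                [
                    r.rel_uncertainty[n]
                    for r in results
                    if r.converged and np.isfinite(r.rel_uncertainty[n])
                ]
                or [np.nan]
            )
        )
        for n in names
    }
    return VoxelwiseResult(
        maps=maps,
        results=results,
        roi_mean=roi_mean,
        mean_rel_fit_error=mean_err,
        mean_rel_uncertainty=mean_u,
        n_converged=int(conv.sum()),
        n_voxels=len(results),
    )


def fit_roibased(series, roi, aif, model: str, protocol=None, **options) -> PkFitResult:
    """Average the wall concentration per time point, then fit once."""
    mask = _roi_mask(roi)
    protocol = protocol or series.protocol
    if not mask.any():
        raise ValueError("ROI is empty")
    conc = _voxel_concentrations(series, mask, protocol)
    mean_curve = ConcentrationCurve(series.times_s, conc.mean(axis=0))
    return fit_curve(mean_curve, aif, model, **options)
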