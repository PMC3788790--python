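"""Forward evaluation of the Patlak, Tofts and Extended Tofts models.

All three solve the two-compartment (plasma / extravascular-extracellular)
tracer model under different assumptions:

    Patlak          C_t(t) = K^trans ∫₀ᵗ C_p dτ + v_p·C_p(t)      (no backflux)
    Tofts           C_t(t) = K^trans ∫₀ᵗ C_p(τ) e^(−k_ep (t−τ)) dτ,  k_ep = K^trans/v_e
    Extended Tofts  C_t(t) = Tofts + v_p·C_p(t)

The AIF is evaluated analytically on a refined uniform internal grid
(default 0.5 s).  The Patlak integral uses the cumulative trapezoid on that
grid; the Tofts convolution uses the exact closed form for a
piecewise-linear C_p convolved with an exponential kernel, advanced by a
linear recursion (an IIR filter), then sampled at the acquisition times.
Analytic Jacobians are provided for Gauss–Newton-type fitting; the partial
with respect to k_ep needs the companion convolution with kernel
u·e^(−k_ep·u), computed by the same recursion technique.

Kinetics units: time in minutes, K^trans and k_ep in min⁻¹, concentrations
in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .curves import SECONDS_PER_MINUTE, ConcentrationCurve

__all__ = [
    "MODELS",
    "PkParams",
    "patlak_forward",
    "tofts_forward",
    "extended_tofts_forward",
    "forward_model",
    "model_jacobian",
]

MODELS = ("patlak", "tofts", "extended_tofts")

#: free parameters of each model, in fitting order
MODEL_PARAMS = {
    "patlak": ("ktrans", "vp"),
    "tofts": ("ktrans", "ve"),
    "extended_tofts": ("ktrans", "vp", "ve"),
}

DEFAULT_GRID_INTERVAL_S = 0.5


@dataclass(frozen=True)
class PkParams:
    """Pharmacokinetic parameters for one model.

    ktrans in min⁻¹; vp and ve are volume fractions.  ``vp`` is absent for
    the Tofts model, ``ve`` for Patlak.
    """

    model: str
    ktrans: float
    vp: float | None = None
    ve: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.ktrans < 0:
            raise ValueError("ktrans must be non-negative")
        names = MODEL_PARAMS[self.model]
        if "vp" in names:
            if self.vp is None or not (0.0 <= self.vp <= 1.0):
                raise ValueError(f"{self.model} requires vp in [0, 1]")
        if "ve" in names:
            if self.ve is None or not (0.0 < self.ve <= 1.0):
                raise ValueError(f"{self.model} requires ve in (0, 1]")

    @property
    def kep(self) -> float | None:
        """Efflux rate constant K^trans/v_e (min⁻¹); None for Patlak."""
        return None if self.ve is None else self.ktrans / self.ve

    @property
    def free_names(self) -> tuple[str, ...]:
        return MODEL_PARAMS[self.model]

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.free_names], dtype=float)

    @classmethod
    def from_vector(cls, model: str, x) -> "PkParams":
        return cls(model=model, **dict(zip(MODEL_PARAMS[model], (float(v) for v in x))))


# ---------------------------------------------------------------------------
# AIF evaluation helpers
# ---------------------------------------------------------------------------
#
# A Parker-form AIF is zero before its onset t0 and jumps to a finite value
# there.  A piecewise-linear representation cannot express that jump, so the
# input is decomposed as C_p = C_p_smooth + J0·H(t−t0): the continuous part
# goes through the piecewise-linear machinery and the step's convolution with
# the exponential kernels is added in closed form.  Objects exposing a ``t0``
# attribute (and vanishing before it) opt in; other callables are treated as
# jump-free.


def _cp_callable(cp):
    """Normalize an AIF input (callable or ConcentrationCurve) to a callable of minutes."""
    if callable(cp):
        return lambda t: np.asarray(cp(t), dtype=float)
    if isinstance(cp, ConcentrationCurve):
        t_min = cp.times_min
        vals = cp.concentration
        return lambda t: np.interp(np.asarray(t, dtype=float), t_min, vals, left=0.0)
    raise TypeError("cp must be callable (minutes -> mM) or a ConcentrationCurve")


def _internal_grid(times_min: np.ndarray, grid_interval_s: float) -> np.ndarray:
    dt = grid_interval_s / SECONDS_PER_MINUTE
    t_max = float(np.max(times_min))
    n = max(int(np.ceil(t_max / dt + 1e-9)), 1)
    return np.linspace(0.0, n * dt, n + 1)


def _onset_jump(cp, cp_fn, t_max: float) -> tuple[float, float]:
    """(t0, jump height) of an AIF-style onset discontinuity, or (0, 0)."""
    t0 = getattr(cp, "t0", None)
    if t0 is None or not (0.0 < t0 < t_max):
        return 0.0, 0.0
    return float(t0), float(np.asarray(cp_fn(np.array([t0])))[0])


def _step_integral(t: np.ndarray, t0: float) -> np.ndarray:
    """∫₀ᵗ H(τ−t0) dτ = (t−t0)₊."""
    return np.maximum(t - t0, 0.0)


def _step_conv_exp(t: np.ndarray, t0: float, k: float) -> np.ndarray:
    """∫₀ᵗ H(τ−t0) e^(−k(t−τ)) dτ = (1 − e^(−k(t−t0)₊))/k, with k→0 limit."""
    u = np.maximum(t - t0, 0.0)
    if k * np.max(u, initial=0.0) < 1e-8:
        return u * (1.0 - k * u / 2.0)
    return -np.expm1(-k * u) / k


def _step_conv_uexp(t: np.ndarray, t0: float, k: float) -> np.ndarray:
    """∫₀ᵗ H(τ−t0) (t−τ) e^(−k(t−τ)) dτ = (1 − e^(−ku)(1+ku))/k², u = (t−t0)₊."""
    u = np.maximum(t - t0, 0.0)
    ku = k * u
    if k * np.max(u, initial=0.0) < 1e-6:
        return u**2 / 2.0 * (1.0 - 2.0 * ku / 3.0)
    return (1.0 - np.exp(-ku) * (1.0 + ku)) / k**2


# ---------------------------------------------------------------------------
# Exact piecewise-linear × exponential convolution
# ---------------------------------------------------------------------------


def _interval_weights(k: float, dt: float) -> tuple[float, float, float, float, float]:
    """Closed-form interval integrals for the exponential-kernel recursion.

    With C_p linear on [0, Δ] (C_p(u) = a + b·u) and E = e^(−kΔ):

        φ1 = ∫ e^(−k(Δ−u)) du,          φ2 = ∫ u e^(−k(Δ−u)) du,
        ψ1 = ∫ w e^(−kw) dw,            ψ2 = ∫ w² e^(−kw) dw   (w = Δ−u),

    so the local contributions are L0 = a·φ1 + b·φ2 for the e^(−ku) kernel
    and L1 = (a+bΔ)·ψ1 − b·ψ2 for the u·e^(−ku) kernel.  Series expansions
    take over for kΔ → 0.
    """
    kd = k * dt
    if kd < 1e-4:  # Taylor to O(kΔ)³: relative truncation error < 1e-17
        e = np.exp(-kd)
        phi1 = dt * (1 - kd / 2 + kd**2 / 6 - kd**3 / 24)
        phi2 = dt**2 * (0.5 - kd / 6 + kd**2 / 24 - kd**3 / 120)
        psi1 = dt**2 * (0.5 - kd / 3 + kd**2 / 8 - kd**3 / 30)
        psi2 = dt**3 * (1.0 / 3 - kd / 4 + kd**2 / 10 - kd**3 / 36)
        return e, phi1, phi2, psi1, psi2
    e = np.exp(-kd)
    phi1 = (1.0 - e) / k
    phi2 = (dt - phi1) / k
    psi1 = (1.0 - e * (1.0 + kd)) / k**2
    psi2 = (2.0 - e * (2.0 + 2.0 * kd + kd**2)) / k**3
    return e, phi1, phi2, psi1, psi2


def _exp_convolutions(cp_grid: np.ndarray, dt: float, kep: float, need_dk: bool):
    """Convolve piecewise-linear C_p with e^(−k u) (and optionally u·e^(−k u)).

    Returns (I, J) on the uniform grid, J = None unless ``need_dk``:

        I(t) = ∫₀ᵗ C_p(τ) e^(−k(t−τ)) dτ
        J(t) = ∫₀ᵗ C_p(τ) (t−τ) e^(−k(t−τ)) dτ = −∂I/∂k
    """
    e, phi1, phi2, psi1, psi2 = _interval_weights(kep, dt)
    a = cp_grid[:-1]
    b = (cp_grid[1:] - cp_grid[:-1]) / dt
    l0 = a * phi1 + b * phi2
    x = np.concatenate(([0.0], l0))
    conv = lfilter([1.0], [1.0, -e], x)
    if not need_dk:
        return conv, None
    l1 = (a + b * dt) * psi1 - b * psi2
    u = np.concatenate(([0.0], e * dt * conv[:-1] + l1))
    dconv = lfilter([1.0], [1.0, -e], u)
    return conv, dconv


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------


def _prepare(cp, times_min, grid_interval_s):
    """Grid the AIF and split off its onset step: returns
    (times, cp_fn, grid, smooth cp on grid, t0, jump)."""
    times_min = np.asarray(times_min, dtype=float)
    cp_fn = _cp_callable(cp)
    grid = _internal_grid(times_min, grid_interval_s)
    cp_grid = cp_fn(grid)
    t0, jump = _onset_jump(cp, cp_fn, float(grid[-1]))
    if jump:
        cp_grid = cp_grid - jump * (grid >= t0)
    return times_min, cp_fn, grid, cp_grid, t0, jump


def patlak_forward(
    params: PkParams, cp, times_min, grid_interval_s: float = DEFAULT_GRID_INTERVAL_S
) -> np.ndarray:
    """Patlak model: C_t = K^trans·∫C_p + v_p·C_p, no backflux."""
    if params.model != "patlak":
        raise ValueError("params.model must be 'patlak'")
    times_min, cp_fn, grid, cp_grid, t0, jump = _prepare(cp, times_min, grid_interval_s)
    integral = cumulative_trapezoid(cp_grid, grid, initial=0.0)
    total = np.interp(times_min, grid, integral)
    if jump:
        total = total + jump * _step_integral(times_min, t0)
    return params.ktrans * total + params.vp * cp_fn(times_min)


def tofts_forward(
    params: PkParams, cp, times_min, grid_interval_s: float = DEFAULT_GRID_INTERVAL_S
) -> np.ndarray:
    """Tofts model: exponential impulse response with rate k_ep = K^trans/v_e."""
    if params.model != "tofts":
        raise ValueError("params.model must be 'tofts'")
    if params.ve is None or params.ve <= 0:
        raise ValueError("Tofts model requires ve > 0")
    times_min, _, grid, cp_grid, t0, jump = _prepare(cp, times_min, grid_interval_s)
    conv, _ = _exp_convolutions(cp_grid, grid[1] - grid[0], params.kep, need_dk=False)
    i_t = np.interp(times_min, grid, conv)
    if jump:
        i_t = i_t + jump * _step_conv_exp(times_min, t0, params.kep)
    return params.ktrans * i_t


def extended_tofts_forward(
    params: PkParams, cp, times_min, grid_interval_s: float = DEFAULT_GRID_INTERVAL_S
) -> np.ndarray:
    """Extended Tofts: Tofts plus the plasma term v_p·C_p."""
    if params.model != "extended_tofts":
        raise ValueError("params.model must be 'extended_tofts'")
    tofts = replace(params, model="tofts", vp=None)
    cp_fn = _cp_callable(cp)
    times_min = np.asarray(times_min, dtype=float)
    return tofts_forward(tofts, cp, times_min, grid_interval_s) + params.vp * cp_fn(times_min)


_FORWARD = {
    "patlak": patlak_forward,
    "tofts": tofts_forward,
    "extended_tofts": extended_tofts_forward,
}


def forward_model(
    params: PkParams, cp, times_min, grid_interval_s: float = DEFAULT_GRID_INTERVAL_S
) -> np.ndarray:
    """Dispatch to the forward model named in ``params.model``."""
    return _FORWARD[params.model](params, cp, times_min, grid_interval_s)


def model_jacobian(
    params: PkParams, cp, times_min, grid_interval_s: float = DEFAULT_GRID_INTERVAL_S
) -> np.ndarray:
    """Analytic sensitivities ∂C_t/∂θ, one column per free parameter.

    Column order follows ``params.free_names``:
    Patlak (K^trans, v_p): [∫C_p, C_p] — parameter-independent.
    Tofts (K^trans, v_e): with I the exponential convolution and
    J = −∂I/∂k_ep,  ∂C_t/∂K = I − (K/v_e)·J and ∂C_t/∂v_e = k_ep²·J.
    Extended Tofts (K^trans, v_p, v_e): Tofts columns plus ∂C_t/∂v_p = C_p.
    """
    times_min, cp_fn, grid, cp_grid, t0, jump = _prepare(cp, times_min, grid_interval_s)
    if params.model == "patlak":
        integral = cumulative_trapezoid(cp_grid, grid, initial=0.0)
        total = np.interp(times_min, grid, integral)
        if jump:
            total = total + jump * _step_integral(times_min, t0)
        return np.column_stack([total, cp_fn(times_min)])

    kep = params.kep
    conv, dconv = _exp_convolutions(cp_grid, grid[1] - grid[0], kep, need_dk=True)
    i_t = np.interp(times_min, grid, conv)
    j_t = np.interp(times_min, grid, dconv)
    if jump:
        i_t = i_t + jump * _step_conv_exp(times_min, t0, kep)
        j_t = j_t + jump * _step_conv_uexp(times_min, t0, kep)
    d_ktrans = i_t - (params.ktrans / params.ve) * j_t
    d_ve = kep**2 * j_t
    if params.model == "tofts":
        return np.column_stack([d_ktrans, d_ve])
    return np.column_stack([d_ktrans, cp_fn(times_min), d_ve])
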