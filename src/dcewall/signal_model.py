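"""Spoiled-gradient-echo signal model and signal→concentration conversion.

The steady-state SPGR (Ernst) equation links gadolinium concentration C to
measured signal through the relaxation rates

    R1(C) = 1/T1₀ + r1·C,   R2(C) = 1/T2₀ + r2·C,
    S(C)  = scale · sin α · (1 − e^(−TR·R1)) / (1 − cos α · e^(−TR·R1)) · e^(−TE·R2).

With short TE the signal is strictly increasing in C over the working
range, so the conversion inverts each sample by bracketed monotone
root-finding.  The signal scale is fixed from the pre-injection baseline,
where C = 0 is assumed.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .curves import ConcentrationCurve, SignalCurve
from .protocol import AcquisitionProtocol, baseline_window

__all__ = [
    "spgr_signal",
    "signal_to_concentration",
    "baseline_window",
    "CONCENTRATION_BRACKET",
]

# Inversion bracket in mM: mildly negative concentrations are tolerated so
# that baseline noise does not bias least-squares residuals.
CONCENTRATION_BRACKET = (-0.5, 20.0)


def spgr_signal(
    concentration,
    protocol: AcquisitionProtocol,
    scale: float = 1.0,
    include_t2: bool = True,
):
    """Forward SPGR signal for gadolinium concentration(s) in mM.

    ``include_t2`` controls whether the e^(−TE·R2) decay factor is applied;
    with TE = 1.5 ms it is a small correction, kept on by default.
    """
    c = np.asarray(concentration, dtype=float)
    alpha = np.deg2rad(protocol.flip_angle)
    r1_rate = 1.0 / protocol.t1_pre + protocol.r1 * c
    e1 = np.exp(-protocol.tr * r1_rate)
    s = scale * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)
    if include_t2:
        r2_rate = 1.0 / protocol.t2_pre + protocol.r2 * c
        s = s * np.exp(-protocol.te * r2_rate)
    return s if s.ndim else float(s)


def _invertible_upper_bound(protocol: AcquisitionProtocol, include_t2: bool) -> float:
    """Upper edge of the monotone (invertible) concentration range.

    With the TE·R2 decay included the signal eventually peaks (T2 loss
    overtakes T1 shortening) — far above the working range, but inversion
    must stop at that maximum.  Without the T2 factor the signal increases
    monotonically toward its asymptote and the full bracket is usable.
    """
    lo, hi = CONCENTRATION_BRACKET
    if not include_t2:
        return hi
    res = minimize_scalar(
        lambda c: -spgr_signal(c, protocol, 1.0, include_t2=True),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def _invert_sample(
    target: float, protocol: AcquisitionProtocol, scale: float, include_t2: bool, hi: float
) -> tuple[float, bool]:
    """Invert one signal sample to concentration; returns (C, clipped)."""
    lo = CONCENTRATION_BRACKET[0]
    f_lo = spgr_signal(lo, protocol, scale, include_t2) - target
    f_hi = spgr_signal(hi, protocol, scale, include_t2) - target
    if f_lo >= 0.0:  # signal at or below the bracket floor
        return (lo, f_lo > 0.0)
    if f_hi <= 0.0:  # signal at or beyond the saturation plateau
        return (hi, f_hi < 0.0)
    c = brentq(
        lambda x: spgr_signal(x, protocol, scale, include_t2) - target,
        lo,
        hi,
        xtol=1e-14,
        rtol=8.881784197001252e-16,
    )
    return (float(c), False)


def signal_to_concentration(
    curve: SignalCurve,
    protocol: AcquisitionProtocol,
    include_t2: bool = True,
) -> ConcentrationCurve:
    """Convert a signal time course to gadolinium concentration (mM).

    The scale factor is fixed from the mean of the first ``n_baseline``
    samples under the assumption C = 0 before injection; every sample is
    then inverted by bracketed root-finding of :func:`spgr_signal`.
    Samples outside the invertible range are clamped to the bracket edge
    and flagged in ``ConcentrationCurve.clipped``.  Negative concentrations
    from noise are retained, not clipped to zero.
    """
    s0 = curve.baseline_mean()
    if s0 <= 0.0:
        raise ValueError("baseline mean signal must be positive")
    unit_baseline = spgr_signal(0.0, protocol, 1.0, include_t2)
    scale = s0 / unit_baseline
    hi = _invertible_upper_bound(protocol, include_t2)

    conc = np.empty_like(curve.signal)
    clipped = np.zeros(curve.signal.shape, dtype=bool)
    for i, s in enumerate(curve.signal):
        conc[i], clipped[i] = _invert_sample(float(s), protocol, scale, include_t2, hi)
    return ConcentrationCurve(curve.times, conc, clipped=clipped)
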