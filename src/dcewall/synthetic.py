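"""Ground-truthed DCE-MRI phantoms: curves, 4-D series, scan-rescan cohorts.

The generator emulates a cardiac-gated dynamic vessel-wall protocol — 25
dynamics at a nominal 18 s interval (realised intervals jittered by
gating), contrast injected at the start of the sixth dynamic, a
slow-injection arterial input with a weak first-pass peak — around an
annular "vessel wall" phantom whose voxels follow known tracer kinetics.
Everything is seeded and bit-reproducible, and the true parameter maps are
returned alongside the rendered signal, so every downstream stage
(conversion, fitting, reproducibility statistics) can be tested against
ground truth.

Noise is additive Gaussian on the magnitude signal: the estimator
calibration stays analytically checkable, and at vessel-wall SNR the
Rician correction is negligible (a Rician option is available).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .aif import ParkerAif, evaluate_aif
from .curves import SECONDS_PER_MINUTE, ConcentrationCurve
from .pk_models import PkParams, forward_model
from .protocol import AcquisitionProtocol
from .signal_model import spgr_signal

__all__ = [
    "DynamicSeries",
    "PhantomSpec",
    "CohortSpec",
    "make_time_grid",
    "simulate_tissue_curve",
    "render_dynamic_series",
    "simulate_cohort",
    "save_series",
    "load_series",
]

DEFAULT_BASELINE = 1000.0  # arbitrary signal units; only ratios matter

# Calibrated so single-voxel fit errors land in the mid-teens-to-twenties
# percent range typical of vessel-wall DCE-MRI; a calibration choice, since
# wall SNR is rarely reported.
DEFAULT_WALL_NOISE_SD = 130.0


@dataclass
class DynamicSeries:
    """4-D dynamic signal (x, y, slice, dynamic) with per-dynamic times."""

    data: np.ndarray
    times_s: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, slice, dynamic)")
        if self.data.shape[3] != self.times_s.size:
            raise ValueError("number of dynamics must match number of timestamps")


def make_time_grid(protocol: AcquisitionProtocol, seed=0) -> np.ndarray:
    """Acquisition timestamps in seconds: nominal spacing plus gating jitter.

    The first sample is at t = 0; each subsequent interval is the nominal
    interval plus i.i.d. zero-mean Gaussian jitter of sd
    ``timing_jitter_sd`` (cumulative-summed).  Should jitter ever produce a
    non-monotonic sequence the times are sorted — deterministically, never
    failing.  The injection time is the timestamp of
    ``injection_dynamic``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intervals = np.full(protocol.n_dynamics - 1, protocol.nominal_interval)
    if protocol.timing_jitter_sd > 0:
        intervals = intervals + rng.normal(0.0, protocol.timing_jitter_sd, intervals.size)
    times = np.concatenate(([0.0], np.cumsum(intervals)))
    times = np.sort(times)
    # enforce strict monotonicity in the (measure-zero) event of ties
    tiny = 1e-9 * max(protocol.nominal_interval, 1.0)
    for i in range(1, times.size):
        if times[i] <= times[i - 1]:
            times[i] = times[i - 1] + tiny
    return times


def injection_time_s(protocol: AcquisitionProtocol, times_s: np.ndarray) -> float:
    """Contrast arrival: the timestamp of the injection dynamic (1-based)."""
    return float(times_s[protocol.injection_dynamic - 1])


def simulate_tissue_curve(
    aif, params, model: str | None = None, times_s=None
) -> ConcentrationCurve:
    """Noiseless tissue concentration for one voxel at the requested times.

    ``params`` may be a :class:`PkParams` or a (ktrans, vp, ve) triple
    combined with ``model`` (unused entries may be None).
    """
    if not isinstance(params, PkParams):
        ktrans, vp, ve = params
        if model is None:
            raise ValueError("model identifier required with tuple parameters")
        params = PkParams(
            model=model,
            ktrans=ktrans,
            vp=None if model == "tofts" else vp,
            ve=None if model == "patlak" else ve,
        )
    times_s = np.asarray(times_s, dtype=float)
    ct = forward_model(params, aif, times_s / SECONDS_PER_MINUTE)
    return ConcentrationCurve(times_s, ct)


@dataclass
class PhantomSpec:
    """Annular vessel-wall phantom with known kinetics.

    The wall is the ring r_inner ≤ r < r_outer around ``center`` on every
    slice; voxels inside r_inner form the lumen (carrying the blood
    curve), everything else stays at the constant baseline.  ``ktrans``,
    ``vp``, ``ve`` may be scalars or full 3-D arrays.  True-parameter
    defaults sit in the vessel-wall regime (K^trans a few 0.01 min⁻¹,
    small v_p, v_e ≈ 0.2).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 1)
    center: tuple[float, float] | None = None
    r_inner: float = 6.0
    r_outer: float = 9.0
    ktrans: float | np.ndarray = 0.043
    vp: float | np.ndarray = 0.01
    ve: float | np.ndarray = 0.2
    generating_model: str = "patlak"
    noise_sd: float = DEFAULT_WALL_NOISE_SD
    baseline: float = DEFAULT_BASELINE
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.r_inner < self.r_outer):
            raise ValueError("require 0 <= r_inner < r_outer")
        if self.center is None:
            self.center = ((self.grid_shape[0] - 1) / 2.0, (self.grid_shape[1] - 1) / 2.0)
        kt = np.broadcast_to(np.asarray(self.ktrans, float), self.grid_shape)
        vp = np.broadcast_to(np.asarray(self.vp, float), self.grid_shape)
        ve = np.broadcast_to(np.asarray(self.ve, float), self.grid_shape)
        if np.any(kt < 0):
            raise ValueError("ktrans must be non-negative")
        if np.any((vp < 0) | (vp > 1)) or np.any((ve < 0) | (ve > 1)):
            raise ValueError("vp and ve must be fractions in [0, 1]")
        if np.any(vp + ve > 1):
            raise ValueError("vp + ve must not exceed 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        """(wall ring, lumen) boolean masks on the spatial grid."""
        nx, ny, nz = self.grid_shape
        x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        r = np.sqrt((x - self.center[0]) ** 2 + (y - self.center[1]) ** 2)
        wall2d = (r >= self.r_inner) & (r < self.r_outer)
        lumen2d = r < self.r_inner
        wall = np.repeat(wall2d[:, :, None], nz, axis=2)
        lumen = np.repeat(lumen2d[:, :, None], nz, axis=2)
        return wall, lumen

    def ring_voxel_count(self) -> int:
        """Analytic wall membership count: voxels with r_inner ≤ r < r_outer."""
        return int(self.masks()[0].sum())


def render_dynamic_series(
    phantom: PhantomSpec,
    protocol: AcquisitionProtocol,
    aif: ParkerAif | None = None,
    rng: np.random.Generator | None = None,
):
    """Render a 4-D signal series from a phantom; returns (series, truth).

    Wall voxels carry tissue kinetics driven by the AIF, lumen voxels the
    blood curve, all other voxels the constant baseline.  Additive noise
    of sd ``noise_sd`` is applied to the magnitude signal.  ``truth``
    holds ground-truth parameter maps (NaN outside the wall) and the wall
    and lumen masks.  The default AIF is the slow-injection population
    model with onset at the injection dynamic's timestamp.
    """
    rng = rng or np.random.default_rng(phantom.seed)
    times_s = make_time_grid(protocol, rng)
    if aif is None:
        aif = ParkerAif.population_slow_injection(
            t0=injection_time_s(protocol, times_s) / SECONDS_PER_MINUTE
        )
    wall, lumen = phantom.masks()
    shape = (*phantom.grid_shape, protocol.n_dynamics)
    # ratio form keeps the C=0 signal exactly equal to the baseline constant
    unit0 = spgr_signal(0.0, protocol, 1.0)
    to_signal = lambda c: phantom.baseline * (spgr_signal(c, protocol, 1.0) / unit0)

    data = np.full(shape, phantom.baseline, dtype=float)

    # blood signal in the lumen
    cb = evaluate_aif(aif, times_s / SECONDS_PER_MINUTE)
    data[lumen] = to_signal(cb)

    # tissue signal in the wall: one forward evaluation per unique parameter triple
    kt = np.broadcast_to(np.asarray(phantom.ktrans, float), phantom.grid_shape)[wall]
    vp = np.broadcast_to(np.asarray(phantom.vp, float), phantom.grid_shape)[wall]
    ve = np.broadcast_to(np.asarray(phantom.ve, float), phantom.grid_shape)[wall]
    triples = np.column_stack([kt, vp, ve])
    uniq, inverse = np.unique(triples, axis=0, return_inverse=True)
    wall_signals = np.empty((triples.shape[0], protocol.n_dynamics))
    model = phantom.generating_model
    for u_idx, (k, p, e) in enumerate(uniq):
        params = PkParams(
            model=model,
            ktrans=k,
            vp=None if model == "tofts" else p,
            ve=None if model == "patlak" else e,
        )
        ct = forward_model(params, aif, times_s / SECONDS_PER_MINUTE)
        wall_signals[inverse == u_idx] = to_signal(ct)
    data[wall] = wall_signals

    if phantom.noise_sd > 0:
        noise = rng.normal(0.0, phantom.noise_sd, shape)
        if phantom.noise_model == "rician":
            imag = rng.normal(0.0, phantom.noise_sd, shape)
            data = np.sqrt((data + noise) ** 2 + imag**2)
        else:
            data = data + noise
        np.clip(data, 0.0, None, out=data)

    series = DynamicSeries(data, times_s, protocol)
    nanmap = lambda v: np.where(wall, v, np.nan)
    truth = {
        "ktrans": nanmap(np.broadcast_to(np.asarray(phantom.ktrans, float), phantom.grid_shape)),
        "vp": nanmap(np.broadcast_to(np.asarray(phantom.vp, float), phantom.grid_shape)),
        "ve": nanmap(np.broadcast_to(np.asarray(phantom.ve, float), phantom.grid_shape)),
        "wall_mask": wall,
        "lumen_mask": lumen,
        "aif": aif,
    }
    return series, truth


@dataclass
class CohortSpec:
    """Scan-rescan cohort design with controlled variance components.

    Subject-level K^trans is log-normal about ``mean_ktrans`` with the
    given between-subject CV; each scan perturbs the subject value through
    a mean-one log-normal factor with the within-subject CV.  Maximal
    aneurysm diameter follows a linear model in the subject's true
    K^trans plus Gaussian residual.
    """

    n_subjects: int = 10
    between_subject_cv: float = 0.40
    within_subject_cv: float = 0.22
    mean_ktrans: float = 0.043  # min^-1
    vp: float = 0.01
    ve: float = 0.2
    diameter_model: tuple[float, float, float] = (43.0, 150.0, 5.0)  # mm, mm·min, mm
    n_rescans: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_subject_cv < 0 or self.within_subject_cv < 0:
            raise ValueError("CVs must be non-negative")
        if self.n_subjects < 1 or self.n_rescans < 1:
            raise ValueError("need at least one subject and one scan")
        if self.mean_ktrans <= 0:
            raise ValueError("mean_ktrans must be positive")


def _lognormal_factors(rng, n, cv):
    """Mean-one multiplicative log-normal factors with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


@dataclass
class SubjectRecord:
    subject_id: str
    ktrans_subject: float
    diameter_mm: float
    ktrans_scans: list[float]
    series: list = field(default_factory=list)  # DynamicSeries per scan (may be empty)
    truths: list = field(default_factory=list)


def simulate_cohort(
    cohort: CohortSpec,
    protocol: AcquisitionProtocol | None = None,
    aif: ParkerAif | None = None,
    phantom: PhantomSpec | None = None,
    render: bool = True,
) -> list[SubjectRecord]:
    """Draw a scan-rescan cohort; optionally render each scan as a series.

    With ``render=False`` only the measurement-level truth (subject and
    per-scan K^trans, diameters) is produced — enough to study the
    reproducibility estimators without imaging overhead.
    """
    protocol = protocol or AcquisitionProtocol()
    phantom = phantom or PhantomSpec()
    rng = np.random.default_rng(cohort.seed)

    subj_factors = _lognormal_factors(rng, cohort.n_subjects, cohort.between_subject_cv)
    ktrans_subject = cohort.mean_ktrans * subj_factors
    icpt, slope, resid_sd = cohort.diameter_model
    diameters = icpt + slope * ktrans_subject + rng.normal(0.0, resid_sd, cohort.n_subjects)

    records: list[SubjectRecord] = []
    for i in range(cohort.n_subjects):
        scan_factors = _lognormal_factors(rng, cohort.n_rescans, cohort.within_subject_cv)
        kt_scans = [float(ktrans_subject[i] * f) for f in scan_factors]
        rec = SubjectRecord(
            subject_id=f"sub{i + 1:02d}",
            ktrans_subject=float(ktrans_subject[i]),
            diameter_mm=float(diameters[i]),
            ktrans_scans=kt_scans,
        )
        if render:
            for kt in kt_scans:
                scan_phantom = replace(
                    phantom, ktrans=kt, vp=cohort.vp, ve=cohort.ve
                )
                series, truth = render_dynamic_series(scan_phantom, protocol, aif, rng=rng)
                rec.series.append(series)
                rec.truths.append(truth)
        records.append(rec)
    return records


def cohort_truth_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Tidy ground truth: one row per (subject, scan)."""
    rows = []
    for rec in records:
        for s, kt in enumerate(rec.ktrans_scans, start=1):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "scan_id": f"scan{s}",
                    "ktrans_true": kt,
                    "vp_true": np.nan,
                    "ve_true": np.nan,
                    "diameter_mm": rec.diameter_mm,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI / sidecar I/O
# ---------------------------------------------------------------------------


def save_series(
    out_dir: str | Path,
    series: DynamicSeries,
    wall_mask: np.ndarray | None = None,
    lumen_mask: np.ndarray | None = None,
) -> Path:
    """Write a series as NIfTI-1 plus a {"times_s": [...]} JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(series.data, affine), out / "series.nii.gz")
    if wall_mask is not None:
        nib.save(nib.Nifti1Image(wall_mask.astype(np.uint8), affine), out / "wall_mask.nii.gz")
    if lumen_mask is not None:
        nib.save(nib.Nifti1Image(lumen_mask.astype(np.uint8), affine), out / "lumen_mask.nii.gz")
    (out / "times.json").write_text(
        json.dumps({"times_s": [float(t) for t in series.times_s]}) + "\n"
    )
    series.protocol.to_json(out / "protocol.json")
    return out


def load_series(in_dir: str | Path) -> tuple[DynamicSeries, np.ndarray | None]:
    """Load a series written by :func:`save_series`; returns (series, wall mask)."""
    d = Path(in_dir)
    img = nib.load(d / "series.nii.gz")
    times = np.asarray(json.loads((d / "times.json").read_text())["times_s"], dtype=float)
    protocol = AcquisitionProtocol.from_json(d / "protocol.json")
    series = DynamicSeries(np.asarray(img.dataobj, dtype=float), times, protocol)
    mask_path = d / "wall_mask.nii.gz"
    mask = None
    if mask_path.exists():
        mask = np.asarray(nib.load(mask_path).dataobj) > 0
    return series, mask
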