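"""End-to-end study orchestration: series in, maps/tables/report out.

A *study* is a directory of per-subject, per-scan dynamic series (NIfTI-1
plus JSON sidecars) described by a ``study.json`` config.  ``run_study``
converts every vessel-wall voxel to concentration, fits the requested
pharmacokinetic models voxel-wise and/or ROI-based, writes parameter maps
and a tidy per-fit CSV, and assembles a model-comparison report: per-model
K^trans, relative fit error and uncertainty summaries, pairwise Wilcoxon
tests and win counts, Spearman correlation with maximal aneurysm diameter,
and the scan-rescan reproducibility table when rescans are present.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .aif import ParkerAif
from .fitting import fit_roibased, fit_voxelwise
from .pk_models import MODELS
from .repro_stats import reproducibility_report, spearman_rho, wilcoxon_signed_rank
from .synthetic import load_series, save_series

__all__ = [
    "ScanEntry",
    "SubjectEntry",
    "StudyConfig",
    "ComparisonReport",
    "run_study",
    "compare_models",
    "write_synthetic_study",
]

logger = logging.getLogger(__name__)

MIN_SUBJECTS_FOR_TESTS = 5


class ScanEntry(BaseModel):
    scan_id: str
    path: str  # directory with series.nii.gz / wall_mask.nii.gz / sidecars


class SubjectEntry(BaseModel):
    subject_id: str
    diameter_mm: float | None = None
    scans: list[ScanEntry]


class StudyConfig(BaseModel):
    """Validated study description (paths are relative to the study root)."""

    subjects: list[SubjectEntry]
    aif_path: str = "aif.json"
    models: list[str] = Field(default_factory=lambda: list(MODELS))
    modes: list[str] = Field(default_factory=lambda: ["voxel", "roi"])
    error_normalization: str = "max"
    optimizer: str = "lm"
    cv_pooling: str = "rms"
    icc_form: str = "icc1"
    grid_interval_s: float = 0.5
    max_nonconverged_fraction: float = 0.2  # above this a scan is flagged poor quality
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


class ModelSummary(BaseModel):
    model: str
    mode: str
    n: int
    ktrans_mean: float
    ktrans_sd: float
    fit_error_mean_pct: float
    fit_error_sd_pct: float
    u_ktrans_mean_pct: float | None = None
    u_ktrans_sd_pct: float | None = None


class PairwiseComparison(BaseModel):
    model_a: str
    model_b: str
    mode: str
    n: int
    p_fit_error: float | None = None
    p_ktrans: float | None = None
    win_fraction_a: float  # fraction of subjects where A has lower fit error
    ktrans_spearman_rho: float | None = None
    ktrans_spearman_p: float | None = None


class DiameterCorrelation(BaseModel):
    model: str
    mode: str
    n: int
    rho: float | None = None
    p: float | None = None


class ReproRow(BaseModel):
    model: str
    mode: str
    n_subjects: int
    icc: float
    cv_pct: float


class ComparisonReport(BaseModel):
    """Everything the model comparison computes, as a validated schema."""

    summaries: list[ModelSummary]
    pairwise: list[PairwiseComparison]
    diameter_correlations: list[DiameterCorrelation]
    reproducibility: list[ReproRow]
    exclusions: list[str] = Field(default_factory=list)


# ---------------------------------------------------------------------------
# fitting a whole study
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "subject",
    "scan",
    "model",
    "mode",
    "ktrans",
    "vp",
    "ve",
    "rel_fit_error_pct",
    "u_ktrans_pct",
    "u_vp_pct",
    "u_ve_pct",
    "converged",
    "n_voxels",
    "n_converged",
    "poor_quality",
]


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{what} not found: {path}")
    return path


def _fit_scan(series, mask, aif, config: StudyConfig, out_maps: Path | None, tag: str):
    """All (model, mode) fits for one scan; returns rows for the fits table."""
    rows = []
    opts = dict(
        error_normalization=config.error_normalization,
        optimizer=config.optimizer,
        grid_interval_s=config.grid_interval_s,
    )
    for model in config.models:
        if "voxel" in config.modes:
            vw = fit_voxelwise(series, mask, aif, model, **opts)
            frac_bad = 1.0 - vw.n_converged / vw.n_voxels
            poor = frac_bad > config.max_nonconverged_fraction
            if out_maps is not None:
                for name, vol in vw.maps.items():
                    nib.save(
                        nib.Nifti1Image(vol, np.eye(4)),
                        out_maps / f"{tag}_{model}_{name}.nii.gz",
                    )
            rows.append(
                {
                    "model": model,
                    "mode": "voxel",
                    "ktrans": vw.roi_mean["ktrans"],
                    "vp": vw.roi_mean.get("vp", np.nan),
                    "ve": vw.roi_mean.get("ve", np.nan),
                    "rel_fit_error_pct": vw.mean_rel_fit_error,
                    "u_ktrans_pct": vw.mean_rel_uncertainty.get("ktrans", np.nan),
                    "u_vp_pct": vw.mean_rel_uncertainty.get("vp", np.nan),
                    "u_ve_pct": vw.mean_rel_uncertainty.get("ve", np.nan),
                    "converged": True,
                    "n_voxels": vw.n_voxels,
                    "n_converged": vw.n_converged,
                    "poor_quality": poor,
                }
            )
        if "roi" in config.modes:
            res = fit_roibased(series, mask, aif, model, **opts)
            u = res.rel_uncertainty
            rows.append(
                {
                    "model": model,
                    "mode": "roi",
                    "ktrans": res.params.ktrans,
                    "vp": res.params.vp if res.params.vp is not None else np.nan,
                    "ve": res.params.ve if res.params.ve is not None else np.nan,
                    "rel_fit_error_pct": res.rel_fit_error,
                    "u_ktrans_pct": u.get("ktrans", np.nan),
                    "u_vp_pct": u.get("vp", np.nan),
                    "u_ve_pct": u.get("ve", np.nan),
                    "converged": res.converged,
                    "n_voxels": int(np.count_nonzero(mask)),
                    "n_converged": np.nan,
                    "poor_quality": not res.converged,
                }
            )
    return rows


def run_study(
    config: StudyConfig | str | Path,
    root: str | Path | None = None,
    out_dir: str | Path | None = None,
    write_maps: bool = True,
) -> ComparisonReport:
    """Fit every subject/scan of a study and build the comparison report.

    ``config`` may be a path to ``study.json`` (its parent becomes the
    study root) or a :class:`StudyConfig` with ``root`` given explicitly.
    Artifacts (fits.csv, parameter maps, report.json/csv) go to
    ``out_dir`` (default ``<root>/results``).  Subjects whose fits fail
    are skipped and recorded in the report's exclusion log; a study where
    every subject fails raises.
    """
    if not isinstance(config, StudyConfig):
        config_path = _require(Path(config), "study config")
        root = config_path.parent
        config = StudyConfig.from_json(config_path)
    elif root is None:
        raise ValueError("root directory required when passing a StudyConfig instance")
    root = Path(root)
    out = Path(out_dir) if out_dir is not None else root / "results"
    out.mkdir(parents=True, exist_ok=True)
    maps_dir = out / "maps" if write_maps else None
    if maps_dir is not None:
        maps_dir.mkdir(exist_ok=True)

    aif = ParkerAif.from_json(_require(root / config.aif_path, "AIF parameters"))
    unknown = set(config.models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown models in config: {sorted(unknown)}")

    all_rows: list[dict] = []
    exclusions: list[str] = []
    for subj in config.subjects:
        try:
            subj_rows = []
            for scan in subj.scans:
                scan_dir = _require(root / scan.path, "scan directory")
                _require(scan_dir / "series.nii.gz", "dynamic series")
                _require(scan_dir / "wall_mask.nii.gz", "vessel wall mask")
                series, mask = load_series(scan_dir)
                tag = f"{subj.subject_id}_{scan.scan_id}"
                rows = _fit_scan(series, mask, aif, config, maps_dir, tag)
                for r in rows:
                    r["subject"] = subj.subject_id
                    r["scan"] = scan.scan_id
                subj_rows.extend(rows)
            all_rows.extend(subj_rows)
        except (OSError, RuntimeError, ValueError) as exc:
            msg = f"{subj.subject_id}: {exc}"
            logger.warning("excluding subject %s", msg)
            exclusions.append(msg)
    if not all_rows:
        raise RuntimeError("all subjects failed; nothing to report")

    fits = pd.DataFrame(all_rows)[_CSV_COLUMNS]
    fits.to_csv(out / "fits.csv", index=False)

    diameters = {
        s.subject_id: s.diameter_mm for s in config.subjects if s.diameter_mm is not None
    }
    report = compare_models(
        fits,
        diameters=diameters or None,
        cv_pooling=config.cv_pooling,
        icc_form=config.icc_form,
    )
    report = report.model_copy(update={"exclusions": exclusions})
    (out / "report.json").write_text(report.model_dump_json(indent=2) + "\n")
    pd.DataFrame([s.model_dump() for s in report.summaries]).to_csv(
        out / "report.csv", index=False
    )
    return report


# ---------------------------------------------------------------------------
# model comparison (a pure function of the per-fit table)
# ---------------------------------------------------------------------------


def _first_scan_frame(fits: pd.DataFrame) -> pd.DataFrame:
    first = fits.sort_values("scan").groupby(["subject", "model", "mode"], sort=True).first()
    return first.reset_index()


def compare_models(
    fits: pd.DataFrame,
    diameters: dict | None = None,
    cv_pooling: str = "rms",
    icc_form: str = "icc1",
) -> ComparisonReport:
    """Build the comparison report from the tidy per-fit table.

    Uses each subject's first scan for cross-model statistics; rescans
    (when present) feed the reproducibility table.  Ties in fit error
    count 0.5 toward each model's win fraction; significance tests are
    suppressed below 5 common subjects.
    """
    first = _first_scan_frame(fits)
    summaries, pairwise, diam_rows = [], [], []

    for (model, mode), grp in first.groupby(["model", "mode"], sort=True):
        u = grp["u_ktrans_pct"].to_numpy(dtype=float)
        u = u[np.isfinite(u)]
        summaries.append(
            ModelSummary(
                model=model,
                mode=mode,
                n=len(grp),
                ktrans_mean=float(grp["ktrans"].mean()),
                ktrans_sd=float(grp["ktrans"].std(ddof=1)) if len(grp) > 1 else 0.0,
                fit_error_mean_pct=float(grp["rel_fit_error_pct"].mean()),
                fit_error_sd_pct=(
                    float(grp["rel_fit_error_pct"].std(ddof=1)) if len(grp) > 1 else 0.0
                ),
                u_ktrans_mean_pct=float(np.mean(u)) if u.size else None,
                u_ktrans_sd_pct=float(np.std(u, ddof=1)) if u.size > 1 else None,
            )
        )
        if diameters:
            merged = grp.assign(diameter=grp["subject"].map(diameters)).dropna(
                subset=["diameter"]
            )
            rho = p = None
            if len(merged) >= MIN_SUBJECTS_FOR_TESTS:
                rho, p = spearman_rho(merged["ktrans"], merged["diameter"])
            diam_rows.append(
                DiameterCorrelation(model=model, mode=mode, n=len(merged), rho=rho, p=p)
            )

    models_present = sorted(first["model"].unique())
    for mode, grp_mode in first.groupby("mode", sort=True):
        wide_err = grp_mode.pivot(index="subject", columns="model", values="rel_fit_error_pct")
        wide_kt = grp_mode.pivot(index="subject", columns="model", values="ktrans")
        for a, b in itertools.combinations(models_present, 2):
            common = wide_err[[a, b]].dropna()
            kt = wide_kt.loc[common.index, [a, b]]
            n = len(common)
            da = common[a].to_numpy()
            db = common[b].to_numpy()
            wins = float(np.sum(da < db) + 0.5 * np.sum(da == db))
            p_err = p_kt = rho = rho_p = None
            if n >= MIN_SUBJECTS_FOR_TESTS:
                if np.any(da != db):
                    _, p_err = wilcoxon_signed_rank(da, db)
                else:
                    p_err = 1.0
                ka, kb = kt[a].to_numpy(), kt[b].to_numpy()
                p_kt = wilcoxon_signed_rank(ka, kb)[1] if np.any(ka != kb) else 1.0
                try:
                    rho, rho_p = spearman_rho(ka, kb)
                except ValueError:
                    pass
            pairwise.append(
                PairwiseComparison(
                    model_a=a,
                    model_b=b,
                    mode=mode,
                    n=n,
                    p_fit_error=p_err,
                    p_ktrans=p_kt,
                    win_fraction_a=wins / n if n else 0.0,
                    ktrans_spearman_rho=rho,
                    ktrans_spearman_p=rho_p,
                )
            )

    repro_rows = []
    n_scans = fits.groupby("subject")["scan"].nunique()
    if (n_scans >= 2).sum() >= 3:  # ICC needs at least 3 complete subjects
        tidy = fits.rename(columns={})[["subject", "scan", "model", "mode", "ktrans"]]
        rep = reproducibility_report(tidy, pooling=cv_pooling, icc_form=icc_form)
        repro_rows = [ReproRow(**row) for row in rep.to_dict("records")]

    return ComparisonReport(
        summaries=summaries,
        pairwise=pairwise,
        diameter_correlations=diam_rows,
        reproducibility=repro_rows,
    )


# ---------------------------------------------------------------------------
# synthetic study writer (simulate -> directory layout run_study reads)
# ---------------------------------------------------------------------------


def write_synthetic_study(
    out_dir: str | Path,
    records,
    protocol,
    aif: ParkerAif,
    config: StudyConfig | None = None,
) -> Path:
    """Materialize a simulated cohort as an on-disk study.

    ``records`` come from :func:`dcewall.synthetic.simulate_cohort` with
    rendering enabled.  Writes per-scan NIfTI series + masks + sidecars,
    the AIF, ground truth CSV, and ``study.json``.
    """
    from .synthetic import cohort_truth_frame

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    subjects = []
    for rec in records:
        if not rec.series:
            raise ValueError("cohort was simulated without rendering; nothing to write")
        scans = []
        for s, (series, truth) in enumerate(zip(rec.series, rec.truths), start=1):
            rel = f"subjects/{rec.subject_id}/scan{s}"
            save_series(
                root / rel,
                series,
                wall_mask=truth["wall_mask"],
                lumen_mask=truth["lumen_mask"],
            )
            scans.append(ScanEntry(scan_id=f"scan{s}", path=rel))
        subjects.append(
            SubjectEntry(subject_id=rec.subject_id, diameter_mm=rec.diameter_mm, scans=scans)
        )
    aif.to_json(root / "aif.json")
    cohort_truth_frame(records).to_csv(root / "truth.csv", index=False)
    config = config or StudyConfig(subjects=subjects)
    config = config.model_copy(update={"subjects": subjects})
    config.to_json(root / "study.json")
    return root
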