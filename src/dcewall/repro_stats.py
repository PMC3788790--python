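"""Scan-rescan reproducibility and nonparametric comparison statistics.

Covers the statistical toolkit for comparing pharmacokinetic models and
assessing K^trans repeatability: within-subject coefficient of variation,
intraclass correlation (one-way random, single measurement, with a two-way
agreement option), the paired Wilcoxon signed-rank test (exact null by
rank-sum enumeration for small n), and Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReproRecord",
    "PairedSample",
    "coefficient_of_variation",
    "icc",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "reproducibility_report",
]


@dataclass(frozen=True)
class ReproRecord:
    """One subject's paired scan-rescan measurements (same units)."""

    subject: str
    scan1: float
    scan2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scan1) and np.isfinite(self.scan2)):
            raise ValueError("scan values must be finite")


@dataclass(frozen=True)
class PairedSample:
    """Per-subject values under two conditions (models, or value vs size)."""

    a: tuple
    b: tuple

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("paired sample requires equal lengths")
        if not np.all(np.isfinite(self.a)) or not np.all(np.isfinite(self.b)):
            raise ValueError("paired values must be finite")

    @classmethod
    def of(cls, a, b) -> "PairedSample":
        return cls(tuple(float(x) for x in a), tuple(float(x) for x in b))


def _pairs_matrix(records) -> np.ndarray:
    if len(records) == 0:
        raise ValueError("no records")
    if isinstance(records[0], ReproRecord):
        return np.array([[r.scan1, r.scan2] for r in records], dtype=float)
    return np.asarray(records, dtype=float)


def coefficient_of_variation(records, pooling: str = "rms") -> float:
    """Within-subject coefficient of variation in percent.

    The within-subject SD of a scan pair is |x₁−x₂|/√2.  With
    ``pooling="rms"`` (default, the standard repeatability convention) the
    overall within-subject SD is the root of the mean within-subject
    variance; ``pooling="mean"`` takes the arithmetic mean of the
    per-subject SDs instead.  Either way, CV = 100 · pooled SD / grand
    mean of all measurements.  Scale-invariant; requires a positive grand
    mean.
    """
    x = _pairs_matrix(records)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    within_sd = np.abs(x[:, 0] - x[:, 1]) / np.sqrt(2.0)
    grand_mean = float(np.mean(x))
    if grand_mean <= 0:
        raise ValueError("grand mean must be positive for a CV")
    if pooling == "rms":
        pooled = float(np.sqrt(np.mean(within_sd**2)))
    elif pooling == "mean":
        pooled = float(np.mean(within_sd))
    else:
        raise ValueError("pooling must be 'rms' or 'mean'")
    return 100.0 * pooled / grand_mean


def icc(records, form: str = "icc1") -> float:
    """Intraclass correlation of paired scan-rescan measurements.

    ``form="icc1"`` (default): one-way random effects, single measurement
    — for k = 2 scans, (MSB − MSW)/(MSB + MSW) from the ANOVA
    decomposition.  ``form="icc_a1"``: two-way random effects, absolute
    agreement, single measurement.
    """
    x = _pairs_matrix(records)
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects for an ICC")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - subj_means[:, None]) ** 2) / (n * (k - 1))
    if msb + msw == 0:
        raise ValueError("zero total variance: ICC undefined")
    if form == "icc1":
        return float((msb - msw) / (msb + (k - 1) * msw))
    if form == "icc_a1":
        scan_means = x.mean(axis=0)
        msc = n * np.sum((scan_means - grand) ** 2) / (k - 1)
        sse = np.sum((x - subj_means[:, None] - scan_means[None, :] + grand) ** 2)
        mse = sse / ((n - 1) * (k - 1))
        denom = msb + (k - 1) * mse + (k / n) * (msc - mse)
        return float((msb - mse) / denom)
    raise ValueError("form must be 'icc1' or 'icc_a1'")


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Exact null pmf of the positive rank sum over all 2^n sign patterns.

    Ranks are doubled so mid-ranks from ties become integers; entry ``w``
    of the result is P(2·W⁺ = w).
    """
    total = int(doubled_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt / 2.0
    return pmf


def wilcoxon_signed_rank(a, b=None, exact_max_n: int = 25) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W⁺, two-sided p).

    Zero differences are dropped (Wilcoxon's rule).  For n ≤
    ``exact_max_n`` the null distribution of the positive rank sum is
    enumerated exactly (mid-ranks supported); larger samples use the
    normal approximation with tie and continuity corrections.  Two-sided
    p is twice the smaller tail, capped at 1.
    """
    if isinstance(a, PairedSample):
        d = np.asarray(a.a, float) - np.asarray(a.b, float)
    elif b is not None:
        d = np.asarray(a, float) - np.asarray(b, float)
    else:
        d = np.asarray(a, float)
    d = d[np.isfinite(d)]
    nonzero = d[d != 0.0]
    if nonzero.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    if nonzero.size < 5:
        raise ValueError("need at least 5 non-zero differences")
    n = nonzero.size
    ranks = stats.rankdata(np.abs(nonzero))
    w_plus = float(np.sum(ranks[nonzero > 0]))

    if n <= exact_max_n:
        doubled = np.rint(2 * ranks).astype(int)
        pmf = _signed_rank_distribution(doubled)
        w2 = int(round(2 * w_plus))
        lower = pmf[: w2 + 1].sum()
        upper = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
        return w_plus, float(p)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    # continuity correction toward the mean
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return w_plus, float(min(1.0, p))


def spearman_rho(a, b=None, method: str = "t") -> tuple[float, float]:
    """Spearman rank correlation; returns (ρ, two-sided p).

    ρ is the Pearson correlation of mid-ranks.  ``method="t"`` uses the
    t approximation with n−2 degrees of freedom (adequate for cohort-size
    samples); ``method="exact"`` runs an exact pairing permutation test
    for n ≤ 10.  Constant inputs leave ρ undefined (ValueError).
    """
    if isinstance(a, PairedSample):
        x, y = np.asarray(a.a, float), np.asarray(a.b, float)
    else:
        x, y = np.asarray(a, float), np.asarray(b, float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) > 1.0 - 1e-12:  # snap exact monotone data to +/-1
        rho = float(np.sign(rho))

    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        res = stats.permutation_test(
            (rx, ry),
            lambda u, v: np.corrcoef(u, v)[0, 1],
            permutation_type="pairings",
            n_resamples=np.inf,
            alternative="two-sided",
        )
        return rho, float(res.pvalue)

    if abs(rho) >= 1.0 - 1e-14:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


def reproducibility_report(
    results: pd.DataFrame,
    value_col: str = "ktrans",
    pooling: str = "rms",
    icc_form: str = "icc1",
) -> pd.DataFrame:
    """ICC and CV per (model, mode) from tidy per-scan results.

    ``results`` needs columns subject, scan, model, mode and
    ``value_col``; exactly two scans per subject are used, subjects with a
    missing rescan are dropped with a warning.  Returns one row per
    (model, mode) with columns icc and cv_pct.
    """
    required = {"subject", "scan", "model", "mode", value_col}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results frame is missing columns: {sorted(missing)}")
    rows = []
    for (model, mode), grp in results.groupby(["model", "mode"], sort=True):
        wide = grp.pivot_table(index="subject", columns="scan", values=value_col)
        complete = wide.dropna()
        dropped = set(wide.index) - set(complete.index)
        if dropped:
            warnings.warn(
                f"{model}/{mode}: dropping subjects without a rescan: {sorted(dropped)}",
                stacklevel=2,
            )
        pairs = complete.to_numpy()[:, :2]
        rows.append(
            {
                "model": model,
                "mode": mode,
                "n_subjects": pairs.shape[0],
                "icc": icc(pairs, form=icc_form),
                "cv_pct": coefficient_of_variation(pairs, pooling=pooling),
            }
        )
    return pd.DataFrame(rows)
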