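import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dcewall import (
    PairedSample,
    ReproRecord,
    coefficient_of_variation,
    icc,
    reproducibility_report,
    spearman_rho,
    wilcoxon_signed_rank,
)


def wilcoxon_enumeration_oracle(d):
    """Two-sided exact p by brute-force enumeration of all sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in
         itertools.product([False, True], repeat=n)]
    )
    lower = np.mean(ws <= w_obs + 1e-12)
    upper = np.mean(ws >= w_obs - 1e-12)
    return w_obs, min(1.0, 2 * min(lower, upper))


def rank_oracle(x):
    """Independent mid-rank computation."""
    x = np.asarray(x, float)
    out = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        out[i] = less + (equal + 1) / 2.0
    return out


class TestCV:
    def test_identical_pairs_zero(self):
        recs = [ReproRecord("a", 0.04, 0.04), ReproRecord("b", 0.02, 0.02)]
        assert coefficient_of_variation(recs) == 0.0

    def test_hand_worked_example_mean_pooling(self):
        """Arithmetic-mean pooling: within SDs {0.00707, 0}, grand mean 0.0325."""
        recs = [ReproRecord("a", 0.04, 0.05), ReproRecord("b", 0.02, 0.02)]
        assert coefficient_of_variation(recs, pooling="mean") == pytest.approx(
            10.879, abs=1e-3
        )

    def test_rms_pooling_hand_example(self):
        recs = [(0.04, 0.05), (0.02, 0.02)]
        within_var = ((0.01 / np.sqrt(2)) ** 2 + 0.0) / 2
        expected = 100 * np.sqrt(within_var) / 0.0325
        assert coefficient_of_variation(recs) == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, c):
        pairs = np.array([[0.04, 0.05], [0.02, 0.03], [0.06, 0.055]])
        for pooling in ("rms", "mean"):
            assert coefficient_of_variation(pairs * c, pooling) == pytest.approx(
                coefficient_of_variation(pairs, pooling), rel=1e-9
            )

    def test_nonpositive_grand_mean_rejected(self):
        with pytest.raises(ValueError, match="grand mean"):
            coefficient_of_variation([(-1.0, -2.0), (0.5, 0.5)])

    def test_estimator_recovers_generative_cv(self, rng):
        """Mean over replicate cohorts tracks the generative within-subject CV."""
        target = 0.22
        sigma2 = np.log1p(target**2)
        cvs = []
        for _ in range(400):
            subj = rng.lognormal(np.log(0.043), 0.35, 10)
            x = subj[:, None] * rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), (10, 2))
            cvs.append(coefficient_of_variation(x))
        assert np.mean(cvs) == pytest.approx(22.0, abs=1.5)


class TestIcc:
    def test_perfect_agreement(self):
        pairs = [(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)]
        assert icc(pairs) == pytest.approx(1.0)

    def test_pure_noise_has_near_zero_icc(self, rng):
        x = rng.normal(0.0, 1.0, (10_000, 2))
        assert abs(icc(x)) < 0.05

    def test_variance_ratio_recovery(self, rng):
        """ICC(1,1) estimates sigma_b^2/(sigma_b^2+sigma_w^2)."""
        vals = []
        for _ in range(300):
            subj = rng.normal(0, np.sqrt(0.7), 60)
            x = subj[:, None] + rng.normal(0, np.sqrt(0.3), (60, 2))
            vals.append(icc(x))
        assert np.mean(vals) == pytest.approx(0.7, abs=0.03)

    def test_affine_invariance(self):
        pairs = np.array([[0.03, 0.04], [0.05, 0.045], [0.02, 0.025], [0.07, 0.06]])
        assert icc(pairs * 3.0 + 10.0) == pytest.approx(icc(pairs), rel=1e-9)
        assert icc(pairs * 3.0 + 10.0, form="icc_a1") == pytest.approx(
            icc(pairs, form="icc_a1"), rel=1e-9
        )

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        pairs = rng.normal(0.05, 0.02, (12, 2)) + rng.normal(0, 0.01, (12, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["s1", "s2"], 12),
                "value": pairs.reshape(-1),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="value")
        icc1_ref = ref.loc[ref["Type"].str.replace("(", "").str.startswith("ICC1"),
                           "ICC"].iloc[0]
        assert icc(pairs) == pytest.approx(icc1_ref, abs=1e-9)
        icca_ref = ref.loc[ref["Type"].str.replace("(", "").str.startswith("ICCA"),
                           "ICC"].iloc[0]
        assert icc(pairs, form="icc_a1") == pytest.approx(icca_ref, abs=1e-9)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc([(1.0, 2.0), (2.0, 1.0)])


class TestWilcoxon:
    def test_n5_all_positive_exact(self):
        w, p = wilcoxon_signed_rank(np.array([1.0, 2.0, 0.5, 3.0, 1.5]))
        assert w == 15.0
        assert p == pytest.approx(2.0 / 32.0)

    def test_antisymmetry(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.3, 1, 10)
        _, p1 = wilcoxon_signed_rank(a, b)
        _, p2 = wilcoxon_signed_rank(b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)

    @pytest.mark.parametrize("n", range(5, 13))
    def test_matches_enumeration_oracle(self, n, rng):
        for _ in range(5):
            d = np.round(rng.normal(0.2, 1.0, n), 2)
            d = np.where(d == 0, 0.11, d)
            w, p = wilcoxon_signed_rank(d)
            w_ref, p_ref = wilcoxon_enumeration_oracle(d)
            assert w == pytest.approx(w_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_matches_scipy_exact_when_no_ties(self, rng):
        d = rng.normal(0.5, 1.0, 14)
        assert np.unique(np.abs(d)).size == 14
        _, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_handles_ties_in_exact_path(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, -0.5, 3.0])
        w, p = wilcoxon_signed_rank(d)
        w_ref, p_ref = wilcoxon_enumeration_oracle(d)
        assert (w, p) == (pytest.approx(w_ref), pytest.approx(p_ref))

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="zero"):
            w, p = wilcoxon_signed_rank(np.zeros(8))
        assert p == 1.0

    def test_large_sample_normal_approximation(self, rng):
        d = rng.normal(0.3, 1.0, 60)
        _, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, p = spearman_rho(x, np.exp(x))
        assert rho == 1.0 and p == 0.0
        rho, _ = spearman_rho(x, -np.sqrt(x))
        assert rho == -1.0

    def test_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        rho, p = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_match_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 5.0, 6.0, 6.0])
        rho, _ = spearman_rho(x, y)
        rx, ry = rank_oracle(x), rank_oracle(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho(np.ones(6), np.arange(6.0))

    def test_exact_permutation_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p_exact = spearman_rho(x, y, method="exact")
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert 0.0 < p_exact <= 1.0


class TestReport:
    def _frame(self, pairs_by_model):
        rows = []
        for model, pairs in pairs_by_model.items():
            for i, (a, b) in enumerate(pairs):
                rows += [
                    {"subject": f"s{i}", "scan": "scan1", "model": model,
                     "mode": "voxel", "ktrans": a},
                    {"subject": f"s{i}", "scan": "scan2", "model": model,
                     "mode": "voxel", "ktrans": b},
                ]
        return pd.DataFrame(rows)

    def test_zero_noise_cohort(self):
        pairs = [(0.03, 0.03), (0.05, 0.05), (0.02, 0.02), (0.06, 0.06)]
        rep = reproducibility_report(self._frame({"patlak": pairs}))
        assert rep.loc[0, "cv_pct"] == 0.0
        assert rep.loc[0, "icc"] == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        pairs = [(0.03, 0.04), (0.05, 0.045), (0.02, 0.03), (0.06, 0.05)]
        rep1 = reproducibility_report(self._frame({"patlak": pairs}))
        rep2 = reproducibility_report(self._frame({"patlak": pairs[::-1]}))
        assert rep1.loc[0, "icc"] == pytest.approx(rep2.loc[0, "icc"])
        assert rep1.loc[0, "cv_pct"] == pytest.approx(rep2.loc[0, "cv_pct"])

    def test_missing_rescan_dropped_with_warning(self):
        df = self._frame(
            {"patlak": [(0.03, 0.04), (0.05, 0.045), (0.02, 0.03), (0.06, 0.05)]}
        )
        df = df.drop(df[(df.subject == "s3") & (df.scan == "scan2")].index)
        with pytest.warns(UserWarning, match="rescan"):
            rep = reproducibility_report(df)
        assert rep.loc[0, "n_subjects"] == 3

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            reproducibility_report(pd.DataFrame({"subject": [], "scan": []}))


def test_paired_sample_validation():
    with pytest.raises(ValueError):
        PairedSample.of([1.0, 2.0], [1.0])
    s = PairedSample.of([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
    w, p = wilcoxon_signed_rank(s)
    assert 0 < p <= 1
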