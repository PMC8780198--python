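"""Agreement/reliability statistics vs independent oracles.

Oracles used here are deliberately written on different routes than the
package: Krippendorff's alpha by direct enumeration of pairable values (no
coincidence matrix), ICC by an explicit ANOVA sums-of-squares recomputation
plus the pingouin reference, Fleiss' kappa against statsmodels.
"""

import math

import numpy as np
import pandas as pd
import pytest

from proxiscale import (
    GradeScale,
    bland_altman,
    confusion_matrix,
    fleiss_kappa,
    icc_2k,
    krippendorff_alpha,
    percent_agreement,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def alpha_pair_enumeration(matrix, metric="nominal"):
    """Krippendorff's alpha by brute-force enumeration of rating pairs."""
    units = [row[~np.isnan(row)] for row in np.asarray(matrix, dtype=float)]
    units = [u for u in units if u.size >= 2]
    pooled = np.concatenate(units)
    values = np.unique(pooled)
    # margin counts: every pairable value contributes exactly once
    n_c = {v: float((pooled == v).sum()) for v in values}
    n = float(pooled.size)

    def delta(a, b):
        if metric == "nominal":
            return 0.0 if a == b else 1.0
        if metric == "interval":
            return (a - b) ** 2
        if metric == "ordinal":
            if a == b:
                return 0.0
            lo, hi = min(a, b), max(a, b)
            s = sum(n_c[v] for v in values if lo <= v <= hi)
            return (s - (n_c[lo] + n_c[hi]) / 2.0) ** 2
        raise ValueError(metric)

    d_o = 0.0
    for u in units:
        m = u.size
        d_o += sum(
            delta(u[i], u[j]) for i in range(m) for j in range(m) if i != j
        ) / (m - 1)
    d_o /= n
    d_e = sum(
        delta(a, b) * n_c[a] * (n_c[b] - (a == b)) for a in values for b in values
    ) / (n * (n - 1))
    return 1.0 - d_o / d_e


def icc2k_anova_oracle(matrix):
    """ICC(2,k) point estimate from an explicit cell-by-cell ANOVA."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_rows = sum(k * (np.mean(m[i]) - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (np.mean(m[:, j]) - grand) ** 2 for j in range(k))
    ss_err = sum(
        (m[i, j] - np.mean(m[i]) - np.mean(m[:, j]) + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


# ---------------------------------------------------------------------------
# percent agreement
# ---------------------------------------------------------------------------


class TestPercentAgreement:
    def test_identical_vectors(self):
        assert percent_agreement([9] * 10, [9] * 10) == 1.0

    def test_half_agreement(self):
        assert percent_agreement((9, 9, 8, 8), (9, 8, 8, 9)) == 0.5

    def test_pairwise_complete_only(self):
        assert percent_agreement([9, np.nan, 8], [9, 7, 7]) == 0.5

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            percent_agreement([9, 8], [9])

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            percent_agreement([np.nan], [5.0])


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.mean_diff, r.sd_diff, r.loa_low, r.loa_high) == (0, 0, 0, 0)

    def test_hand_arithmetic(self):
        r = bland_altman([1.0, 0.0], [0.0, 1.0])  # d = (1, -1)
        assert r.mean_diff == 0.0
        assert r.sd_diff == pytest.approx(math.sqrt(2))
        assert r.loa_high == pytest.approx(2.7719, abs=1e-4)
        assert r.loa_low == pytest.approx(-2.7719, abs=1e-4)

    def test_translation_equivariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = bland_altman(x, y)
        shift = bland_altman(x + 5.5, y)
        assert shift.mean_diff == pytest.approx(base.mean_diff + 5.5, abs=1e-9)
        assert shift.loa_low == pytest.approx(base.loa_low + 5.5, abs=1e-9)
        assert shift.loa_high == pytest.approx(base.loa_high + 5.5, abs=1e-9)

    def test_loa_brackets_mean(self, rng):
        r = bland_altman(rng.normal(size=20), rng.normal(size=20))
        assert r.loa_low <= r.mean_diff <= r.loa_high

    def test_single_pair_errors(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


# ---------------------------------------------------------------------------
# ICC(2, k)
# ---------------------------------------------------------------------------


class TestICC2k:
    def test_identical_columns_give_one(self):
        m = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
        assert icc_2k(m).icc == pytest.approx(1.0)

    def test_rater_offsets_without_noise_closed_form(self):
        """Zero residual noise: absolute-agreement ICC(2,k) equals the
        closed form MS_R / (MS_R + MS_C / n); systematic rater offsets keep
        it strictly below 1."""
        subj = np.array([1.0, 2.0, 3.0, 4.0])
        offs = np.array([0.0, 0.5, -0.3])
        m = subj[:, None] + offs[None, :]
        n, k = m.shape
        msr = k * np.var(subj, ddof=1)
        msc = n * np.var(offs + subj.mean(), ddof=1)
        assert icc_2k(m).icc == pytest.approx(msr / (msr + msc / n), abs=1e-9)
        # without offsets the same table gives exactly 1
        assert icc_2k(np.tile(subj[:, None], (1, 3))).icc == pytest.approx(1.0, abs=1e-12)

    def test_matches_anova_oracle_on_random_tables(self, rng):
        for _ in range(100):
            n = rng.integers(4, 12)
            k = rng.integers(2, 6)
            m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            assert icc_2k(m).icc == pytest.approx(icc2k_anova_oracle(m), abs=1e-10)

    def test_matches_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for seed in range(10):
            r = np.random.default_rng(seed)
            n, k = 8, 3
            m = r.normal(size=(n, k)) + r.normal(size=(n, 1))
            long = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), k),
                    "rater": np.tile(np.arange(k), n),
                    "score": m.ravel(),
                }
            )
            icc_all = pingouin.intraclass_corr(
                long, targets="subject", raters="rater", ratings="score"
            ).set_index("Type")
            # two-way random, average measures: labeled ICC2k or ICC(A,k)
            label = "ICC2k" if "ICC2k" in icc_all.index else "ICC(A,k)"
            ref = icc_all.loc[label]
            res = icc_2k(m)
            assert res.icc == pytest.approx(ref["ICC"], abs=1e-9)
            assert res.p_value == pytest.approx(ref["pval"], abs=1e-9)
            lo, hi = ref["CI95%"] if "CI95%" in ref.index else ref["CI95"]
            assert res.ci_low == pytest.approx(lo, abs=5e-3)  # pingouin rounds CIs
            assert res.ci_high == pytest.approx(hi, abs=5e-3)

    def test_ci_brackets_estimate(self, rng):
        m = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        r = icc_2k(m)
        assert r.ci_low <= r.icc <= r.ci_high <= 1.0

    def test_missing_entries_rejected(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError):
            icc_2k(m)

    def test_zero_subject_variance_warns(self):
        m = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        with pytest.warns(UserWarning, match="zero between-subject"):
            assert icc_2k(m).icc == 0.0


# ---------------------------------------------------------------------------
# Krippendorff's alpha
# ---------------------------------------------------------------------------


class TestKrippendorffAlpha:
    def test_perfect_agreement(self):
        m = np.tile(np.array([[9.0], [8.0], [7.0], [9.0]]), (1, 3))
        for metric in ("nominal", "ordinal", "interval"):
            assert krippendorff_alpha(m, metric) == pytest.approx(1.0)

    def test_two_by_two_hand_value(self):
        """Two raters on two items, ratings (1,2) and (2,1): alpha = -0.5."""
        m = np.array([[1.0, 2.0], [2.0, 1.0]])
        assert krippendorff_alpha(m, "nominal") == pytest.approx(-0.5)

    def test_missing_rater_column_ignored(self):
        m = np.array([[9.0, 9.0], [8.0, 7.0], [9.0, 9.0], [7.0, 7.0]])
        m_ext = np.column_stack([m, np.full(4, np.nan)])
        assert krippendorff_alpha(m_ext) == pytest.approx(krippendorff_alpha(m))

    def test_subjects_with_single_rating_dropped(self):
        m = np.array([[9.0, 9.0], [8.0, np.nan], [7.0, 7.0], [9.0, 8.0]])
        kept = np.array([[9.0, 9.0], [7.0, 7.0], [9.0, 8.0]])
        assert krippendorff_alpha(m) == pytest.approx(krippendorff_alpha(kept))

    def test_single_category_errors(self):
        with pytest.raises(ValueError):
            krippendorff_alpha(np.full((4, 3), 9.0))

    @pytest.mark.parametrize("metric", ["nominal", "ordinal", "interval"])
    def test_matches_pair_enumeration_oracle(self, rng, metric):
        """50 random tables with missing data agree with the independent
        pair-enumeration computation to 1e-9."""
        for _ in range(50):
            n = rng.integers(4, 12)
            k = rng.integers(2, 5)
            m = rng.integers(1, 5, size=(n, k)).astype(float)
            mask = rng.uniform(size=m.shape) < 0.15
            m[mask] = np.nan
            if np.unique(m[~np.isnan(m)]).size < 2:
                continue
            try:
                ours = krippendorff_alpha(m, metric)
            except ValueError:
                continue
            assert ours == pytest.approx(alpha_pair_enumeration(m, metric), abs=1e-9)

    def test_random_raters_alpha_near_zero(self):
        """Chance correction: two independent uniform raters over 10,000
        subjects give alpha ~ 0 within Monte-Carlo error."""
        r = np.random.default_rng(0)
        m = r.integers(1, 5, size=(10_000, 2)).astype(float)
        assert abs(krippendorff_alpha(m, "nominal")) < 0.03

    def test_ordinal_at_least_nominal_for_adjacent_disagreements(self):
        """When all disagreements are adjacent-category slips, the ordinal
        metric penalizes them less than the nominal metric."""
        r = np.random.default_rng(1)
        base = r.integers(2, 5, size=200).astype(float)
        partner = base.copy()
        flip = r.uniform(size=200) < 0.3
        partner[flip] += r.choice([-1.0, 1.0], size=flip.sum())
        m = np.column_stack([base, partner])
        assert krippendorff_alpha(m, "ordinal") >= krippendorff_alpha(m, "nominal")


# ---------------------------------------------------------------------------
# Fleiss' kappa
# ---------------------------------------------------------------------------


class TestFleissKappa:
    def test_unanimous_raters(self):
        m = np.tile(np.array([[9.0], [8.0], [7.0], [9.0]]), (1, 3))
        assert fleiss_kappa(m) == pytest.approx(1.0)

    def test_two_by_two_hand_value(self):
        """Subjects (1,2) and (2,1): P-bar = 0, P-bar_e = 0.5, kappa = -1."""
        m = np.array([[1.0, 2.0], [2.0, 1.0]])
        assert fleiss_kappa(m) == pytest.approx(-1.0)

    def test_relabeling_invariance(self, rng):
        m = rng.integers(1, 4, size=(20, 3)).astype(float)
        relabeled = np.select([m == 1, m == 2, m == 3], [7.0, 5.0, 9.0])
        assert fleiss_kappa(m) == pytest.approx(fleiss_kappa(relabeled))

    def test_matches_statsmodels_reference(self, rng):
        inter_rater = pytest.importorskip("statsmodels.stats.inter_rater")
        for _ in range(20):
            m = rng.integers(1, 5, size=(12, 4)).astype(float)
            agg, _ = inter_rater.aggregate_raters(m.astype(int))
            assert fleiss_kappa(m) == pytest.approx(
                inter_rater.fleiss_kappa(agg), abs=1e-12
            )

    def test_single_category_errors(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.full((4, 3), 9.0))

    def test_unequal_rater_counts_rejected(self):
        m = np.array([[9.0, 8.0], [7.0, np.nan]])
        with pytest.raises(ValueError):
            fleiss_kappa(m)


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------


class TestConfusionMatrix:
    def test_identical_vectors_diagonal(self):
        scale = GradeScale()
        ratings = [9, 8, 7, 5, 9, 9]
        cm = confusion_matrix(ratings, ratings, scale)
        assert np.array_equal(cm, np.diag([1, 1, 1, 3]))

    def test_trace_identity_with_percent_agreement(self, rng):
        scale = GradeScale()
        grades = np.array(scale.grades)
        for _ in range(1000):
            n = rng.integers(2, 30)
            a = rng.choice(grades, size=n)
            b = rng.choice(grades, size=n)
            cm = confusion_matrix(a, b, scale)
            assert np.trace(cm) / cm.sum() == pytest.approx(percent_agreement(a, b))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            confusion_matrix([], [], GradeScale())

    def test_label_outside_scale_errors(self):
        with pytest.raises(ValueError):
            confusion_matrix([9, 6], [9, 9], GradeScale())
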