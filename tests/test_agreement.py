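import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gmedge import tables
from gmedge.agreement import (
    CONCORDANCE_ORDER,
    AgreementEstimate,
    ConcordanceCounts,
    DegenerateAgreementError,
    chi2_2x2,
    cohen_kappa,
    concordance_counts,
    fleiss_kappa_fixed,
    icc_single_absolute,
    matrix_to_category_counts,
    median_of,
    paired_t,
    pairwise_summary,
    ratings_matrix,
    unanimity_proportion,
)

# ---------------------------------------------------------------------------
# independent from-definition oracles


def oracle_cohen_kappa(x, y, k, linear=False):
    n = len(x)
    p = np.zeros((k, k))
    for xi, yi in zip(x, y):
        p[int(xi) - 1, int(yi) - 1] += 1 / n
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            w = 1 - abs(i - j) / (k - 1) if linear else float(i == j)
            po += w * p[i, j]
            pe += w * p[i, :].sum() * p[:, j].sum()
    return (po - pe) / (1 - pe)


def oracle_fleiss(counts):
    """Spreadsheet-style step-by-step multirater kappa."""
    counts = np.asarray(counts, float)
    N, k = counts.shape
    m = counts[0].sum()
    P_i = [(row * (row - 1)).sum() / (m * (m - 1)) for row in counts]
    P_bar = sum(P_i) / N
    p_j = counts.sum(axis=0) / (N * m)
    P_e = sum(p**2 for p in p_j)
    return (P_bar - P_e) / (1 - P_e)


def oracle_icc_a1(data):
    """Sums of squares computed by definition loops."""
    data = np.asarray(data, float)
    n, m = data.shape
    grand = data.mean()
    ss_rows = sum(m * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(m))
    ss_tot = sum((v - grand) ** 2 for v in data.ravel())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (m - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (m - 1))
    return (msr - mse) / (msr + (m - 1) * mse + (m / n) * (msc - mse))


def random_panel(rng, n, m, k):
    return rng.integers(1, k + 1, size=(n, m)).astype(float)


# ---------------------------------------------------------------------------


class TestCohenKappa:
    @pytest.mark.parametrize("weighting", ["none", "linear"])
    def test_perfect_agreement(self, rng, weighting):
        x = rng.integers(1, 6, 30)
        est = cohen_kappa(x, x, k=5, weighting=weighting)
        assert est.value == pytest.approx(1.0)

    def test_2x2_table_against_definition(self):
        # cross-table (25, 5; 5, 25)
        x = np.repeat([1, 1, 2, 2], [25, 5, 5, 25])
        y = np.repeat([1, 2, 1, 2], [25, 5, 5, 25])
        est = cohen_kappa(x, y, k=2)
        assert est.value == pytest.approx(oracle_cohen_kappa(x, y, 2))
        assert est.value == pytest.approx(2 / 3)  # (0.833-0.5)/(1-0.5)

    def test_linear_weighting_credits_near_misses(self, rng):
        x = rng.integers(1, 5, 40)
        y = x + 1  # always exactly one category apart
        linear = cohen_kappa(x, y, k=5, weighting="linear")
        unweighted = cohen_kappa(x, y, k=5, weighting="none")
        assert linear.value > unweighted.value

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("weighting", ["none", "linear"])
    def test_matches_statsmodels_point_and_se(self, seed, weighting):
        sm_ir = pytest.importorskip("statsmodels.stats.inter_rater")
        rng = np.random.default_rng(seed)
        k = 4
        x = rng.integers(1, k + 1, 30)
        y = np.clip(x + rng.integers(-1, 2, 30), 1, k)
        table = np.zeros((k, k))
        for xi, yi in zip(x, y):
            table[xi - 1, yi - 1] += 1
        sm = sm_ir.cohens_kappa(table, wt=None if weighting == "none" else "linear")
        est = cohen_kappa(x, y, k=k, weighting=weighting)
        assert est.value == pytest.approx(sm.kappa, abs=1e-10)
        assert est.se == pytest.approx(np.sqrt(sm.var_kappa), abs=1e-10)

    def test_binary_weighted_equals_unweighted(self, rng):
        x = rng.integers(1, 3, 50)
        y = rng.integers(1, 3, 50)
        a = cohen_kappa(x, y, k=2, weighting="none")
        b = cohen_kappa(x, y, k=2, weighting="linear")
        assert a.value == pytest.approx(b.value)

    def test_missing_pairs_dropped(self):
        x = np.array([1, 2, np.nan, 2, 1, 2])
        y = np.array([1, 2, 1, np.nan, 1, 2])
        est = cohen_kappa(x, y, k=2)
        assert est.n == 4 and est.value == pytest.approx(1.0)

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateAgreementError):
            cohen_kappa([1, 1, 1], [1, 1, 1], k=1)


class TestFleissKappa:
    def test_published_std_counts(self):
        counts = ConcordanceCounts((47, 5, 3, 4, 11, 50)).to_category_counts()
        est = fleiss_kappa_fixed(counts)
        assert round(est.value, 2) == 0.82
        assert round(est.ci_low, 2) == 0.77 and round(est.ci_high, 2) == 0.88

    def test_published_gmedge_counts(self):
        counts = ConcordanceCounts((51, 4, 1, 0, 5, 58)).to_category_counts()
        est = fleiss_kappa_fixed(counts)
        assert round(est.value, 2) == 0.93
        assert round(est.ci_low, 2) == 0.87 and round(est.ci_high, 2) == 0.99

    def test_unanimous_panels_give_kappa_one(self):
        counts = np.array([[5, 0]] * 4 + [[0, 5]] * 6, dtype=float)
        assert fleiss_kappa_fixed(counts).value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_stepwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(3, [0.4, 0.6], size=8).astype(float)
        est = fleiss_kappa_fixed(counts)
        assert est.value == pytest.approx(oracle_fleiss(counts), abs=1e-12)

    def test_matches_statsmodels_point(self, rng):
        sm_ir = pytest.importorskip("statsmodels.stats.inter_rater")
        counts = rng.multinomial(5, [0.3, 0.5, 0.2], size=15).astype(float)
        est = fleiss_kappa_fixed(counts)
        assert est.value == pytest.approx(sm_ir.fleiss_kappa(counts, method="fleiss"))

    def test_unequal_rating_counts_rejected(self):
        with pytest.raises(ValueError, match="fixed panel"):
            fleiss_kappa_fixed(np.array([[3, 2], [2, 2]], float))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_label_swap_invariance(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(5, [0.5, 0.5], size=10).astype(float)
        a = fleiss_kappa_fixed(counts)
        b = fleiss_kappa_fixed(counts[:, ::-1])
        assert a.value == pytest.approx(b.value, abs=1e-12)
        assert -1 <= a.value <= 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_subject_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(4, [0.6, 0.4], size=9).astype(float)
        a = fleiss_kappa_fixed(counts)
        b = fleiss_kappa_fixed(counts[rng.permutation(9)])
        assert a.value == pytest.approx(b.value, abs=1e-12)


class TestICC:
    def test_identical_raters_perfect(self):
        data = np.tile(np.arange(1.0, 7.0)[:, None], (1, 3))
        assert icc_single_absolute(data).value == pytest.approx(1.0)

    def test_matches_anova_oracle(self, rng):
        data = random_panel(rng, 6, 3, 5)
        est = icc_single_absolute(data)
        assert est.value == pytest.approx(oracle_icc_a1(data), abs=1e-12)

    def test_matches_pingouin_with_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        data = random_panel(rng, 8, 4, 5)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 4),
            "rater": np.tile(np.arange(4), 8),
            "score": data.ravel(),
        })
        row = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        row = row[row["Type"] == "ICC(A,1)"].iloc[0]
        est = icc_single_absolute(data)
        assert est.value == pytest.approx(row["ICC"], abs=1e-10)
        np.testing.assert_allclose([est.ci_low, est.ci_high], row["CI95"], atol=5e-3)

    def test_grand_shift_invariance(self, rng):
        data = random_panel(rng, 7, 3, 5)
        a = icc_single_absolute(data)
        b = icc_single_absolute(data + 11.0)
        assert a.value == pytest.approx(b.value, abs=1e-12)

    def test_single_rater_offset_reduces_absolute_agreement(self, rng):
        truth = rng.integers(1, 6, size=(10, 1)).astype(float)
        data = truth + rng.normal(0, 0.4, size=(10, 4))
        shifted = data.copy()
        shifted[:, 0] += 3.0
        assert icc_single_absolute(shifted).value < icc_single_absolute(data).value


class TestConcordance:
    def test_trivial_unanimous_panels(self):
        matrix = np.array([[2] * 5] * 3 + [[1] * 5] * 2, dtype=float)
        counts = concordance_counts(matrix)
        assert counts.counts == (3, 0, 0, 0, 0, 2)

    def test_simulated_panel_matches_row_tally(self, rng):
        matrix = rng.integers(1, 3, size=(120, 5)).astype(float)
        counts = concordance_counts(matrix)
        tally = [int(((matrix == 2).sum(axis=1) == p).sum()) for p in CONCORDANCE_ORDER]
        assert list(counts.counts) == tally
        assert counts.total == 120

    def test_zero_one_coding_accepted(self):
        matrix = np.array([[1, 1, 1, 1, 1], [0, 0, 0, 0, 0], [1, 0, 1, 1, 0]], float)
        assert concordance_counts(matrix).counts == (1, 0, 1, 0, 0, 1)

    def test_wrong_rater_count_rejected(self):
        with pytest.raises(ValueError, match="5 raters"):
            concordance_counts(np.ones((4, 4)))

    def test_counts_round_trip_category_counts(self):
        counts = ConcordanceCounts((47, 5, 3, 4, 11, 50))
        # rebuild a binary matrix with the stated number of positives per row
        rows = []
        for npos, cnt in zip(CONCORDANCE_ORDER, counts.counts):
            rows += [[2] * npos + [1] * (5 - npos)] * cnt
        back = concordance_counts(np.array(rows, float))
        assert back.counts == counts.counts

    def test_unanimity_from_published_counts(self):
        _, pct_std = unanimity_proportion(ConcordanceCounts((47, 5, 3, 4, 11, 50)))
        _, pct_gme = unanimity_proportion(ConcordanceCounts((51, 4, 1, 0, 5, 58)))
        assert pct_std == 80.8 and pct_gme == 91.6

    def test_all_unanimous_is_100(self):
        _, pct = unanimity_proportion(ConcordanceCounts((7, 0, 0, 0, 0, 3)))
        assert pct == 100.0


class TestChi2:
    def test_published_concordance_table(self):
        res = chi2_2x2(97, 23, 109, 10)
        assert round(res["p"], 3) == 0.016

    def test_identical_rows(self):
        res = chi2_2x2(10, 10, 10, 10)
        assert res["chi2"] == pytest.approx(0.0) and res["p"] == pytest.approx(1.0)

    def test_matches_expected_cell_arithmetic(self):
        a, b, c, d = 12, 8, 5, 15
        n = a + b + c + d
        expected = [
            (a + b) * (a + c) / n, (a + b) * (b + d) / n,
            (c + d) * (a + c) / n, (c + d) * (b + d) / n,
        ]
        chi2 = sum((o - e) ** 2 / e for o, e in zip((a, b, c, d), expected))
        assert chi2_2x2(a, b, c, d)["chi2"] == pytest.approx(chi2)

    def test_matches_scipy_without_correction(self):
        res = chi2_2x2(97, 23, 109, 10)
        chi2, p, _, _ = sps.chi2_contingency([[97, 23], [109, 10]], correction=False)
        assert res["chi2"] == pytest.approx(chi2) and res["p"] == pytest.approx(p)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 5, 5)


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_constant_nonzero_difference_flagged(self):
        res = paired_t([2, 3, 4, 5], [1, 2, 3, 4])
        assert res["zero_variance"] == 1.0 and res["p"] == 0.0

    def test_matches_scipy(self, rng):
        x = rng.integers(1, 6, 10).astype(float)
        y = np.clip(x + rng.integers(-1, 2, 10), 1, 5).astype(float)
        if np.all(x == y):
            x[0] += 1
        res = paired_t(x, y)
        t, p = sps.ttest_rel(x, y)
        assert res["t"] == pytest.approx(t) and res["p"] == pytest.approx(p)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


class TestPairwiseSummary:
    def _matrix(self, rng, m=5):
        data = rng.integers(1, 3, size=(30, m)).astype(float)
        return pd.DataFrame(data, columns=[chr(65 + i) for i in range(m)])

    def test_five_raters_give_ten_pairs(self, rng):
        summary = pairwise_summary(self._matrix(rng), k=2)
        assert len(summary["pairs"]) == len(list(itertools.combinations("ABCDE", 2))) == 10

    def test_rater_relabelling_invariance(self, rng):
        matrix = self._matrix(rng)
        shuffled = matrix[["C", "A", "E", "B", "D"]]
        a = sorted(e.value for e in pairwise_summary(matrix, k=2)["pairs"].values())
        b = sorted(e.value for e in pairwise_summary(shuffled, k=2)["pairs"].values())
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_published_median_columns(self):
        t1 = tables.pairwise_weighted_kappas()
        t2 = tables.pairwise_binary_kappas()
        assert round(median_of(t1["std"]), 2) == 0.70
        assert round(median_of(t1["gmedge"]), 2) == 0.80
        assert round(median_of(t2["std"]), 2) == 0.82
        assert round(median_of(t2["gmedge"]), 2) == 0.93


class TestRatingsPlumbing:
    def test_matrix_pivot_and_binary_coding(self):
        df = pd.DataFrame({
            "subject": ["s1", "s1", "s2", "s2"],
            "rater": ["A", "B", "A", "B"],
            "method": ["std"] * 4,
            "score5": [5, 4, 1, 2],
            "binary": [1, 1, 0, 0],
            "confidence5": [5, 4, 5, 3],
        })
        matrix = ratings_matrix(df, "std", scale="binary")
        np.testing.assert_array_equal(matrix.to_numpy(), [[2, 2], [1, 1]])
        counts = matrix_to_category_counts(matrix, k=2)
        np.testing.assert_array_equal(counts, [[0, 2], [2, 0]])

    def test_kappa_estimate_invariants(self, rng):
        est = cohen_kappa(rng.integers(1, 3, 40), rng.integers(1, 3, 40), k=2)
        assert isinstance(est, AgreementEstimate)
        assert -1 <= est.value <= 1
        assert est.ci_low <= est.value <= est.ci_high
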