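"""Agreement battery: each statistic against an independent hand/oracle
computation on small worked tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from periprog.agreement import (
    classification_matrix,
    cochran_q,
    fleiss_kappa,
    icc21,
    location_count_tests,
    mcnemar,
    venn_summary,
)


class TestCochranQ:
    def test_identical_columns(self):
        m = np.tile([[1], [0], [1], [1]], (1, 3))
        assert cochran_q(m) == (0.0, 1.0)

    def test_hand_computed_value(self):
        # rows (1,1,0) x3 and (1,0,0) x2:
        # Q = (k-1)[k*sum(Cj^2) - N^2] / (k*N - sum(Ri^2))
        #   = 2*(3*(25+9+0) - 64) / (24 - 14) = 7.6
        m = np.array([[1, 1, 0]] * 3 + [[1, 0, 0]] * 2)
        q, p = cochran_q(m)
        assert q == pytest.approx(7.6)
        assert p == pytest.approx(stats.chi2.sf(7.6, 2))

    def test_k2_equals_uncorrected_mcnemar_chi2(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            m = rng.integers(0, 2, size=(30, 2))
            b = int(np.sum((m[:, 0] == 1) & (m[:, 1] == 0)))
            c = int(np.sum((m[:, 0] == 0) & (m[:, 1] == 1)))
            q, _ = cochran_q(m)
            if b + c == 0:
                assert q == 0.0
            else:
                assert q == pytest.approx((b - c) ** 2 / (b + c))


class TestMcNemar:
    def test_five_discordant_one_sided_pattern(self):
        x = np.array([1, 1, 1, 1, 1, 0, 0])
        y = np.array([0, 0, 0, 0, 0, 0, 0])
        assert mcnemar(x, y) == pytest.approx(2 * 0.5**5)  # 0.0625

    def test_balanced_discordance_capped_at_one(self):
        x = np.array([1, 0, 1, 0])
        y = np.array([0, 1, 0, 1])
        assert mcnemar(x, y) == 1.0

    def test_identical_vectors(self):
        x = np.array([1, 0, 1])
        assert mcnemar(x, x) == 1.0

    def test_chi2_variant(self):
        x = np.array([1] * 10 + [0] * 10)
        y = np.array([0] * 6 + [1] * 4 + [0] * 10)
        b, c = 6, 0
        expect = stats.chi2.sf((b - c) ** 2 / (b + c), 1)
        assert mcnemar(x, y, exact=False) == pytest.approx(expect)


def hand_fleiss(m):
    """Direct textbook formula for binary ratings, n subjects x k raters."""
    m = np.asarray(m)
    n, k = m.shape
    ones = m.sum(axis=1)
    zeros = k - ones
    p_i = (ones * (ones - 1) + zeros * (zeros - 1)) / (k * (k - 1))
    p_bar = p_i.mean()
    p1 = ones.sum() / (n * k)
    p_e = p1**2 + (1 - p1) ** 2
    return (p_bar - p_e) / (1 - p_e)


class TestFleissKappa:
    WORKED = np.array(
        [[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0], [0, 1, 1]]
    )

    def test_worked_table_matches_hand_formula(self):
        kappa, _, _ = fleiss_kappa(self.WORKED, n_permutations=50, seed=0)
        assert kappa == pytest.approx(hand_fleiss(self.WORKED))
        # frozen from the hand formula: P-bar=0.6, Pe=113/225
        assert kappa == pytest.approx(0.19642, abs=1e-4)

    def test_perfect_agreement(self):
        m = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 1], [0, 0, 0]])
        kappa, p, rng_pair = fleiss_kappa(m, n_permutations=200, seed=1)
        assert kappa == pytest.approx(1.0)
        assert p < 0.05
        assert rng_pair == (pytest.approx(1.0), pytest.approx(1.0))

    def test_null_shuffles_center_on_zero(self):
        rng = np.random.default_rng(3)
        kappas = []
        for _ in range(200):
            m = rng.integers(0, 2, size=(40, 3))
            kappas.append(fleiss_kappa(m, n_permutations=1, seed=0)[0])
        assert np.nanmean(kappas) == pytest.approx(0.0, abs=0.02)

    def test_monte_carlo_p_reproducible_and_calibrated(self):
        m = self.WORKED
        k1 = fleiss_kappa(m, n_permutations=500, seed=42)
        k2 = fleiss_kappa(m, n_permutations=500, seed=42)
        assert k1 == k2
        assert 0.0 < k1[1] <= 1.0

    def test_degenerate_single_category(self):
        kappa, p, _ = fleiss_kappa(np.ones((5, 3), dtype=int), n_permutations=10, seed=0)
        assert np.isnan(kappa) and np.isnan(p)

    def test_invariant_to_row_relabeling(self):
        rng = np.random.default_rng(9)
        m = rng.integers(0, 2, size=(25, 3))
        k1, _, _ = fleiss_kappa(m, n_permutations=1, seed=0)
        k2, _, _ = fleiss_kappa(m[rng.permutation(25)], n_permutations=1, seed=0)
        assert k1 == pytest.approx(k2)


def hand_icc21(m):
    """Two-way ANOVA mean-squares decomposition for ICC(2,1)."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_columns_with_row_variance(self):
        m = np.tile([[1.0], [0.0], [1.0], [0.0], [1.0]], (1, 3))
        icc, rng_pair = icc21(m)
        assert icc == pytest.approx(1.0)
        assert rng_pair[0] == pytest.approx(1.0)

    def test_anticorrelated_columns_negative(self):
        m = np.array([[1, 0], [0, 1], [1, 0], [0, 1], [1, 0]], dtype=float)
        icc, _ = icc21(m)
        assert icc < 0

    def test_worked_table_matches_anova_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            m = rng.integers(0, 2, size=(12, 3)).astype(float)
            if np.allclose(m, m.flat[0]):
                continue
            icc, _ = icc21(m)
            assert icc == pytest.approx(hand_icc21(m), abs=1e-9)

    def test_zero_variance_undefined(self):
        icc, _ = icc21(np.ones((5, 3)))
        assert np.isnan(icc)


class TestLocationCounts:
    def test_identical_columns(self):
        counts = {"SAP": np.arange(52), "SWAP": np.arange(52), "FDT": np.arange(52)}
        out = location_count_tests(counts)
        assert out["friedman"] == {"statistic": 0.0, "p": 1.0}
        assert all(p == 1.0 for p in out["wilcoxon_pairwise"].values())

    def test_uniform_shift_detected(self):
        base = np.arange(52, dtype=float)
        counts = {"SAP": base + 1, "SWAP": base, "FDT": base}
        out = location_count_tests(counts)
        assert out["friedman"]["p"] < 0.05
        assert out["wilcoxon_pairwise"]["SAP-SWAP"] < 0.05
        assert out["wilcoxon_pairwise"]["SWAP-FDT"] == 1.0

    def test_exact_wilcoxon_on_small_untied_sample(self):
        base = np.zeros(52)
        shifted = base.copy()
        shifted[:6] = [1, 2, 3, 4, 5, 6]  # 6 nonzero untied differences
        out = location_count_tests({"SAP": shifted, "SWAP": base, "FDT": base})
        expect = stats.wilcoxon(shifted, base, method="exact").pvalue
        assert out["wilcoxon_pairwise"]["SAP-SWAP"] == pytest.approx(expect)

    def test_null_rejection_rate(self):
        # independent exchangeable columns (permuting a single shared column
        # would pin the column totals and make the test ultra-conservative)
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            counts = {m: rng.normal(3.0, 1.0, size=52) for m in ("SAP", "SWAP", "FDT")}
            if location_count_tests(counts)["friedman"]["p"] < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.04)


class TestVenn:
    def test_all_triple(self):
        m = pd.DataFrame(np.ones((7, 3), dtype=int), columns=["SAP", "SWAP", "FDT"])
        out = venn_summary(m)
        assert out["regions"]["SAP&SWAP&FDT"] == 7
        assert sum(out["regions"].values()) == 7

    def test_disjoint_singletons(self):
        m = pd.DataFrame(np.eye(3, dtype=int), columns=["SAP", "SWAP", "FDT"])
        out = venn_summary(m)
        assert out["regions"]["SAP"] == 1
        assert out["regions"]["SWAP"] == 1
        assert out["regions"]["FDT"] == 1
        assert out["regions"]["SAP&SWAP&FDT"] == 0

    def test_regions_match_set_algebra_oracle(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.integers(0, 2, size=(40, 3)), columns=["SAP", "SWAP", "FDT"])
        out = venn_summary(m)["regions"]
        sets = {c: set(np.flatnonzero(m[c])) for c in m.columns}
        universe = sets["SAP"] | sets["SWAP"] | sets["FDT"]
        assert sum(out.values()) == len(universe)
        only_sap = sets["SAP"] - sets["SWAP"] - sets["FDT"]
        assert out["SAP"] == len(only_sap)
        assert out["SAP&SWAP&FDT"] == len(sets["SAP"] & sets["SWAP"] & sets["FDT"])

    def test_median_baseline_md(self):
        m = pd.DataFrame(
            [[1, 0, 0], [1, 1, 0], [0, 0, 0]], columns=["SAP", "SWAP", "FDT"]
        )
        out = venn_summary(m, baseline_md=[-5.0, -1.0, -10.0])
        assert out["median_baseline_md"]["SAP"] == pytest.approx(-3.0)
        assert out["median_baseline_md"]["FDT"] is None


def test_classification_matrix_excludes_indeterminate():
    rows = []
    for eye, statuses in [
        ("A:OD", ("progressing", "stable", "progressing")),
        ("B:OD", ("indeterminate", "stable", "stable")),
        ("C:OD", ("stable", "progressing", "stable")),
    ]:
        for m, s in zip(("SAP", "SWAP", "FDT"), statuses):
            rows.append({"eye_id": eye, "modality": m, "conservative": s})
    table = pd.DataFrame(rows)
    M = classification_matrix(table, "conservative", "progression")
    assert list(M.index) == ["A:OD", "C:OD"]
    assert M.loc["A:OD"].tolist() == [1, 0, 1]
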