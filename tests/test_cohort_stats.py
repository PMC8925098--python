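from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micmac.cohort_stats import (
    cohort_summary,
    correlation_matrix,
    feature_select_correlation,
    mann_whitney_u,
    spearman_r,
)
from micmac.stack_io import bundled_cohort_table, default_analysis_groups


def exact_mw_p(a, b):
    """Enumeration oracle: two-sided exact Mann-Whitney p by listing every
    assignment of the pooled ranks to group A."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    mean_u = n1 * len(b) / 2
    us = []
    for idx in combinations(range(len(pooled)), n1):
        u = np.sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2
        us.append(abs(u - mean_u))
    us = np.asarray(us)
    return np.mean(us >= abs(u_obs - mean_u) - 1e-12)


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert not res.significant

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.normal(size=4)
            b = rng.normal(size=5)
            res = mann_whitney_u(a, b)
            assert res.p_value == pytest.approx(exact_mw_p(a, b), abs=1e-9)

    def test_identical_samples_symmetric(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_type_i_error_calibrated(self):
        """Under the null (same distribution, n=20 each) the 5% test must
        reject at 0.05 +- 0.02 over 1000 simulations."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            rejections += mann_whitney_u(a, b).significant
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_exact_and_asymptotic_branches_agree(self):
        """At n1=n2=10 (asymptotic branch) the normal approximation must sit
        within 0.02 of the exact p on tie-free data."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.normal(size=10)
            b = rng.normal(0.3, 1, size=10)
            asym = mann_whitney_u(a, b).p_value
            exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert abs(asym - exact) <= 0.02


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.array([0.1, 0.5, 1.2, 2.0, 3.3])
        res = spearman_r(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)
        assert res.r2_spear == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        res = spearman_r(x, -x)
        assert res.rho == pytest.approx(-1.0)

    def test_printed_rank_formula_example(self):
        res = spearman_r([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8)
        assert res.r2_spear == pytest.approx(0.64)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_equals_pearson_of_average_ranks(self):
        """Oracle identity: Spearman rho is the Pearson correlation of the
        average-rank transforms, including under ties."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
            y = rng.normal(size=20)
            if np.unique(x).size < 2:
                continue
            rho = spearman_r(x, y).rho
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)


class TestFeatureSelection:
    def test_62_to_16_reduction(self):
        """16 independent columns plus 46 duplicates of them collapse back
        to exactly the 16 originals."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(300, 16))
        dup_idx = rng.integers(0, 16, size=46)
        X = np.hstack([base, base[:, dup_idx]])
        names = [f"orig_{i}" for i in range(16)] + [f"dup_{j}" for j in range(46)]
        kept = feature_select_correlation(pd.DataFrame(X, columns=names))
        assert kept == [f"orig_{i}" for i in range(16)]

    def test_duplicate_column_dropped(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert feature_select_correlation(X) == ["a"]

    def test_independent_gaussians_all_kept(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(1000, 10)))
        assert len(feature_select_correlation(X)) == 10

    def test_constant_feature_retained(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "c": [5.0, 5, 5], "b": [2.0, 4, 6]})
        kept = feature_select_correlation(X)
        assert "c" in kept


class TestCohortSummary:
    def test_printed_descriptives_reproduced(self):
        table = bundled_cohort_table()
        groups = default_analysis_groups(table)
        summary = cohort_summary(table, groups)
        assert summary["CTL"].mean_age == 83.1
        assert summary["AD"].mean_age == 87.1
        assert summary["DLB"].mean_age == 77.3
        assert summary["AD"].mean_pmd == 23.1
        assert summary["DLB"].mean_pmd == 19.4
        assert summary["CTL"].percent_female == 54.5
        assert summary["AD"].percent_female == 30.0
        assert summary["DLB"].percent_female == 37.5

    def test_single_member_group(self):
        table = bundled_cohort_table()
        s = cohort_summary(table, {"one": ["1"]})["one"]
        assert s.mean_age == 86.0
        assert s.percent_female == 100.0

    def test_empty_group_rejected(self):
        table = bundled_cohort_table()
        with pytest.raises(ValueError):
            cohort_summary(table, {"none": []})


class TestCorrelationMatrix:
    @staticmethod
    def _tables(seed, coupled=False, n_cases=10):
        rng = np.random.default_rng(seed)
        rows_v, rows_l = [], []
        for sf in ("CA1", "CA3", "DG/CA4"):
            for c in range(n_cases):
                u = rng.normal()
                feats = {f"f{i}": rng.normal() for i in range(16)}
                if coupled:
                    feats["f0"] = u + 0.1 * rng.normal()
                rows_v.append({"case_id": f"c{c}", "subfield": sf} | feats)
                for m in ("pTau", "Abeta", "pSyn"):
                    load = 10 + (5 * u if (coupled and m == "pTau") else rng.normal())
                    rows_l.append(
                        {"case_id": f"c{c}", "subfield": sf, "marker": m, "percent": load}
                    )
        return pd.DataFrame(rows_v), pd.DataFrame(rows_l)

    def test_output_dimensions(self):
        v, l = self._tables(0)
        out = correlation_matrix(v, l)
        assert len(out) == 16 * 3 * 3

    def test_planted_link_flagged_positive(self):
        v, l = self._tables(1, coupled=True)
        out = correlation_matrix(v, l)
        cell = out[
            (out.variable == "f0") & (out.marker == "pTau") & (out.subfield == "CA1")
        ].iloc[0]
        assert cell.significant and cell.rho > 0

    def test_null_flag_rate_near_alpha(self):
        """Fully independent cohort: ~5% of cells flagged (binomial band)."""
        flagged = total = 0
        for seed in range(8):
            v, l = self._tables(100 + seed)
            out = correlation_matrix(v, l)
            flagged += out.significant.sum()
            total += len(out)
        rate = flagged / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * se + 0.005

    def test_too_few_samples_marked_undefined(self):
        v, l = self._tables(2, n_cases=2)
        out = correlation_matrix(v, l)
        assert not out.defined.any()
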