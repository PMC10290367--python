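"""Group-comparison battery: exactness, conventions, and selection rule.

The exact Mann-Whitney path is cross-checked against an independent
brute-force permutation oracle; Cohen's d against its closed form.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import combinations

from osteoquant import (
    choose_test,
    cohens_d,
    cohens_d_from_summary,
    group_table,
    ks_normality,
    levene,
    mann_whitney_u,
    students_t,
)
from osteoquant.stats import SubjectRecord, table_to_markdown


def brute_force_mw_p(a, b):
    """Independent permutation oracle: two-tailed exact Mann-Whitney p."""
    from scipy.stats import rankdata

    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    n_a = len(a)
    ranks = rankdata(pooled)
    mu = n_a * len(b) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0

    u_obs = u_of(range(n_a))
    dev = abs(u_obs - mu)
    labels = list(combinations(range(len(pooled)), n_a))
    hits = sum(1 for idx in labels if abs(u_of(idx) - mu) >= dev - 1e-12)
    return hits / len(labels)


class TestStudentsT:
    def test_identical_samples(self):
        t, df, p = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_known_shift_closed_form(self):
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        t, df, p = students_t(a, b)
        # pooled SD 1 -> t = -10 / sqrt(2/3)
        assert t == pytest.approx(-10.0 / np.sqrt(2.0 / 3.0))
        assert p < 0.001

    def test_zero_variance_conventions(self):
        assert students_t([2.0, 2.0], [2.0, 2.0])[2] == 1.0
        assert students_t([2.0, 2.0], [3.0, 3.0])[2] == 0.0


class TestCohensD:
    def test_matches_summary_form_exactly(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 2, 6)
        d_raw = cohens_d(a, b)
        d_sum = cohens_d_from_summary(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert d_raw == pytest.approx(d_sum, abs=1e-12)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_sd_undefined(self):
        assert np.isnan(cohens_d_from_summary(1.0, 0.0, 6, 2.0, 0.0, 6))


class TestLevene:
    def test_identical_multisets(self):
        w, p = levene([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_detects_variance_ratio(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 10, 50)
        _, p = levene(a, b)
        assert p < 0.01

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 2, 20)
        w1, _ = levene(a, b)
        w2, _ = levene(a, b + 100.0)
        assert w1 == pytest.approx(w2)


class TestKSNormality:
    def test_statistic_bounded(self):
        rng = np.random.default_rng(4)
        d, _ = ks_normality(rng.normal(size=50))
        assert 0.0 <= d <= 1.0

    def test_exponential_rejected_with_power(self):
        rng = np.random.default_rng(5)
        rejected = sum(
            ks_normality(rng.exponential(size=100))[1] < 0.05 for _ in range(50)
        )
        assert rejected > 45

    def test_null_rejection_near_alpha(self):
        rng = np.random.default_rng(6)
        rejected = sum(
            ks_normality(rng.normal(size=80))[1] < 0.05 for _ in range(400)
        )
        assert 0.01 < rejected / 400 < 0.10

    def test_constant_sample_non_normal_by_convention(self):
        _, p = ks_normality([5.0, 5.0, 5.0, 5.0])
        assert p == 0.0


class TestMannWhitney:
    def test_textbook_separation(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_path_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 10, size=6).astype(float)
        b = rng.integers(0, 10, size=6).astype(float)
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    @pytest.mark.parametrize("n_a,n_b", [(4, 5), (7, 7), (3, 6)])
    def test_exact_path_other_sizes(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        a = rng.normal(size=n_a)
        b = rng.normal(0.5, 1.0, size=n_b)
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    @given(
        st.lists(st.integers(0, 6), min_size=5, max_size=7),
        st.lists(st.integers(0, 6), min_size=5, max_size=7),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_p_in_unit_interval_with_ties(self, a, b):
        _, p = mann_whitney_u(a, b)
        assert 0.0 <= p <= 1.0


class TestChooseTest:
    def test_clean_normals_choose_t(self):
        rng = np.random.default_rng(7)
        wins = sum(
            choose_test(rng.normal(size=30), rng.normal(size=30))[0] == "t"
            for _ in range(50)
        )
        assert wins > 40

    def test_skewed_sample_chooses_mann_whitney(self):
        rng = np.random.default_rng(8)
        wins = sum(
            choose_test(rng.normal(size=60), rng.lognormal(0, 1.5, size=60))[0]
            == "mann_whitney"
            for _ in range(50)
        )
        assert wins > 40


class TestGroupTable:
    @staticmethod
    def _records(rng, shift=0.0):
        recs = []
        for arm, delta in (("Control", 0.0), ("CEMF", shift)):
            for i in range(6):
                recs.append(
                    SubjectRecord(
                        subject_id=f"{arm}_{i}",
                        arm=arm,
                        model="17mm",
                        callus_volume=float(rng.normal(7.3 + delta, 1.3)),
                        rigidity_op=float(rng.normal(0.5 + delta / 10, 0.2)),
                        tissue_fractions={"new_bone": float(rng.normal(25, 5))},
                    )
                )
        return recs

    def test_swapping_arms_preserves_p_negates_d(self):
        rng = np.random.default_rng(9)
        recs = self._records(rng, shift=3.0)
        tab = group_table(recs)
        swapped = [
            SubjectRecord(
                **{
                    **r.__dict__,
                    "arm": "CEMF" if r.arm == "Control" else "Control",
                }
            )
            for r in recs
        ]
        tab_sw = group_table(swapped)
        row = tab.set_index("parameter").loc["callus_volume"]
        row_sw = tab_sw.set_index("parameter").loc["callus_volume"]
        assert row["p_two_tailed"] == pytest.approx(row_sw["p_two_tailed"])
        assert row["cohens_d"] == pytest.approx(-row_sw["cohens_d"])

    def test_overrides_route_parameters_to_tests(self):
        rng = np.random.default_rng(10)
        tab = group_table(self._records(rng)).set_index("parameter")
        assert tab.loc["callus_volume", "test_used"] == "t"
        assert tab.loc["rigidity_op", "test_used"] == "mann_whitney"
        assert tab.loc["tissue_new_bone", "test_used"] == "t"

    def test_missing_values_excluded_pairwise(self):
        rng = np.random.default_rng(11)
        recs = self._records(rng)
        recs[0] = SubjectRecord(**{**recs[0].__dict__, "callus_volume": None})
        tab = group_table(recs).set_index("parameter")
        assert tab.loc["callus_volume", "n_missing"] == 1
        assert tab.loc["callus_volume", "n_Control"] == 5

    def test_markdown_rendering_contains_all_parameters(self):
        rng = np.random.default_rng(12)
        tab = group_table(self._records(rng))
        md = table_to_markdown(tab)
        for param in tab["parameter"]:
            assert param in md
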