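"""Two-group testing, percent change, outlier-adjusted re-testing, Venn."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnome import (
    ConfigurationError,
    MirnomeError,
    percent_change,
    run_de,
    shapiro_branch_test,
    venn_partition,
)


def exact_mw_two_sided_p(a, b):
    """Enumeration oracle: permutation distribution of the MW U statistic."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(
            (x > y) + 0.5 * (x == y) for x in group_a for y in group_b
        )

    observed = u_stat(a, b)
    n_b = len(b)
    mid = n_a * n_b / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(combo)]
        u = u_stat(ga, gb)
        if abs(u - mid) >= abs(observed - mid):
            count += 1
        total += 1
    return count / total


class TestShapiroBranch:
    def test_identical_groups_are_exchangeable(self):
        r = shapiro_branch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p == 1.0 or r.p > 0.9
        assert r.direction in ("none", "up", "down")
        r2 = shapiro_branch_test([4.0, 4.0, 4.0], [4.0, 4.0, 4.0])
        assert r2.p == 1.0 and r2.direction == "none"

    def test_mann_whitney_exact_matches_enumeration_oracle(self):
        """{1,2,3} vs {4,5,6}: 2 of the 20 labelings are as extreme -> p = 0.1."""
        r = shapiro_branch_test([1, 2, 3], [4, 5, 6], test="mann_whitney")
        assert r.test == "mann_whitney"
        assert r.p == pytest.approx(0.1, abs=1e-12)
        assert r.p == pytest.approx(exact_mw_two_sided_p([1, 2, 3], [4, 5, 6]), abs=1e-12)
        assert r.direction == "down"

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 30), min_size=3, max_size=6),
        st.lists(st.integers(0, 30), min_size=3, max_size=6),
    )
    def test_mann_whitney_exact_agrees_with_enumeration_on_tie_free_data(self, a, b):
        pooled = a + b
        if len(set(pooled)) != len(pooled):
            return  # exact branch applies to tie-free data
        r = shapiro_branch_test(a, b, test="mann_whitney")
        assert r.p == pytest.approx(exact_mw_two_sided_p(a, b), abs=1e-9)

    def test_student_t_hand_arithmetic(self):
        """{1..5} vs {2..6}: pooled SD sqrt(2.5), SE 1 -> t = -1, df 8, p ~ 0.347."""
        r = shapiro_branch_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert r.test == "t_student"
        assert r.statistic == pytest.approx(-1.0, abs=1e-12)
        assert r.p == pytest.approx(0.34659, abs=1e-4)
        assert r.direction == "down"

    def test_non_normal_data_routes_to_mann_whitney(self):
        a = [1.0, 1.1, 1.2, 1.1, 1.0, 25.0, 1.3, 1.2, 1.1, 1.0]
        b = [2.0, 2.1, 2.2, 2.3, 2.0, 2.1, 2.2, 2.3, 2.4, 2.5]
        r = shapiro_branch_test(a, b)
        assert r.test == "mann_whitney"

    def test_group_smaller_than_two_rejected(self):
        with pytest.raises(ConfigurationError):
            shapiro_branch_test([1.0], [2.0, 3.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_label_swap_preserves_p_and_flips_direction(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        r1 = shapiro_branch_test(a, b)
        r2 = shapiro_branch_test(b, a)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)
        flip = {"up": "down", "down": "up", "none": "none"}
        assert r2.direction == flip[r1.direction]

    def test_mw_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        a = rng.exponential(1.0, 9)
        b = rng.exponential(2.0, 9)
        r1 = shapiro_branch_test(a, b, test="mann_whitney")
        r2 = shapiro_branch_test(np.exp(a), np.exp(b), test="mann_whitney")
        assert r1.p == pytest.approx(r2.p, rel=1e-12)

    def test_t_p_invariant_under_common_affine_transform(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 1, 10)
        r1 = shapiro_branch_test(a, b, test="t_student")
        r2 = shapiro_branch_test(3 * a + 7, 3 * b + 7, test="t_student")
        assert r1.p == pytest.approx(r2.p, rel=1e-9)


class TestPercentChange:
    @pytest.mark.parametrize(
        "case, control, direction, expected",
        [(150, 100, "up", 50.0), (100, 310, "down", 210.0), (100, 100, "none", 0.0)],
    )
    def test_asymmetric_convention(self, case, control, direction, expected):
        assert percent_change(case, control, direction) == pytest.approx(expected)

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(MirnomeError):
            percent_change(0, 10, "down")
        with pytest.raises(MirnomeError):
            percent_change(10, 0, "up")


class TestRunDe:
    def test_empty_robust_set_yields_empty_table(self, small_fit):
        results, _ = small_fit
        table = run_de(results.normalized, results.mask, results.groups, probes=[])
        assert table.to_frame().empty

    def test_table_sorted_by_ascending_p(self, small_fit):
        results, _ = small_fit
        frame = results.de_frame
        assert frame["p"].is_monotonic_increasing

    def test_tier_partition_matches_p_values(self, small_fit):
        results, _ = small_fit
        frame = results.de_frame
        assert ((frame["p"] < 0.05) == (frame["tier"] == "significant")).all()
        assert (((frame["p"] >= 0.05) & (frame["p"] < 0.1)) == (frame["tier"] == "trend")).all()

    def test_low_n_probes_are_logged_not_tested(self, small_fit):
        results, _ = small_fit
        log = [l for l in results.logs if l.stage == "de_low_n_probes"][0]
        frame = results.de_frame
        assert log.parameters["n_tested"] == len(frame)
        assert set(log.removed_ids).isdisjoint(set(frame["probe_id"]))

    def test_outlier_removal_conserves_sample_counts(self, small_fit):
        """adjusted n + removed = first-pass (detected) n, per group and probe."""
        results, _ = small_fit
        frame = results.de_frame.set_index("probe_id")
        for probe, row in frame.iterrows():
            det = results.mask.detected.loc[probe]
            n_case_det = sum(det[s] for s, g in results.groups.items() if g == "case")
            n_ctrl_det = sum(det[s] for s, g in results.groups.items() if g == "control")
            total_removed = row["removed_outliers"]
            assert (n_case_det + n_ctrl_det) - (row["n_case"] + row["n_control"]) == total_removed


class TestVenn:
    def test_identical_sets(self):
        part = venn_partition(["a", "b"], ["a", "b"], 5)
        assert (part.shared, part.exclusive_a, part.exclusive_b, part.neither) == (2, 0, 0, 3)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError):
            venn_partition(["a", "b"], ["c"], 2)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_matches_brute_force_set_arithmetic(self, a, b):
        universe = 31
        part = venn_partition([str(x) for x in a], [str(x) for x in b], universe)
        assert part.shared == len(a & b)
        assert part.exclusive_a == len(a - b)
        assert part.exclusive_b == len(b - a)
        assert part.neither == universe - len(a | b)
        assert part.shared + part.exclusive_a + part.exclusive_b + part.neither == universe
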