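"""ROC/AUC identities, DeLong CI, and centroid-linkage leaf ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnome import ConfigurationError, DegenerateInputError, cluster_leaf_order, roc_auc_ci


def pair_count_auc(case, control):
    """Exhaustive pair-counting oracle: U / (n1 n2) with ties counting 1/2."""
    wins = sum((c > k) + 0.5 * (c == k) for c in case for k in control)
    return wins / (len(case) * len(control))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc_ci([5, 6, 7, 1, 2, 3], ["case"] * 3 + ["control"] * 3)
        assert r.auc == 1.0
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)

    def test_controls_1_3_cases_2_4_gives_three_quarters(self):
        r = roc_auc_ci([1, 3, 2, 4], ["control", "control", "case", "case"])
        assert r.auc == pytest.approx(0.75, abs=1e-12)
        assert r.n_case == 2 and r.n_control == 2

    def test_orientation_flips_low_scoring_cases(self):
        r = roc_auc_ci([1, 2, 5, 6], ["case", "case", "control", "control"])
        assert r.orientation == "case_low"
        assert r.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            roc_auc_ci([1, 2, 3], ["case", "case", "case"])

    def test_auc_equals_pair_counting_on_random_instances(self):
        """AUC = U/(n1 n2) on 200 random instances, with and without ties."""
        rng = np.random.default_rng(123)
        for trial in range(200):
            n1, n2 = rng.integers(2, 11, 2)
            if trial % 2:
                case = rng.integers(0, 6, n1).astype(float)  # many ties
                control = rng.integers(0, 6, n2).astype(float)
            else:
                case = rng.normal(0.5, 1, n1)
                control = rng.normal(0, 1, n2)
            r = roc_auc_ci(np.concatenate([case, control]), ["case"] * n1 + ["control"] * n2)
            expected = pair_count_auc(case, control)
            expected = max(expected, 1 - expected)  # orientation
            assert abs(r.auc - expected) < 1e-12

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, 16)
        labels = ["case"] * 8 + ["control"] * 8
        r1 = roc_auc_ci(values, labels)
        r2 = roc_auc_ci(np.exp(values), labels)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        assert r1.ci_low == pytest.approx(r2.ci_low, abs=1e-12)

    def test_label_swap_leaves_oriented_auc_unchanged(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, 14)
        labels = np.array(["case"] * 7 + ["control"] * 7)
        swapped = np.where(labels == "case", "control", "case")
        r1 = roc_auc_ci(values, labels)
        r2 = roc_auc_ci(values, swapped)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)

    def test_delong_ci_matches_proc_oracle(self):
        """Frozen from R pROC ci.auc(..., method="delong") on this instance."""
        values = [2.1, 3.3, 1.8, 4.0, 2.7, 3.9, 5.2, 2.2, 1.0, 2.0, 1.5, 2.5, 0.7, 1.9, 2.4, 3.1]
        labels = ["case"] * 8 + ["control"] * 8
        r = roc_auc_ci(values, labels)
        assert r.auc == pytest.approx(0.8125, abs=1e-12)
        assert r.ci_low == pytest.approx(0.595334701732, abs=1e-9)
        assert r.ci_high == pytest.approx(1.0, abs=1e-12)


def naive_centroid_agglomeration(dist2):
    """Independent stepwise oracle: same linkage, naive bookkeeping."""
    n = dist2.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {(i, j): dist2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, i in enumerate(keys):
            for j in keys[ai + 1:]:
                cand = (d[(i, j)], (i, j))
                if best is None or cand < best:
                    best = cand
        d2ij, (i, j) = best
        ni, nj = len(clusters[i]), len(clusters[j])
        for k in keys:
            if k in (i, j):
                continue
            dki, dkj = d[tuple(sorted((k, i)))], d[tuple(sorted((k, j)))]
            upd = (ni * dki + nj * dkj) / (ni + nj) - ni * nj * d2ij / (ni + nj) ** 2
            d[tuple(sorted((k, nxt)))] = max(upd, 0.0)
        clusters[nxt] = clusters.pop(i) + clusters.pop(j)
        merges.append((i, j, np.sqrt(max(d2ij, 0.0))))
        nxt += 1
    return merges


class TestLeafOrder:
    def test_two_probes_single_merge(self):
        frame = pd.DataFrame([[1, 2, 3], [3, 1, 2]], index=["a", "b"], columns=list("xyz"))
        leaf = cluster_leaf_order(frame)
        assert leaf.order == ["a", "b"]
        assert len(leaf.merges) == 1

    def test_rank_preserving_transform_merges_first(self):
        frame = pd.DataFrame(
            {
                "a": [1.0, 2.0, 3.0, 4.0],
                "b": [10.0, 20.0, 31.0, 45.0],  # same ranks as a -> distance 0
                "c": [4.0, 3.0, 2.0, 1.0],
            }
        ).T
        leaf = cluster_leaf_order(frame)
        i, j, height, size = leaf.merges[0]
        assert {i, j} == {0, 1}
        assert height == pytest.approx(0.0, abs=1e-12)
        # root merge is (c, {a,b}); lower cluster index (the leaf c) goes left
        assert leaf.order == ["c", "a", "b"]

    def test_single_probe_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cluster_leaf_order(pd.DataFrame([[1, 2, 3]], index=["a"]))

    def test_matches_naive_stepwise_oracle(self):
        rng = np.random.default_rng(21)
        frame = pd.DataFrame(rng.normal(size=(6, 8)), index=[f"p{i}" for i in range(6)])
        leaf = cluster_leaf_order(frame)
        from mirnome.diagnostics import _spearman_distance

        d2 = _spearman_distance(frame.to_numpy(), list(frame.index)) ** 2
        expected = naive_centroid_agglomeration(d2)
        assert [(i, j) for i, j, *_ in leaf.merges] == [(i, j) for i, j, _ in expected]
        assert [h for *_, h, _ in leaf.merges] == pytest.approx([h for *_, h in expected], abs=1e-12)

    def test_leaf_order_is_deterministic(self):
        rng = np.random.default_rng(22)
        frame = pd.DataFrame(rng.normal(size=(7, 9)), index=[f"p{i}" for i in range(7)])
        assert cluster_leaf_order(frame).order == cluster_leaf_order(frame).order

    def test_order_is_permutation_of_input(self):
        rng = np.random.default_rng(23)
        frame = pd.DataFrame(rng.normal(size=(9, 5)), index=[f"p{i}" for i in range(9)])
        leaf = cluster_leaf_order(frame)
        assert sorted(leaf.order) == sorted(frame.index)
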