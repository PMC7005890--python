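"""Per-variable ROC diagnostics and heatmap leaf ordering.

The empirical AUC equals the Mann-Whitney U statistic divided by
n_case * n_control, with ties at the decision threshold contributing 1/2.
Its 95% confidence interval uses the DeLong placement-value variance
estimator (the default of the standard ROC packages), which is
deterministic and fast.  Orientation is chosen automatically so the
reported AUC is at least 0.5; the chosen orientation is returned.

Leaf ordering for heatmap display uses agglomerative clustering with a
Spearman correlation distance (1 - rank correlation between probe rows)
and centroid linkage via the Lance-Williams update.  Centroid linkage over
a non-Euclidean correlation distance is mathematically improper and can
produce inversions (a merge lower than an earlier one); inversions are
recorded in the linkage record rather than silently reordered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegenerateInputError


@dataclass
class ROCResult:
    """Empirical AUC with DeLong 95% CI, oriented so auc >= 0.5."""

    variable_id: str
    auc: float
    ci_low: float
    ci_high: float
    orientation: str  # case_high | case_low
    n_case: int
    n_control: int


@dataclass
class LeafOrder:
    """Dendrogram leaf order plus the merge record.

    ``merges`` holds (left_cluster, right_cluster, height, size) tuples in
    merge order; cluster indices < n_probes are leaves, >= n_probes are
    prior merges.  ``inversions`` lists merge step indices whose height is
    below the running maximum.
    """

    order: list[str]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)
    inversions: list[int] = field(default_factory=list)


def _placements(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: for each case, the fraction of controls it
    beats (ties 1/2); symmetrically for controls."""
    v10 = np.array(
        [(np.sum(c > control) + 0.5 * np.sum(c == control)) / control.size for c in case]
    )
    v01 = np.array(
        [(np.sum(case > c) + 0.5 * np.sum(case == c)) / case.size for c in control]
    )
    return v10, v01


def roc_auc_ci(
    values: Sequence[float],
    labels: Sequence[str],
    alpha: float = 0.05,
    variable_id: str = "",
) -> ROCResult:
    """Empirical AUC (= U / (n_case * n_control)) with a DeLong CI.

    ``labels`` holds "case"/"control" per value; both classes need at least
    2 members.  If cases tend to score lower than controls, the variable is
    flipped (orientation ``case_low``) so the reported AUC is >= 0.5.
    """
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(labels))
    case = values[labels == "case"]
    control = values[labels == "control"]
    if case.size < 2 or control.size < 2:
        raise ConfigurationError("need at least 2 values per class")

    v10, v01 = _placements(case, control)
    auc = float(np.mean(v10))
    orientation = "case_high"
    if auc < 0.5:
        orientation = "case_low"
        v10, v01 = 1.0 - v10, 1.0 - v01
        auc = 1.0 - auc

    var = float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return ROCResult(
        variable_id=variable_id,
        auc=auc,
        ci_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci_high=float(np.clip(auc + half, 0.0, 1.0)),
        orientation=orientation,
        n_case=int(case.size),
        n_control=int(control.size),
    )


def _spearman_distance(matrix: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """1 - Spearman rank correlation between rows; constant rows get
    distance 1 to everything (logged with a warning)."""
    n = matrix.shape[0]
    constant = [i for i in range(n) if np.ptp(matrix[i]) == 0.0]
    if constant:
        warnings.warn(
            f"constant rows assigned Spearman distance 1 to all others: "
            f"{[ids[i] for i in constant]}",
            stacklevel=3,
        )
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    dist = 1.0 - corr
    for i in constant:
        dist[i, :] = 1.0
        dist[:, i] = 1.0
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_leaf_order(matrix: pd.DataFrame) -> LeafOrder:
    """Order probe rows by centroid-linkage agglomeration over Spearman
    distance.

    Merging uses the Lance-Williams centroid update on squared distances:
    d(k, ij)^2 = (ni d(k,i)^2 + nj d(k,j)^2) / (ni+nj)
                 - ni nj d(i,j)^2 / (ni+nj)^2
    (negative squared distances from the improper metric are clamped to 0).
    Ties are broken deterministically by the smallest (i, j) cluster-index
    pair, and the leaf order is a recursive left-before-right traversal
    with the lower-index cluster on the left.
    """
    if matrix.shape[0] < 2:
        raise DegenerateInputError("leaf ordering needs at least 2 probes")
    ids = list(matrix.index)
    n = len(ids)
    d2 = _spearman_distance(matrix.to_numpy(dtype=float), ids) ** 2

    # cluster bookkeeping: index -> (children or leaf, size)
    sizes = {i: 1 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    active = list(range(n))
    dist2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist2[(i, j)] = float(d2[i, j])

    merges: list[tuple[int, int, float, int]] = []
    inversions: list[int] = []
    next_id = n
    max_height = -np.inf
    while len(active) > 1:
        best = min(
            ((dist2[(min(i, j), max(i, j))], (min(i, j), max(i, j)))
             for a, i in enumerate(active) for j in active[a + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        d2_ij, (i, j) = best
        height = float(np.sqrt(max(d2_ij, 0.0)))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dki = dist2[(min(k, i), max(k, i))]
            dkj = dist2[(min(k, j), max(k, j))]
            upd = (ni * dki + nj * dkj) / (ni + nj) - ni * nj * d2_ij / (ni + nj) ** 2
            dist2[(k, new)] = max(upd, 0.0)
        active = [k for k in active if k not in (i, j)] + [new]
        sizes[new] = ni + nj
        children[new] = (i, j)
        if merges and height < max_height:
            inversions.append(len(merges))
        max_height = max(max_height, height)
        merges.append((i, j, height, ni + nj))

    def _leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = children[node]
        return _leaves(left) + _leaves(right)

    order = [ids[i] for i in _leaves(next_id - 1)]
    return LeafOrder(order=order, merges=merges, inversions=inversions)
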