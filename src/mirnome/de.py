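"""Two-group testing with a normality branch, outlier-adjusted re-testing,
percent-change reporting and cross-fraction Venn bookkeeping.

The testing scheme: Shapiro-Wilk normality is assessed in each group
(p > 0.05 means "normal"); when both groups pass, a two-sided equal-variance
Student's t test is used, otherwise a two-sided Mann-Whitney test.  Two
significance tiers are reported: p < 0.05 (significant) and 0.05 <= p < 0.1
(trend).  For probes whose first-pass p falls below the trend cutoff, a
single-pass 2-SD band outlier filter is applied per group and the test is
re-run on the retained values; the reported result is the adjusted one.
No multiple-testing correction drives the tiers (a Benjamini-Hochberg
column is emitted as supplementary output only), mirroring common practice
in small-cohort discovery panels.

Percent change uses an asymmetric convention: over-expression is reported
relative to the control level, under-expression relative to the case level
— the only convention under which under-expression can exceed 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, MirnomeError
from .filtering import DetectionMask, FilterLog, chauvenet_filter
from .normalization import NormalizedMatrix

TIERS = ("significant", "trend", "ns")


@dataclass
class GroupCompareResult:
    """Outcome of one two-group comparison after censoring/outlier removal."""

    variable_id: str
    n_case: int
    n_control: int
    test: str  # t_student | mann_whitney
    statistic: float
    p: float
    direction: str  # up | down | none
    pct_change: float
    tier: str
    removed_case: int = 0
    removed_control: int = 0

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"invalid tier {self.tier!r}")


@dataclass
class DETable:
    """Per-probe test outcomes, sorted by ascending p, with provenance."""

    results: list[GroupCompareResult]
    fraction: str | None = None
    logs: list[FilterLog] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.results, key=lambda r: (r.p, r.variable_id))
        frame = pd.DataFrame(
            {
                "probe_id": [r.variable_id for r in rows],
                "n_case": [r.n_case for r in rows],
                "n_control": [r.n_control for r in rows],
                "test": [r.test for r in rows],
                "statistic": [r.statistic for r in rows],
                "p": [r.p for r in rows],
                "direction": [r.direction for r in rows],
                "pct_change": [r.pct_change for r in rows],
                "tier": [r.tier for r in rows],
                "removed_outliers": [r.removed_case + r.removed_control for r in rows],
            }
        )
        if len(frame):
            frame.insert(6, "p_bh", stats.false_discovery_control(frame["p"].to_numpy()))
        else:
            frame.insert(6, "p_bh", pd.Series(dtype=float))
        return frame

    def significant(self) -> list[str]:
        return [r.variable_id for r in self.results if r.tier == "significant"]


@dataclass(frozen=True)
class VennPartition:
    """Counts of probes shared, exclusive to each fraction, or in neither."""

    shared: int
    exclusive_a: int
    exclusive_b: int
    neither: int
    universe: int


def _tier(p: float, alpha: float = 0.05, trend: float = 0.1) -> str:
    if p < alpha:
        return "significant"
    if p < trend:
        return "trend"
    return "ns"


def percent_change(case_summary: float, control_summary: float, direction: str) -> float:
    """Percent difference under the asymmetric convention.

    up: 100 * (case - control) / control; down: 100 * (control - case) / case.
    A ``down`` change can therefore exceed 100%.
    """
    if direction == "none":
        return 0.0
    if direction == "up":
        if control_summary == 0:
            raise MirnomeError("percent change undefined: control summary is zero")
        return 100.0 * (case_summary - control_summary) / control_summary
    if direction == "down":
        if case_summary == 0:
            raise MirnomeError("percent change undefined: case summary is zero")
        return 100.0 * (control_summary - case_summary) / case_summary
    raise ValueError(f"invalid direction {direction!r}")


def shapiro_branch_test(
    a: Sequence[float],
    b: Sequence[float],
    variable_id: str = "",
    normality_alpha: float = 0.05,
    require_both_normal: bool = True,
    test: str = "auto",
) -> GroupCompareResult:
    """Two-group comparison with the normality branch (a = cases, b = controls).

    Shapiro-Wilk is run on each group (needs n >= 3 and non-constant data;
    otherwise the group counts as non-normal).  Both groups normal ->
    equal-variance Student's t; otherwise Mann-Whitney (exact null
    distribution when both n <= 15 with no ties, normal approximation with
    tie and continuity correction otherwise).  Direction follows the case
    vs control location: means under t, medians under Mann-Whitney.

    ``test`` may force a branch ("t_student" / "mann_whitney") instead of
    the automatic normality routing.
    """
    if test not in ("auto", "t_student", "mann_whitney"):
        raise ValueError(f"invalid test {test!r}")
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ConfigurationError("each group needs at least 2 values")

    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        # identical constants in both groups: no evidence of any difference
        return GroupCompareResult(
            variable_id=variable_id, n_case=int(x.size), n_control=int(y.size),
            test="mann_whitney", statistic=float(x.size * y.size / 2.0), p=1.0,
            direction="none", pct_change=0.0, tier="ns",
        )

    def _normal(v: np.ndarray) -> bool:
        if v.size < 3 or np.ptp(v) == 0.0:
            return False
        return stats.shapiro(v).pvalue > normality_alpha

    if test == "auto":
        normal_a, normal_b = _normal(x), _normal(y)
        is_normal = (normal_a and normal_b) if require_both_normal else (normal_a or normal_b)
    else:
        is_normal = test == "t_student"

    if is_normal:
        res = stats.ttest_ind(x, y, equal_var=True)
        test, statistic, p = "t_student", float(res.statistic), float(res.pvalue)
        loc_case, loc_ctrl = float(np.mean(x)), float(np.mean(y))
    else:
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (x.size <= 15 and y.size <= 15 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        test, statistic, p = "mann_whitney", float(res.statistic), float(res.pvalue)
        loc_case, loc_ctrl = float(np.median(x)), float(np.median(y))

    p = min(p, 1.0)
    if loc_case > loc_ctrl:
        direction = "up"
    elif loc_case < loc_ctrl:
        direction = "down"
    else:
        direction = "none"
    try:
        pct = percent_change(loc_case, loc_ctrl, direction)
    except MirnomeError:
        pct = float("nan")
    return GroupCompareResult(
        variable_id=variable_id, n_case=int(x.size), n_control=int(y.size),
        test=test, statistic=statistic, p=p, direction=direction,
        pct_change=pct, tier=_tier(p),
    )


def run_de(
    norm: NormalizedMatrix,
    mask: DetectionMask,
    groups: Mapping[str, str],
    probes: Sequence[str] | None = None,
    trend_p: float = 0.1,
    chauvenet_sd: float = 2.0,
    chauvenet_floor: int | None = 10,
    normality_alpha: float = 0.05,
) -> DETable:
    """Test every probe for a case/control difference, with outlier re-testing.

    For each probe the sample universe is the set of samples detected for
    that probe (censored samples drop out, so per-probe n varies).  Probes
    whose first-pass p falls below ``trend_p`` are re-tested after per-group
    2-SD band outlier removal, with a per-group retention floor
    (``chauvenet_floor``, default 10).  Probes whose per-group n falls below
    2 after censoring are excluded and logged.
    """
    if probes is None:
        probes = [p for p in norm.values.index if p in mask.detected.index]
    sample_ids = [s for s in norm.values.columns if s in groups]
    case_ids = [s for s in sample_ids if groups[s] == "case"]
    ctrl_ids = [s for s in sample_ids if groups[s] == "control"]
    if not case_ids or not ctrl_ids:
        raise ConfigurationError("both groups must be represented among samples")

    results: list[GroupCompareResult] = []
    excluded: list[str] = []
    for probe in probes:
        det = mask.detected.loc[probe]
        vals = norm.values.loc[probe]
        case = vals[[s for s in case_ids if det[s]]].to_numpy(dtype=float)
        ctrl = vals[[s for s in ctrl_ids if det[s]]].to_numpy(dtype=float)
        if case.size < 2 or ctrl.size < 2:
            excluded.append(probe)
            continue
        first = shapiro_branch_test(case, ctrl, probe, normality_alpha)
        if first.p < trend_p:
            case_kept, case_rm = chauvenet_filter(case, chauvenet_sd, chauvenet_floor)
            ctrl_kept, ctrl_rm = chauvenet_filter(ctrl, chauvenet_sd, chauvenet_floor)
            if case_rm or ctrl_rm:
                adjusted = shapiro_branch_test(case_kept, ctrl_kept, probe, normality_alpha)
                adjusted.removed_case = len(case_rm)
                adjusted.removed_control = len(ctrl_rm)
                results.append(adjusted)
                continue
        results.append(first)

    log = FilterLog(
        stage="de_low_n_probes",
        removed_ids=excluded,
        criterion="fewer than 2 detected samples in a group",
        parameters={"n_in": len(list(probes)), "n_tested": len(results)},
    )
    return DETable(results=results, logs=[log])


def venn_partition(
    set_a: Sequence[str],
    set_b: Sequence[str],
    universe_size: int,
) -> VennPartition:
    """Exact set bookkeeping of two robust probe sets over a panel universe."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if len(union) > universe_size:
        raise ValueError(
            f"universe ({universe_size}) smaller than union of sets ({len(union)})"
        )
    shared = len(a & b)
    return VennPartition(
        shared=shared,
        exclusive_a=len(a) - shared,
        exclusive_b=len(b) - shared,
        neither=universe_size - len(union),
        universe=universe_size,
    )
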