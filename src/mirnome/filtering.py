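"""Quality and detection filters: RIN gate, low-coverage sample removal,
robust-probe selection, and the 2-SD band ("Chauvenet") outlier filter.

Every filter returns a :class:`FilterLog` entry recording the stage name,
what was removed and under which criterion, so the sample/probe universe at
each stage is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateInputError, IntegrityError


@dataclass
class FilterLog:
    """One filtering stage: what was removed, under which rule."""

    stage: str
    removed_ids: list = field(default_factory=list)
    criterion: str = ""
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "removed_ids": list(self.removed_ids),
            "criterion": self.criterion,
            "parameters": dict(self.parameters),
        }


@dataclass
class DetectionMask:
    """Boolean probe x sample detection grid: raw count >= threshold."""

    detected: pd.DataFrame
    threshold: float


def filter_by_rin(
    samples: pd.DataFrame,
    min_rin: float = 7.0,
) -> tuple[list[str], FilterLog]:
    """Keep samples whose RIN exceeds ``min_rin`` (strict: exactly 7 fails).

    RNA integrity can only be scored on cellular RNA, so samples of the
    vesicle fraction pass unconditionally; a cellular sample with no RIN is
    an integrity error.

    Parameters
    ----------
    samples : DataFrame
        Indexed by sample_id with ``fraction`` and ``rin`` columns.
    """
    kept, removed = [], []
    for sid, row in samples.iterrows():
        if row.get("fraction") == "ev_fraction":
            kept.append(sid)
            continue
        rin = row.get("rin")
        if rin is None or (isinstance(rin, float) and np.isnan(rin)):
            raise IntegrityError(f"cell-fraction sample {sid!r} has no RIN value")
        (kept if float(rin) > min_rin else removed).append(sid)
    log = FilterLog(
        stage="rin_gate",
        removed_ids=removed,
        criterion=f"rin > {min_rin} (ev_fraction exempt)",
        parameters={"min_rin": min_rin, "n_in": len(samples), "n_kept": len(kept)},
    )
    return kept, log


def drop_low_coverage_samples(
    mask: DetectionMask,
    max_below_frac: float = 0.40,
) -> tuple[list[str], FilterLog]:
    """Remove samples non-detected in ``max_below_frac`` or more of the probes.

    The boundary is inclusive (a sample at exactly 40% non-detected is
    removed).  The mask must already be restricted to the probe universe the
    rule counts over (endogenous probes).
    """
    det = mask.detected
    if det.shape[0] == 0:
        raise DegenerateInputError("detection mask has zero probes")
    below_frac = 1.0 - det.mean(axis=0)
    removed = [s for s in det.columns if below_frac[s] >= max_below_frac]
    kept = [s for s in det.columns if s not in set(removed)]
    log = FilterLog(
        stage="low_coverage_samples",
        removed_ids=removed,
        criterion=f"non-detected fraction >= {max_below_frac}",
        parameters={
            "max_below_frac": max_below_frac,
            "n_probes": int(det.shape[0]),
            "n_in": int(det.shape[1]),
            "n_kept": len(kept),
            "below_frac": {s: float(below_frac[s]) for s in removed},
        },
    )
    return kept, log


def robust_probe_filter(
    mask: DetectionMask,
    groups: Mapping[str, str],
    min_frac: float = 0.75,
) -> tuple[list[str], FilterLog]:
    """Keep probes detected in at least ``min_frac`` of samples of either group.

    "At least" is inclusive: a probe detected in exactly 75% of one group is
    kept even if absent from the other.
    """
    det = mask.detected
    case_ids = [s for s in det.columns if groups.get(s) == "case"]
    ctrl_ids = [s for s in det.columns if groups.get(s) == "control"]
    if not case_ids or not ctrl_ids:
        raise ConfigurationError("both groups must have at least one sample")
    frac_case = det[case_ids].mean(axis=1)
    frac_ctrl = det[ctrl_ids].mean(axis=1)
    keep = (frac_case >= min_frac) | (frac_ctrl >= min_frac)
    kept = [p for p in det.index if keep[p]]
    removed = [p for p in det.index if not keep[p]]
    log = FilterLog(
        stage="robust_probes",
        removed_ids=removed,
        criterion=f"detected fraction >= {min_frac} in either group",
        parameters={
            "min_frac": min_frac,
            "n_case": len(case_ids),
            "n_control": len(ctrl_ids),
            "n_in": int(det.shape[0]),
            "n_kept": len(kept),
        },
    )
    return kept, log


def chauvenet_filter(
    values: Sequence[float],
    n_sd: float = 2.0,
    min_keep: int | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Single-pass 2-SD band outlier removal.

    Computes the mean m and sample SD s of the input once and removes values
    with ``|x - m| > n_sd * s``; there is no re-iteration after removal.
    Inputs with fewer than 3 values, or with s = 0, are returned unchanged.

    ``min_keep`` is an optional retention floor: if removing every
    band-violator would leave fewer than ``min_keep`` values, the most
    extreme violators are removed first and removal stops at the floor.
    The floor is disabled by default at this level; the differential-
    expression stage applies it per group (default 10).

    Returns (kept values in input order, removed indices into the input).
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 3:
        return arr, []
    m = float(np.mean(arr))
    s = float(np.std(arr, ddof=1))
    if s == 0.0:
        return arr, []
    dev = np.abs(arr - m)
    violators = np.nonzero(dev > n_sd * s)[0]
    if violators.size == 0:
        return arr, []
    # most extreme first; ties broken by index for determinism
    order = sorted(violators, key=lambda i: (-dev[i], i))
    allowed = len(order)
    if min_keep is not None:
        allowed = min(allowed, max(0, n - min_keep))
    removed = sorted(int(i) for i in order[:allowed])
    kept = np.delete(arr, removed)
    return kept, removed
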