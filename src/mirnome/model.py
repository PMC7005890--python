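"""Model/Results facade over the per-fraction analysis pipeline.

:class:`MiRNAPanelDE` is built from a :class:`~mirnome.io.CountMatrix` for
one blood fraction; ``fit()`` runs the full chain — RIN gate, background
threshold from negative controls, reference-set normalization, detection
censoring, low-coverage sample removal, robust-probe selection,
normality-branched testing with outlier-adjusted re-testing — and returns a
:class:`MiRNAPanelDEResults` carrying the per-probe estimates (percent
change), their evidence (p values, tiers), diagnostics (ROC/AUC, leaf
order) and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import de as de_mod
from . import diagnostics as diag_mod
from .exceptions import ConfigurationError
from .filtering import (
    DetectionMask,
    FilterLog,
    drop_low_coverage_samples,
    filter_by_rin,
    robust_probe_filter,
)
from .io import CountMatrix, read_count_table
from .normalization import (
    NormalizedMatrix,
    ThresholdResult,
    apply_normalization,
    background_threshold,
    reference_factors,
)

_DEFAULT_REFERENCE = {"cell_fraction": "top_n", "ev_fraction": "spikein"}


class MiRNAPanelDE:
    """Two-group differential-expression model for one nCounter fraction.

    Parameters
    ----------
    counts : CountMatrix
        Panel counts with group/fraction/RIN metadata; all samples must
        belong to a single fraction.
    reference : {"top_n", "spikein"}, optional
        Normalization reference; defaults to top-100 endogenous probes for
        the cellular fraction and spike-ins for the vesicle fraction.
    top_n : int
        Size of the top-expressed reference set (default 100).
    min_rin : float
        Cellular samples need RIN strictly above this (default 7.0).
    max_below_frac : float
        Samples non-detected in this fraction of probes or more are
        dropped (default 0.40, boundary inclusive).
    min_frac : float
        Probes must be detected in at least this fraction of samples of
        either group (default 0.75).
    chauvenet_sd, chauvenet_floor : float, int or None
        Width of the outlier band in SDs (default 2.0) and the per-group
        retention floor during outlier removal (default 10; None disables).
    alpha, trend_p : float
        Significance tiers: p < alpha significant, p < trend_p trend
        (defaults 0.05 / 0.1).
    apply_rin_gate : bool
        Disable to analyse rosters without RIN metadata.
    """

    def __init__(
        self,
        counts: CountMatrix,
        reference: str | None = None,
        top_n: int = 100,
        min_rin: float = 7.0,
        max_below_frac: float = 0.40,
        min_frac: float = 0.75,
        chauvenet_sd: float = 2.0,
        chauvenet_floor: int | None = 10,
        alpha: float = 0.05,
        trend_p: float = 0.1,
        apply_rin_gate: bool = True,
    ):
        fractions = set(counts.samples["fraction"].dropna())
        if len(fractions) > 1:
            raise ConfigurationError(f"matrix mixes fractions {sorted(fractions)}; fit one at a time")
        self.fraction = next(iter(fractions), None)
        if reference is None:
            if self.fraction is None:
                raise ConfigurationError("cannot infer reference: no fraction metadata")
            reference = _DEFAULT_REFERENCE[self.fraction]
        self.counts = counts
        self.reference = reference
        self.top_n = top_n
        self.min_rin = min_rin
        self.max_below_frac = max_below_frac
        self.min_frac = min_frac
        self.chauvenet_sd = chauvenet_sd
        self.chauvenet_floor = chauvenet_floor
        self.alpha = alpha
        self.trend_p = trend_p
        self.apply_rin_gate = apply_rin_gate

    @classmethod
    def from_count_table(
        cls, path: str | Path, sample_sheet: str | Path, **kwargs
    ) -> "MiRNAPanelDE":
        return cls(read_count_table(path, sample_sheet), **kwargs)

    def fit(self) -> "MiRNAPanelDEResults":
        logs: list[FilterLog] = []

        matrix = self.counts
        if self.apply_rin_gate:
            kept, log = filter_by_rin(matrix.samples, self.min_rin)
            logs.append(log)
            matrix = matrix.subset(samples=kept)

        threshold = background_threshold(matrix)
        factors = reference_factors(matrix, self.reference, self.top_n)
        norm = apply_normalization(matrix, factors, threshold)

        # probe universe for the coverage rules: endogenous probes that are
        # detected in at least one sample (probes entering normalization)
        endo = matrix.endogenous_ids
        endo_det = norm.detected.loc[endo]
        universe = [p for p in endo if endo_det.loc[p].any()]
        mask = DetectionMask(detected=norm.detected.loc[universe], threshold=threshold.threshold)

        kept_samples, cov_log = drop_low_coverage_samples(mask, self.max_below_frac)
        cov_log.parameters["probe_universe"] = "endogenous probes detected in >= 1 sample"
        logs.append(cov_log)
        mask = DetectionMask(detected=mask.detected[kept_samples], threshold=threshold.threshold)

        groups = {
            s: g
            for s, g in matrix.samples["group"].items()
            if s in set(kept_samples) and g in ("case", "control")
        }
        robust, robust_log = robust_probe_filter(mask, groups, self.min_frac)
        logs.append(robust_log)

        detable = de_mod.run_de(
            norm,
            mask,
            groups,
            probes=robust,
            trend_p=self.trend_p,
            chauvenet_sd=self.chauvenet_sd,
            chauvenet_floor=self.chauvenet_floor,
        )
        detable.fraction = self.fraction
        logs.extend(detable.logs)
        detable.logs = list(logs)

        return MiRNAPanelDEResults(
            model=self,
            threshold=threshold,
            factors=factors,
            normalized=norm,
            mask=mask,
            kept_samples=list(kept_samples),
            groups=groups,
            robust_probes=list(robust),
            detable=detable,
            logs=logs,
        )


@dataclass
class MiRNAPanelDEResults:
    """Fitted results: estimates, evidence, diagnostics and provenance."""

    model: MiRNAPanelDE
    threshold: ThresholdResult
    factors: pd.Series
    normalized: NormalizedMatrix
    mask: DetectionMask
    kept_samples: list[str]
    groups: dict[str, str]
    robust_probes: list[str]
    detable: de_mod.DETable
    logs: list[FilterLog]

    @property
    def de_frame(self) -> pd.DataFrame:
        return self.detable.to_frame()

    @property
    def significant_probes(self) -> list[str]:
        return self.detable.significant()

    def roc(self, probes: list[str] | None = None) -> pd.DataFrame:
        """Per-probe empirical AUC with DeLong 95% CI.

        Defaults to the significant-tier probes; values are the normalized
        counts of samples detected for each probe, the same universe the
        tests used.
        """
        if probes is None:
            probes = self.significant_probes
        rows = []
        for probe in probes:
            det = self.mask.detected.loc[probe]
            sids = [s for s in self.kept_samples if det[s] and s in self.groups]
            values = self.normalized.values.loc[probe, sids]
            labels = [self.groups[s] for s in sids]
            r = diag_mod.roc_auc_ci(values, labels, variable_id=probe)
            rows.append(
                {
                    "probe_id": r.variable_id,
                    "auc": r.auc,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "orientation": r.orientation,
                    "n_case": r.n_case,
                    "n_control": r.n_control,
                }
            )
        return pd.DataFrame(rows, columns=["probe_id", "auc", "ci_low", "ci_high", "orientation", "n_case", "n_control"])

    def leaf_order(self, probes: list[str] | None = None) -> diag_mod.LeafOrder:
        """Heatmap leaf order of (by default) the significant probes."""
        if probes is None:
            probes = self.significant_probes
        sub = self.normalized.values.loc[probes, self.kept_samples]
        return diag_mod.cluster_leaf_order(sub)

    def summary(self) -> str:
        """Plain-text account of the fitted pipeline."""
        frame = self.de_frame
        n_sig = int((frame["tier"] == "significant").sum()) if len(frame) else 0
        n_trend = int((frame["tier"] == "trend").sum()) if len(frame) else 0
        lines = [
            "Two-group nCounter miRNA differential expression",
            "=" * 48,
            f"fraction:            {self.model.fraction}",
            f"normalization:       {self.model.reference}"
            + (f" (n={self.model.top_n})" if self.model.reference == "top_n" else ""),
            f"background threshold: {self.threshold.threshold:.2f} counts "
            f"(geomean {self.threshold.neg_geomean:.2f} + 2 x SD {self.threshold.neg_sd:.2f}, "
            f"n={self.threshold.n_values})",
            f"samples analysed:    {len(self.kept_samples)} "
            f"(case {sum(g == 'case' for g in self.groups.values())}, "
            f"control {sum(g == 'control' for g in self.groups.values())})",
            f"robust probes:       {len(self.robust_probes)}",
            f"significant (p<{self.model.alpha}): {n_sig}",
            f"trend (p<{self.model.trend_p}):      {n_trend}",
        ]
        for log in self.logs:
            lines.append(f"  [{log.stage}] removed {len(log.removed_ids)}: {log.criterion}")
        if n_sig:
            lines.append("")
            lines.append("top significant probes:")
            cols = ["probe_id", "n_case", "n_control", "test", "p", "direction", "pct_change"]
            head = frame[frame["tier"] == "significant"][cols].head(10)
            lines.append(head.to_string(index=False))
        return "\n".join(lines)
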