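"""End-to-end orchestration: ingest or simulate, fit each fraction, write
tables, ROC diagnostics, cross-fraction Venn bookkeeping and a run report.

A single config (YAML-loadable) names exactly one input source — RCC lane
directory, count table + sample sheet, or a simulation request — plus every
pipeline constant as a defaulted parameter.  Outputs are plain TSV/JSON with
deterministic ordering, so identical config + seed gives byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .de import venn_partition
from .exceptions import ConfigurationError
from .io import CountMatrix, read_count_table, read_rcc_dir, write_count_table, write_sample_sheet
from .model import MiRNAPanelDE
from .simulate import GroundTruth, SimulationConfig, simulate_counts

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """One pipeline run: exactly one input source plus tuning parameters."""

    count_table: str | None = None
    sample_sheet: str | None = None
    rcc_dir: str | None = None
    simulation: dict | None = None  # SimulationConfig kwargs; "fractions" lists profiles
    seed: int = 0
    top_n: int = 100
    min_rin: float = 7.0
    max_below_frac: float = 0.40
    min_frac: float = 0.75
    chauvenet_sd: float = 2.0
    chauvenet_floor: int | None = 10
    alpha: float = 0.05
    trend_p: float = 0.1
    apply_rin_gate: bool = True

    def __post_init__(self) -> None:
        sources = [
            self.count_table is not None,
            self.rcc_dir is not None,
            self.simulation is not None,
        ]
        if sum(sources) != 1:
            raise ConfigurationError("config must name exactly one input source")
        if (self.count_table is None) != (self.sample_sheet is None):
            raise ConfigurationError("count_table and sample_sheet go together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunReport:
    """Everything needed to audit one run."""

    version: str
    seed: int
    config: dict
    fractions: dict = field(default_factory=dict)  # fraction -> stage summaries
    venn: dict | None = None

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True, default=str) + "\n")
        return path


def _load_inputs(config: PipelineConfig) -> list[tuple[str, CountMatrix, GroundTruth | None]]:
    """Return one (fraction, matrix, truth) triple per fraction in the input."""
    if config.simulation is not None:
        params = dict(config.simulation)
        fractions = params.pop("fractions", [params.pop("fraction_profile", "cell_fraction")])
        out = []
        for profile in fractions:
            sim_cfg = SimulationConfig(fraction_profile=profile, seed=config.seed, **params)
            matrix, truth = simulate_counts(sim_cfg)
            out.append((profile, matrix, truth))
        return out

    if config.rcc_dir is not None:
        records = read_rcc_dir(config.rcc_dir)
        matrix = CountMatrix.from_records(records)
    else:
        matrix = read_count_table(config.count_table, config.sample_sheet)
    out = []
    for fraction in sorted(set(matrix.samples["fraction"].dropna())):
        sids = [s for s, f in matrix.samples["fraction"].items() if f == fraction]
        out.append((fraction, matrix.subset(samples=sids), None))
    if not out:
        raise ConfigurationError("no fraction labels in the sample metadata")
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Run the full flow for every fraction in the input and write artifacts.

    Per fraction: normalized values, factors, threshold report, filter log,
    DE table, ROC table and heatmap leaf order.  When two fractions are
    present, the robust probe sets are partitioned over the shared
    endogenous panel (Venn bookkeeping).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report = RunReport(version=__version__, seed=config.seed, config=asdict(config))
    robust_sets: dict[str, list[str]] = {}
    universe: set[str] = set()

    for fraction, matrix, truth in _load_inputs(config):
        tag = {"cell_fraction": "cell", "ev_fraction": "ev"}.get(fraction, fraction)
        fdir = out_dir / tag
        fdir.mkdir(exist_ok=True)

        write_count_table(matrix, fdir / "raw_counts.tsv")
        write_sample_sheet(matrix, fdir / "sample_sheet.csv")
        if truth is not None:
            truth.to_frame().to_csv(fdir / "ground_truth.tsv", sep="\t", index=False, lineterminator="\n")

        model = MiRNAPanelDE(
            matrix,
            top_n=config.top_n,
            min_rin=config.min_rin,
            max_below_frac=config.max_below_frac,
            min_frac=config.min_frac,
            chauvenet_sd=config.chauvenet_sd,
            chauvenet_floor=config.chauvenet_floor,
            alpha=config.alpha,
            trend_p=config.trend_p,
            apply_rin_gate=config.apply_rin_gate,
        )
        results = model.fit()

        results.normalized.values.round(4).to_csv(fdir / "normalized.tsv", sep="\t", lineterminator="\n")
        results.factors.round(6).to_frame().to_csv(fdir / "factors.tsv", sep="\t", lineterminator="\n")
        (fdir / "threshold.json").write_text(
            json.dumps(asdict(results.threshold), indent=2, sort_keys=True) + "\n"
        )
        with open(fdir / "filter_log.jsonl", "w") as fh:
            for log in results.logs:
                fh.write(json.dumps(log.to_dict(), sort_keys=True) + "\n")
        de_frame = results.de_frame
        de_frame.to_csv(fdir / "de_table.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.6g")
        roc = results.roc()
        roc.to_csv(fdir / "roc.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.6g")
        if len(results.significant_probes) >= 2:
            leaf = results.leaf_order()
            (fdir / "leaf_order.json").write_text(
                json.dumps({"order": leaf.order, "inversions": leaf.inversions}, indent=2) + "\n"
            )
        (fdir / "summary.txt").write_text(results.summary() + "\n")

        robust_sets[fraction] = results.robust_probes
        universe |= set(matrix.endogenous_ids)
        report.fractions[fraction] = {
            "n_samples_in": int(matrix.samples.shape[0]),
            "n_samples_analysed": len(results.kept_samples),
            "threshold": results.threshold.threshold,
            "n_robust_probes": len(results.robust_probes),
            "n_significant": len(results.significant_probes),
            "n_trend": int((de_frame["tier"] == "trend").sum()) if len(de_frame) else 0,
        }

    if len(robust_sets) == 2:
        (frac_a, set_a), (frac_b, set_b) = sorted(robust_sets.items())
        part = venn_partition(set_a, set_b, len(universe))
        report.venn = {
            "fraction_a": frac_a,
            "fraction_b": frac_b,
            **asdict(part),
        }
        (out_dir / "venn.json").write_text(json.dumps(report.venn, indent=2, sort_keys=True) + "\n")

    report.to_json(out_dir / "run_report.json")
    return report
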