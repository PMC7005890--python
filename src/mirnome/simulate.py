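"""Synthetic two-group nCounter-style miRNA panels with known ground truth.

The generator emulates the structure of a human miRNA codeset run on two
blood fractions: 798 endogenous probes, a handful of negative ligation
controls whose counts estimate background, six non-human spike-in probes
added at a fixed amount, and two groups of samples (cases vs controls).
Counts follow a negative-binomial (Poisson-gamma) model — the overdispersed
noise digital counting shows in practice — with per-probe baseline means
drawn from a log-normal distribution and a per-sample technical scale
factor applied to every probe of a lane.

Two fraction profiles are provided.  The cellular profile (PBMC-like) has
high baseline expression and moderate dispersion, so detection above
background is high; the vesicle profile (EV-like) has lower means and
higher dispersion, so its background threshold lands in the low tens while
the cellular one lands in the high tens, and detection rates differ between
profiles.

A planted subset of endogenous probes is differentially expressed between
groups with multiplicative fold effects; the planted set, directions and
folds are returned as :class:`GroundTruth` so downstream recovery can be
measured.  All draws are deterministic given the seed: each operation uses
its own RNG stream keyed by (seed, operation name), so adding operations
does not shift existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import CountMatrix, ProbeAnnotation

#: Per-fraction defaults: baseline log-mean/log-sd of the per-probe mean
#: count, endogenous dispersion, negative-control mean/dispersion.
_PROFILE_DEFAULTS = {
    "cell_fraction": {
        "baseline_log_mean": 5.5,
        "baseline_log_sd": 1.6,
        "dispersion": 0.25,
        "negative_mean": 30.0,
        "negative_dispersion": 0.3,
    },
    "ev_fraction": {
        "baseline_log_mean": 3.8,
        "baseline_log_sd": 1.8,
        "dispersion": 0.5,
        "negative_mean": 8.0,
        "negative_dispersion": 0.3,
    },
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic panel.

    ``baseline_log_mean``/``baseline_log_sd``/``dispersion`` and the
    negative-control parameters default to the fraction profile's values
    when left as ``None``.
    """

    n_endogenous: int = 798
    n_negative: int = 8
    n_spikein: int = 6
    n_case: int = 15
    n_control: int = 15
    fraction_profile: str = "cell_fraction"
    baseline_log_mean: float | None = None
    baseline_log_sd: float | None = None
    dispersion: float | None = None
    negative_mean: float | None = None
    negative_dispersion: float | None = None
    spike_mean: float = 5000.0
    spike_dispersion: float = 0.01
    scale_log_sd: float = 0.15
    n_de: int = 0
    fold_range: tuple[float, float] = (1.1, 3.0)
    de_min_expression: float = 4.0
    outlier_rate: float = 0.0
    outlier_multiplier: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction_profile not in _PROFILE_DEFAULTS:
            raise ConfigurationError(f"unknown fraction profile {self.fraction_profile!r}")
        if self.n_de > self.n_endogenous:
            raise ConfigurationError("n_de exceeds the number of endogenous probes")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ConfigurationError("outlier_rate must lie in [0, 1]")
        lo, hi = self.fold_range
        if not (lo >= 1.0 and lo <= hi):
            raise ConfigurationError("fold_range must satisfy 1 <= low <= high")
        for name in ("n_endogenous", "n_negative", "n_spikein", "n_case", "n_control", "n_de"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def resolved(self) -> "SimulationConfig":
        """Fill profile-dependent ``None`` fields from the fraction profile."""
        prof = _PROFILE_DEFAULTS[self.fraction_profile]
        updates = {
            key: prof[key]
            for key in ("baseline_log_mean", "baseline_log_sd", "dispersion",
                        "negative_mean", "negative_dispersion")
            if getattr(self, key) is None
        }
        return replace(self, **updates) if updates else self


@dataclass
class GroundTruth:
    """The simulator's planted truth, for recovery testing."""

    de_probes: dict[str, tuple[str, float]] = field(default_factory=dict)
    outlier_cells: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": list(self.de_probes),
                "direction": [d for d, _ in self.de_probes.values()],
                "fold": [f for _, f in self.de_probes.values()],
            }
        )


def _stream(seed: int, operation: str) -> np.random.Generator:
    """One RNG stream per (seed, operation name)."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(operation.encode())])


def _nbinom(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw one synthetic panel and its ground truth.

    Endogenous counts: NB(mean = baseline_i * fold_i(group) * scale_j,
    dispersion); negative controls: low-mean NB independent of group;
    spike-ins: high-mean low-dispersion NB sharing only the per-sample
    technical scale.  Deterministic given ``config.seed``.
    """
    cfg = config.resolved()

    probes = (
        [ProbeAnnotation(f"hsa-mir-sim-{i + 1:04d}", "Endogenous") for i in range(cfg.n_endogenous)]
        + [ProbeAnnotation(f"NEG_{chr(65 + i)}", "Negative") for i in range(cfg.n_negative)]
        + [ProbeAnnotation(f"SPIKE_{i + 1}", "SpikeIn", "non-human") for i in range(cfg.n_spikein)]
    )
    endo_ids = [p.probe_id for p in probes if p.code_class == "Endogenous"]

    sample_ids = [f"CASE{i + 1:02d}" for i in range(cfg.n_case)] + [
        f"CTRL{i + 1:02d}" for i in range(cfg.n_control)
    ]
    groups = ["case"] * cfg.n_case + ["control"] * cfg.n_control
    n_samples = len(sample_ids)

    rng_base = _stream(cfg.seed, cfg.fraction_profile + ":baseline")
    baseline = np.exp(rng_base.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_endogenous))

    # Planted effects must be recoverable: the DE pool is restricted to
    # probes whose baseline mean sits well above the negative-control mean
    # (factor de_min_expression), so detection censoring cannot erase the
    # planted truth.
    rng_de = _stream(cfg.seed, cfg.fraction_profile + ":de")
    if cfg.n_de:
        pool = np.nonzero(baseline >= cfg.de_min_expression * cfg.negative_mean)[0]
        if pool.size < cfg.n_de:
            raise ConfigurationError(
                f"only {pool.size} probes are expressed enough to host planted "
                f"effects; lower n_de or de_min_expression"
            )
        de_idx = rng_de.choice(pool, size=cfg.n_de, replace=False)
    else:
        de_idx = np.array([], dtype=int)
    folds = rng_de.uniform(cfg.fold_range[0], cfg.fold_range[1], cfg.n_de)
    directions = np.where(np.arange(cfg.n_de) % 2 == 0, "up", "down")
    de_probes = {
        endo_ids[i]: (str(d), float(f)) for i, d, f in zip(de_idx, directions, folds)
    }

    rng_scale = _stream(cfg.seed, cfg.fraction_profile + ":scale")
    scale = np.exp(rng_scale.normal(0.0, cfg.scale_log_sd, n_samples))

    case_mult = np.ones(cfg.n_endogenous)
    for i, d, f in zip(de_idx, directions, folds):
        case_mult[i] = f if d == "up" else 1.0 / f

    rng_counts = _stream(cfg.seed, cfg.fraction_profile + ":counts")
    endo = np.empty((cfg.n_endogenous, n_samples), dtype=np.int64)
    for j, grp in enumerate(groups):
        mult = case_mult if grp == "case" else 1.0
        mean_j = baseline * mult * scale[j]
        endo[:, j] = _nbinom(rng_counts, mean_j, cfg.dispersion)

    rng_neg = _stream(cfg.seed, cfg.fraction_profile + ":negative")
    neg = np.empty((cfg.n_negative, n_samples), dtype=np.int64)
    for j in range(n_samples):
        neg[:, j] = _nbinom(
            rng_neg, np.full(cfg.n_negative, cfg.negative_mean) * scale[j], cfg.negative_dispersion
        )

    rng_spike = _stream(cfg.seed, cfg.fraction_profile + ":spikein")
    spk = np.empty((cfg.n_spikein, n_samples), dtype=np.int64)
    for j in range(n_samples):
        spk[:, j] = _nbinom(
            rng_spike, np.full(cfg.n_spikein, cfg.spike_mean) * scale[j], cfg.spike_dispersion
        )

    counts = pd.DataFrame(
        np.vstack([endo, neg, spk]) if cfg.n_negative or cfg.n_spikein else endo,
        index=pd.Index([p.probe_id for p in probes], name="probe_id"),
        columns=sample_ids,
        dtype="int64",
    )
    ann = pd.DataFrame(
        {"code_class": [p.code_class for p in probes], "accession": [p.accession for p in probes]},
        index=counts.index,
    )
    rng_rin = _stream(cfg.seed, cfg.fraction_profile + ":rin")
    if cfg.fraction_profile == "cell_fraction":
        rin = np.clip(rng_rin.normal(8.6, 0.6, n_samples), 1.0, 10.0).round(1).tolist()
    else:
        rin = [None] * n_samples
    samples = pd.DataFrame(
        {"group": groups, "fraction": [cfg.fraction_profile] * n_samples, "rin": rin},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = CountMatrix(counts=counts, annotations=ann, samples=samples)
    truth = GroundTruth(de_probes=de_probes, seed=cfg.seed)

    if cfg.outlier_rate > 0:
        matrix, truth = inject_outliers(
            matrix, truth, cfg.outlier_rate, cfg.outlier_multiplier, cfg.seed
        )
    return matrix, truth


def inject_outliers(
    matrix: CountMatrix,
    truth: GroundTruth,
    rate: float,
    multiplier: float,
    seed: int,
) -> tuple[CountMatrix, GroundTruth]:
    """Multiply a Bernoulli(rate) selection of endogenous cells by ``multiplier``.

    Outliers are multiplicative so they survive normalization, as real flier
    counts do; control probes (negative/spike-in) are left untouched so the
    background threshold and technical factors are unaffected.  Selected
    cells are recorded in ``GroundTruth.outlier_cells``.
    """
    if not (0.0 <= rate <= 1.0):
        raise ConfigurationError("rate must lie in [0, 1]")
    if multiplier <= 1.0:
        raise ConfigurationError("multiplier must exceed 1")
    new_counts = matrix.counts.copy()
    cells: list[tuple[str, str]] = []
    if rate > 0:
        rng = _stream(seed, "outliers")
        endo = matrix.endogenous_ids
        pick = rng.random((len(endo), len(matrix.sample_ids))) < rate
        sub = new_counts.loc[endo].to_numpy()
        sub[pick] = np.rint(sub[pick] * multiplier).astype(np.int64)
        new_counts.loc[endo] = sub
        rows, cols = np.nonzero(pick)
        cells = [(endo[i], matrix.sample_ids[j]) for i, j in zip(rows, cols)]
    out = CountMatrix(counts=new_counts, annotations=matrix.annotations.copy(), samples=matrix.samples.copy())
    new_truth = GroundTruth(
        de_probes=dict(truth.de_probes),
        outlier_cells=list(truth.outlier_cells) + cells,
        seed=truth.seed,
    )
    return out, new_truth
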