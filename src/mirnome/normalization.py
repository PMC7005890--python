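"""Background thresholding and reference-set geometric-mean normalization.

Background is estimated per blood fraction from the negative ligation
controls: the geometric mean of all pooled negative-control counts plus two
standard deviations.  Raw counts strictly below that threshold are treated
as non-detected and censored from every downstream statistic (the platform
censors rather than subtracts background).

Technical normalization rescales each sample so the geometric mean of a
reference probe set is equal across samples.  The cellular fraction uses
the top-100 endogenous probes by mean raw count (content normalization);
the vesicle fraction, where no stable endogenous reference exists, uses
the six non-human spike-in probes (technical normalization).

Conventions, recorded here because dialects differ between tools: zeros are
replaced by 1 before any geometric mean (platform convention); standard
deviations use the n-1 (sample) formula; detection is ``raw >= threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateInputError, IntegrityError
from .io import CountMatrix

REFERENCES = ("top_n", "spikein")


@dataclass(frozen=True)
class ThresholdResult:
    """Fraction-level background threshold and its components.

    ``threshold == neg_geomean + 2 * neg_sd`` exactly; ``n_values`` is the
    number of pooled negative-control counts (probes x samples).
    """

    threshold: float
    neg_geomean: float
    neg_sd: float
    n_values: int


@dataclass
class NormalizedMatrix:
    """Per-sample rescaled counts plus the censoring mask.

    ``values[i, j] = raw[i, j] * factors[j]``.  ``detected`` flags cells
    whose *raw* count reached the background threshold; censored values are
    retained for inspection but must be excluded from downstream statistics.
    """

    values: pd.DataFrame
    factors: pd.Series
    reference: str
    threshold_applied: ThresholdResult
    detected: pd.DataFrame
    raw: CountMatrix

    @property
    def samples(self) -> pd.DataFrame:
        return self.raw.samples

    @property
    def annotations(self) -> pd.DataFrame:
        return self.raw.annotations


def geometric_mean(values: np.ndarray) -> float:
    """Geometric mean with zeros replaced by 1 (platform convention)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateInputError("geometric mean of an empty set")
    if (values < 0).any():
        raise ValueError("geometric mean of negative values")
    values = np.where(values == 0, 1.0, values)
    if values.max() == values.min():  # exact for constant input
        return float(values[0])
    return float(np.exp(np.mean(np.log(values))))


def background_threshold(matrix: CountMatrix) -> ThresholdResult:
    """Pool all negative-control counts of the fraction and return
    geometric mean + 2 sample standard deviations.

    The SD is taken over the pooled counts as observed (zeros included);
    only the geometric mean applies the zero -> 1 replacement.
    """
    neg_ids = matrix.probes_of_class("Negative")
    if not neg_ids:
        raise ConfigurationError("no Negative-class probes in the panel")
    pooled = matrix.counts.loc[neg_ids].to_numpy(dtype=float).ravel()
    if pooled.size < 2:
        raise DegenerateInputError("fewer than 2 pooled negative-control values")
    geomean = geometric_mean(pooled)
    sd = float(np.std(pooled, ddof=1))
    return ThresholdResult(
        threshold=geomean + 2.0 * sd,
        neg_geomean=geomean,
        neg_sd=sd,
        n_values=int(pooled.size),
    )


def reference_factors(
    matrix: CountMatrix,
    reference: str,
    n: int = 100,
) -> pd.Series:
    """Per-sample scale factors equalizing the reference-set geometric mean.

    ``top_n``: the reference set is the ``n`` endogenous probes with the
    highest mean raw count across samples (ties broken by probe_id); this is
    chosen on raw counts, before any censoring, since factor computation
    precedes normalization.  ``spikein``: the SpikeIn-class probes.

    factor(sample) = mean over samples of reference geomeans / that
    sample's reference geomean, so factors average to 1 on the geomean
    scale and all are > 0.
    """
    if reference not in REFERENCES:
        raise ConfigurationError(f"unknown reference {reference!r}")
    if reference == "top_n":
        endo = matrix.endogenous_ids
        if len(endo) < n:
            raise ConfigurationError(f"top_n reference needs >= {n} endogenous probes, have {len(endo)}")
        means = matrix.counts.loc[endo].mean(axis=1)
        order = sorted(endo, key=lambda p: (-means[p], p))
        ref_ids = order[:n]
    else:
        ref_ids = matrix.probes_of_class("SpikeIn")
        if not ref_ids:
            raise ConfigurationError("spikein reference requires SpikeIn-class probes")

    geomeans = pd.Series(
        {sid: geometric_mean(matrix.counts.loc[ref_ids, sid].to_numpy()) for sid in matrix.sample_ids}
    )
    target = float(geomeans.mean())
    factors = target / geomeans
    factors.name = "factor"
    factors.attrs["reference_ids"] = list(ref_ids)
    return factors


def apply_normalization(
    matrix: CountMatrix,
    factors: Mapping[str, float] | pd.Series,
    threshold: ThresholdResult,
) -> NormalizedMatrix:
    """Rescale counts by per-sample factors and censor sub-threshold cells.

    Cells whose raw count is strictly below the threshold are flagged
    non-detected regardless of the factor; the normalized value is kept for
    inspection.  Dividing ``values`` by the factors recovers raw counts
    exactly.
    """
    factors = pd.Series(dict(factors)) if not isinstance(factors, pd.Series) else factors
    missing = [s for s in matrix.sample_ids if s not in factors.index]
    if missing:
        raise IntegrityError(f"missing normalization factors for samples: {missing}")
    factors = factors.loc[matrix.sample_ids].astype(float)
    if (factors <= 0).any():
        raise IntegrityError("normalization factors must be positive")
    values = matrix.counts.astype(float).mul(factors, axis=1)
    detected = matrix.counts.ge(threshold.threshold)
    reference = factors.attrs.get("reference_ids")
    ref_kind = "spikein" if reference and all(
        matrix.annotations.loc[r, "code_class"] == "SpikeIn" for r in reference
    ) else "top_n"
    return NormalizedMatrix(
        values=values,
        factors=factors,
        reference=ref_kind,
        threshold_applied=threshold,
        detected=detected,
        raw=matrix,
    )
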