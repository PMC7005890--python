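# Methods

This note records the statistical procedure the package implements, the
conventions chosen where dialects differ between tools, what the synthetic
panels do and do not emulate, and the known limitations.

## Data model

The pipeline's currency is an integer probe × sample count grid
(`CountMatrix`) with probe-class annotations (Endogenous, Negative,
Positive, SpikeIn, Housekeeping) and per-sample metadata (group, blood
fraction, optional RIN). Counts are digital molecule counts and are kept as
hard integers; fractional inputs are rejected rather than rounded.
Probe-class strings are matched case-insensitively through an alias table;
in particular "Ligation" probes — the negative ligation controls of miRNA
codesets — map to the Negative class, since their counts estimate
background.

## Background threshold

Per fraction, all Negative-class counts of all samples are pooled and the
threshold is their geometric mean plus two standard deviations. Conventions:

- zeros are replaced by 1 before the geometric mean only (the platform's
  convention); the SD is computed on the pooled counts as observed;
- the SD is the sample (n−1) standard deviation, consistently everywhere in
  the package;
- detection is `raw count ≥ threshold`; strictly smaller counts are
  censored. Censoring, not background subtraction: censored cells keep
  their normalized value for inspection but are excluded from every
  downstream statistic.

One pooled threshold per fraction (rather than per sample) is used because
a single number per fraction is what this thresholding style reports; on
the synthetic defaults it lands in the high tens for the cellular profile
and the low tens for the vesicle profile.

## Normalization

Per-sample factors equalize the geometric mean of a reference probe set:
factor(s) = mean over samples of the reference geomeans / sample s's
reference geomean, so factors are positive and average to one on the
geomean scale. The cellular fraction uses the 100 endogenous probes with
the highest mean raw count (ties broken lexicographically by probe id),
selected before any censoring since factors are computed from raw counts;
the cell-free fraction, which has no stable endogenous reference, uses the
spike-in probes. After normalization the per-sample reference geomeans
agree to a relative 1e-9, and dividing by the factors recovers raw counts
exactly.

## Filter cascade

1. **RIN gate**: cellular samples with RIN strictly above 7 pass (exactly
   7 fails); cell-free samples pass unconditionally; a cellular sample
   without a RIN is an error, not a silent pass.
2. **Low-coverage samples**: a sample is dropped when the fraction of
   non-detected probes is ≥ 0.40 (boundary inclusive). The probe universe
   for this rule is the endogenous probes detected in at least one sample
   — i.e. the probes that entered normalization at all; the choice is
   recorded in the filter log since "the normalized miRNAs" admits more
   than one reading.
3. **Robust probes**: kept when detected in ≥ 0.75 of samples of either
   group (inclusive; one group suffices).

Thresholds and factors are not recomputed after sample drops, matching the
fixed order normalize → drop samples → select probes. Every stage emits a
log entry (stage, removed ids, criterion, parameters) from which the
sample/probe universe at any point can be reconstructed.

## Two-group testing

Per probe, the sample universe is the set of samples detected for that
probe — per-probe n therefore varies. Normality is assessed per group with
Shapiro–Wilk (p > 0.05 ⇒ normal; groups with n < 3 or constant values
count as non-normal). Both groups normal ⇒ two-sided equal-variance
Student's t (Welch available behind a flag); otherwise two-sided
Mann–Whitney, exact when both n ≤ 15 and the pooled data is tie-free,
normal approximation with tie and continuity correction otherwise.
Requiring *both* groups to pass normality is the conservative reading of a
branch rule that could also be read one-sided; it is configurable.

Tiers: p < 0.05 significant, 0.05 ≤ p < 0.1 trend. No multiple-testing
correction drives the tiers; a Benjamini–Hochberg column is attached to
the output table as supplementary information only.

**Outlier adjustment.** Probes whose first-pass p falls below the trend
cutoff are re-tested after a single-pass per-group outlier filter: values
farther than 2 sample SDs from their group mean are removed (no
re-iteration), never removing below a per-group floor of 10 retained
values (most extreme removed first; the floor is configurable and disabled
at the raw-function level). Removal — not winsorizing — is used, so
per-group n shrinks and the shrinkage is reported. Note the classical
Chauvenet rule (expected count < 0.5 under the normal tail) is *not* the
default; the explicit 2-SD band is.

This re-testing step is mildly anticonservative by construction: trimming
tails shrinks the within-group variance, and on null panels it raises the
significant-tier fraction from ≈ 0.055 (first pass) by roughly 0.02–0.03.
That is a property of the procedure itself, visible in the package's null
calibration, and worth keeping in mind when interpreting borderline hits.

**Percent change** uses an asymmetric convention: over-expression is
100·(case − control)/control, under-expression 100·(control − case)/case —
the only convention under which under-expression can exceed 100%. Location
summaries are medians when the final test is Mann–Whitney, means under t.

## ROC diagnostics

The empirical AUC equals the Mann–Whitney U statistic divided by
n_case·n_control, ties counting ½ (verified against exhaustive pair
counting). The 95% CI uses the DeLong placement-value variance, truncated
to [0, 1]; orientation is auto-selected so AUC ≥ 0.5 and reported. The
implementation reproduces the reference R implementation's DeLong interval
to 1e-12 on fixture data.

## Heatmap leaf ordering

Probe rows are clustered agglomeratively on Spearman distance
(1 − rank correlation; constant rows get distance 1 to everything, with a
warning) with centroid linkage via the Lance–Williams update on squared
distances. Centroid linkage over a correlation distance is not a proper
Euclidean centroid; negative squared updates are clamped to zero and
height inversions are recorded in the linkage record rather than hidden.
Ties break on the smallest cluster-index pair and leaves are emitted
left-before-right with the lower-index cluster left, making the order
deterministic.

## Synthetic panels

The generator emulates a human miRNA codeset run: 798 endogenous probes, 8
negative ligation controls, 6 non-human spike-ins, and two groups of 15
samples by default. Counts are negative-binomial (Poisson–gamma), the
overdispersed noise digital counting shows, with per-probe baseline means
drawn log-normally and a log-normal per-sample technical scale factor
(SD 0.15) applied to every probe of a lane. Profile defaults:

| parameter | cellular | vesicle |
|---|---|---|
| baseline log-mean / log-SD | 5.5 / 1.6 | 3.8 / 1.8 |
| endogenous dispersion | 0.25 | 0.5 |
| negative-control mean (dispersion 0.3) | 30 | 8 |
| spike-in mean (dispersion 0.01) | 5000 | 5000 |

These place the background threshold in the high tens (cellular) and low
tens (vesicle) and give per-sample detection comfortably above the 40%
coverage rule, with the vesicle profile noisier and sparser — the
qualitative contrast between cellular and cell-free fractions. Dispersion
values are calibration choices, not inferences from any dataset.

Planted differential expression multiplies case-group means by a fold
drawn from the configured range (alternating up/down). The DE-eligible
pool is restricted to probes with baseline mean ≥ 4× the negative-control
mean (`de_min_expression`): planted truth must be recoverable in
principle, and an effect planted below background would be erased by
censoring, not by the testing machinery. Injected outliers multiply a
Bernoulli selection of endogenous cells (controls excluded, so thresholds
and factors are unaffected) by a configured factor — multiplicative so
they survive normalization, as real flier counts do.

Randomness: every operation draws from its own RNG stream keyed by
(seed, fraction profile, operation name), so identical seeds give
bit-identical panels and adding operations does not shift existing draws.

What the simulator does *not* emulate: lane/cartridge batch effects,
positive-control titration curves, probe cross-hybridization, sample
pairing, or any real miRNA identity. Passing calibration and recovery
tests therefore demonstrates the pipeline's statistical behaviour under a
clean overdispersed count model, not performance on any particular cohort.

## Problem sizes and numerical choices

The bundled experiments use the default panel (798 probes, 15 vs 15, or
13 vs 13 with 20 planted fold-2 effects for recovery), which runs the full
chain in a few seconds. Degenerate inputs are handled explicitly: constant
groups route to the rank test with p = 1 when groups are identical;
geometric means of constant vectors are returned exactly; an empty
reference set, absent negative controls, or a group with fewer than two
detected samples raise typed errors (the last is logged and the probe
excluded rather than failing the run).

## Limitations

- Cohort-level numbers from real data (the 69/17-count thresholds, specific
  marker lists, individual AUCs) require the original deposited dataset and
  are treated as documented expectations, not test assertions.
- The percent-change convention and the both-groups normality rule are
  inferences from reported ranges and practice, exposed as options.
- No paired designs, covariates or batch terms; comparisons are strictly
  two independent groups.
- The Chauvenet-adjusted re-test inflates the false-positive rate slightly
  (see above); users wanting strict error control should gate on the
  supplementary BH column instead of the unadjusted tiers.
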