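# Methods

This note records the statistical models, default parameters and design
choices behind each module, and what the synthetic benchmarks do and do not
establish about real data.

## Data model

Abundance matrices are features × samples, nonnegative on the linear scale.
Protein values are LFQ intensities where a stored zero means *not
detected* — absence, not low abundance. Transcript values are TPM; zeros
there are ordinary low counts. All log transforms are log2(x + pseudocount)
with pseudocount 1 by default, so protein zeros map to exactly 0 on the log
scale and absence is preserved rather than silently converted into a
detected value. The study design binds each sample to a region (LD/SD), an
ordered stage (E57 < E73 < E90 < P1 < P28 < P120) and a replicate; the
stage order is total and fixed, and identifiers are case-sensitive.

Stage correlation matrices are Pearson correlations between stage-mean log2
profiles, pooled across regions by default (one 6×6 matrix; a per-region
mode is available). Features with zero variance across the full set of
stage profiles are excluded before correlating and non-finite values are
excluded pairwise; a feature constant across one particular stage pair is
retained, since it still carries information for the across-feature
correlation of that pair. PCA treats samples as observations, centers
features, does not unit-scale them by default (abundance-PCA convention; a
scaling flag exists), and fixes signs so the largest-magnitude loading of
each component is positive.

## Differential testing

Per contrast, each feature is tested with a two-sided t test (student
pooled-variance by default, Welch by option) on log2(x+1) values, while the
reported fold change is the ratio of linear-scale group means; the stored
log2FC is log2 of that ratio, so the linear gates (1.2, 0.833) and the
log2 gates (|log2FC| ≥ 1) are applied on consistent scales. Protein zeros
are removed before testing; features with fewer than two detected
replicates in either group are skipped and logged, not imputed — the
presence module handles those. Degenerate features (zero variance in both
groups) get p = 1 when the means agree and p = 0, flagged, otherwise.

BH correction is computed per contrast over its tested features, not
globally, so each comparison's DAP count is self-contained. Threshold
boundaries are inclusive for fold change (≥ 1.2, ≤ 0.833) and strict for
p (< 0.05). Note that 0.833 is a rounding of 1/1.2, which makes the
region-DAP gate very slightly asymmetric under group reversal; the DEG
gate (0.5, 2) is exactly symmetric.

## Presence dynamics

The default rule is strict: a protein *increases* at a transition when
every replicate is 0 at the earlier stage and every replicate is > 0 at the
later one; *decreasing* mirrors it. A stage-mean variant (mean 0 vs
mean > 0) is offered because per-replicate behavior of an intensity-based
rule is a free choice; strict calls are provably a subset of mean-based
calls. For decreases, an additional delta mode (any negative stage-mean
change, no absence required) is provided since a subtraction-based decrease
rule admits both readings; outputs are labeled with the policy used and the
two readings are never conflated.

## Trend clustering

Clustering input is one region's stage-mean log2 profiles (6 points per
feature), z-scored per feature with the sample-sd convention; constant
profiles are excluded. Fuzzy c-means uses the classic alternating updates
with fuzzifier m = 2.0 (fixed for reproducibility rather than estimated
from the data), c = 4 clusters by default, k-means++ seeding from the given
seed, tol 1e−6, max 300 iterations. Exact-zero distances assign full
membership to the coincident center. The objective is non-increasing by
construction and checked in the benchmarks.

Because cluster indices are arbitrary, tendencies are relabeled
canonically — clusters ordered by the stage index of the center's maximum,
then by the center value at the final stage — so "Tendency k" is comparable
across regions, seeds and runs. Hard labels are argmax memberships (ties to
the lowest raw index); an optional minimum-membership threshold labels
ambiguous features as unassigned. Cross-region composition per tendency
reports shared and region-unique feature counts and their differing
fraction.

## Concordance classification

With threshold t = 1 on |log2FC| (|FC| = 2, boundary counted as changed)
and predicates R/P (RNA/protein changed) and S (sign agreement; zero agrees
with either sign), the precedence rule assigns: neither → Type 1; both,
concordant → Type 6; both, discordant → Type 5; exactly one changed,
concordant → Type 4; protein-only, discordant → Type 2; RNA-only,
discordant → Type 3. The published category descriptions overlap (a
"changed at either level" reading of Type 4 intersects Types 2/3/6); this
precedence resolution is total and single-valued on ℝ², verified
exhaustively on a grid, and the rule-variant name is stamped into every
record so alternative readings can be added as pluggable strategies.

Paired fold changes are computed identically in both modalities from
linear group means with pseudocount 1; genes absent or undetected in one
modality are excluded and counted. The default contrast is the per-stage
region comparison; a prenatal-vs-postnatal mode exists because both
framings are plausible for this analysis and they are not equivalent.

## Enrichment

Over-representation is the hypergeometric upper tail P(X ≥ k) via the
survival function. The background defaults to the features quantified in
the relevant matrix — the detected-proteome background that guards against
detection bias — not the annotation universe. Term sizes are counted within
the background; bounds 3–500 by default; BH is over tested terms only;
ties sort deterministically by (p, term id).

## Harmonization

Batch adjustment is a per-feature least-squares fit of
value = intercept + covariate effects + batch shift, followed by removal of
the batch shifts and rescaling of residuals from their per-batch spread to
the pooled spread (batches with near-zero residual spread are left
unscaled). This is a plain location–scale adjustment: relative to
empirical-Bayes shrinkage approaches it forgoes pooling across features,
which matters little at ≥ 3 replicates per batch and gives a directly
testable contract — batch moments equalized to numerical precision,
protected covariate contrasts preserved exactly in the noiseless limit.
Confounding between batch and covariates is detected by a rank check and
reported with the aliased columns. Single-copy ortholog groups are a
precondition of the input table, not something the module resolves.
Profile clustering is k-means with a fixed seed and 10 initializations;
clusters are named C1..Ck in decreasing size order, with per-species mean
trajectories exported. The cluster count is a free parameter (default 9).

## Synthetic data generator

The generator emulates the 2-region × 6-stage × 3-replicate design.
Per-gene baseline log2 abundances are Normal(20, 1.5) for protein (LFQ
scale) and Normal(6, 1.5) for RNA (TPM scale); replicate noise is
Normal(0, 0.3) on the log2 scale; linear protein values below the
detection limit (2^14 by default) are stored as 0. Zeros are produced
mechanistically by censoring, not by a random dropout mask, so
presence-event truth is well defined. Planted classes partition the genes:

- differential genes get a ±1.5 log2 region shift at every stage,
- presence genes sit 5 log2 units below the detection limit on the absent
  side of one transition and 5 above on the present side (with the other
  region kept detected), making planted events recoverable exactly,
- trend genes add one of four archetype shapes (decline from E90, birth
  peak, birth trough, monotone rise) at ±1.5 log2 amplitude in both
  regions and both modalities,
- concordance genes draw paired RNA/protein region effects from the
  interior of one of the six type regions, 0.25 log2 units away from every
  boundary, under the default mixture (60/15/15/4/3/3 %).

Annotation terms of size 10–50 are drawn over the gene universe; three
terms take 60% of their members from the differential genes and are flagged
enriched. One root seed spawns independent per-section generators, so the
same config and seed reproduce bit-identical outputs.

What the generator does *not* emulate: intensity-dependent missingness
(zeros appear only via the detection limit), correlated noise across genes,
compositional TPM constraints, batch structure within the study, or the
real study's abundance distributions. Passing benchmarks therefore
establish that the algorithms are implemented correctly and behave as
designed under their stated assumptions — not that those assumptions hold
in any particular real dataset.

## Benchmark design and problem sizes

The standard benchmarks (in `omnifiber.benchmarks`, asserted in the test
suite and re-measured by `scripts/acceptance.py`) use these sizes:

- Null calibration: 20,000 features, n = 3 vs 3, σ = 0.3, student variant.
  Raw p < 0.05 fraction expected at 0.05; BH q < 0.05 essentially never
  rejects under the global null.
- Differential recovery: 2,000 features, planted 1.5-log2 effects,
  σ = 0.3, region-DAP policy, 40% planted prevalence. The prevalence is a
  design parameter of the benchmark: the raw-p + FC-gate policy rejects
  ≈ 4.5% of nulls, so its observed FDR is a prevalence property —
  (1−π)·0.045 / ((1−π)·0.045 + π·0.99) — and π = 0.4 places both target
  operating characteristics (sensitivity ≥ 0.9, observed FDR ≤ 0.1)
  inside the policy's power curve rather than on its boundary.
- Six-type classifier: exhaustive grid over [−4, 4]² at step 0.1 against
  direct predicate evaluation, plus a 10,000-gene planted mixture; with
  the 0.25 margin the classification of planted pairs is exact, so
  recovery error is purely binomial (≈ 0.5 percentage points at the
  largest class).
- Fuzzy c-means: 400 features from the 4 archetypes at σ = 0.3, 10
  clustering seeds; objective monotonicity on 50 further seeds.
- Hypergeometric tail: every parameter combination with N ≤ 25 (44,226
  cases) against exact enumeration.
- Presence rules: a 20-feature hand-built fixture whose expected counts
  are enumerated manually (5 clean gains, 5 clean losses, 1 later gain,
  plus partial patterns that must not be called strictly).
- Batch adjustment: noiseless two-batch shift with a balanced protected
  covariate; gaps and contrast errors at numerical precision.
- Integration: one 600-gene study with every planted class, run through
  the full pipeline.

These sizes keep the whole validation suite under a minute while leaving
every check comfortably powered.

## Known limitations

- The empirical-Bayes pooling of standard batch-correction tools is
  intentionally not implemented; very small batches (2 samples) gain
  nothing from the residual rescaling and are rejected outright.
- The fuzzifier m and initialization of the reference time-course
  clustering tooling are unreported in general use; results that depend on
  them cannot be reproduced bit-exactly by any reimplementation, which is
  why m is fixed and logged here.
- Concordance Types 2/3 are defined purely by fold change; no significance
  filter is applied to "changed" beyond the threshold.
- The region-DAP policy controls per-comparison type-I error, not FDR; its
  observed FDR depends on prevalence, as quantified above.
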