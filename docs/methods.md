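# Methods

This note documents the models and procedures implemented in
`orthoarray`, the parameters that matter, the numerical choices, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Probe matching

A *hit* is an ungapped alignment of a full 25-mer PM probe to a 25-nt
window of a transcript, at offsets 0 … len − 25. Windows that would
overhang a transcript end are not considered: a shared 20-mer whose
implied 25-nt window falls outside the transcript is not a hit. This
window-based contract is shared by the seed-and-extend implementation
and by the exhaustive scanner used to validate it, and it is what makes
the tier definitions unambiguous. `N` bases in transcripts match
nothing; probes themselves are strictly ACGT.

Tier definitions, in precedence order:

- **EXACT** — zero mismatches.
- **END_MM** — every mismatch lies in a contiguous prefix and/or suffix
  of the probe, with 1 ≤ total ≤ `max_end_mismatch` (default 2). Both
  ends may carry mismatches simultaneously; an internal mismatch
  disqualifies the tier.
- **TANDEM** — longest contiguous run of matches ≥ `min_tandem`
  (default 20), mismatches anywhere.
- **RESCUE** — all mismatches terminal, total ≤ `rescue_max_end_mismatch`
  (default 9, so a contiguous core of ≥ 16). Off by default: it models
  the manual salvage of probe sets that fail the stricter tiers, and
  keeping it opt-in keeps the headline pipeline deterministic and
  strict.

Each (transcript, offset, strand) pair yields at most one hit, at its
best tier. Both strands are searched by default (probe-table export
conventions vary); strand is recorded and a flag restricts search to
the given orientation.

**Seeding.** Transcripts are indexed by exact k-mers with
k = `min_tandem`, shrunk to 25 − `rescue_max_end_mismatch` when the
rescue tier is enabled. Every qualifying hit contains a contiguous
exact run of at least k bases, and any such run of length ≥ k within a
25-mer contains a k-mer starting at a seedable probe position, so the
index discovers every hit (completeness). Seeds shorter than 8 are
refused to bound the index size.

## Library construction

Per probe set: (1) probes whose hits span ≥ 2 *genes* are removed —
specificity is judged at the gene level, because cDNA databases carry
several transcripts per gene and the end goal is a one-to-one
probe-set↔gene map; (2) the set is assigned to the gene hit by the
plurality of the remaining probes, ties broken by the higher summed
tier rank (EXACT 4 … RESCUE 1) and then the lexicographically smallest
gene id; (3) probes pointing at any other gene ("intermingling") are
dropped; (4) the representative transcript is the assigned-gene
transcript hit by the most retained probes (ties: smallest id);
(5) sets with < 3 probe pairs are rejected — three pairs is the
accepted floor for probe-level summarization algorithms.

When the rescue tier is enabled and step (1) would eliminate *every*
probe of a set, specificity is re-judged on each probe's best-tier hits
only, so a probe EXACT to one gene and rescue-level to another counts
as specific. This is the programmatic form of the manual review such
sets traditionally received.

Redundancy collapse keeps one probe set per gene — most retained
probes, then higher summed tier rank, then smallest probe-set id. Every
tie-break in the package is total and documented, so identical inputs
give byte-identical libraries; the library's `created` field is derived
from the content hash of the cDNA database and the matching parameters
rather than the wall clock for the same reason.

MM probes are never matched independently: the MM partner of a retained
PM probe is defined positionally (complement at base 13) and carried
only by the probe-pair bookkeeping. The canonical library format is
versioned JSON; an ASCII CDF-like text export is provided for
interoperability, and binary CDF/CEL formats are out of scope.

## Intensity binding

Rather than editing CEL headers to point at a new library, a library
and a set of CEL files are paired explicitly at call time; header
library names are ignored. Remapping is a pure coordinate lookup —
values are never transformed — which makes subset/permutation
properties exactly testable.

## RMA

- **Background** (per array): observed = signal + noise with
  signal ~ Exp(1/α), noise ~ N(μ, σ²). μ is the mode of a
  Silverman-bandwidth Gaussian KDE evaluated on a 512-point uniform
  grid; σ is the RMS of the sub-mode half times √2; α is the mean
  excess over the mode. The corrected value E[signal | observed]
  = m + σ·φ(m/σ)/Φ(m/σ) with m = x − μ − σ²/α, evaluated with the
  log-scale normal CDF for stability; it is strictly positive and
  monotone. The estimator constants are fixed and validated against a
  quadrature oracle rather than bit-matched to any legacy code.
- **Quantile normalization** (across arrays): each column's sorted
  values are replaced by the row-wise mean of all columns' sorted
  values; tied values within a column receive the mean of the
  reference values their ranks span, preserving within-column ranks.
  The reference is computed after sorting each rank's values so the
  result is bit-for-bit independent of sample order.
- **Median polish** (per probe set, after log₂): alternating row/column
  median sweeps in the classic order (row medians, recentre column
  effects, column medians, recentre row effects) until the total
  absolute residual changes by less than `mp_tol` (default 0.01) or
  `mp_max_iter` (default 10) sweeps. The expression estimate per sample
  is the overall effect plus the column effect.

Normalization pools the library's PM probes — the virtual array is the
analysis unit — with a whole-chip flag for comparing against
full-design pipelines.

Two behaviours of this chain are worth knowing. Quantile normalization
remaps by rank, so in near-noiseless data a differential shift that
crosses no other gene's values can be partially or entirely removed;
with realistic noise and modest differential fractions the effect is a
small global attenuation. And background correction assumes a
background-dominated probe population; applied to data with no additive
background component it over-subtracts. Both are properties of the
standard algorithms, not of this implementation, and they drive two
defaults below.

## ANN ranking

Each transcript is scored alone: a 1 → `hidden_units` (2) → 1 network
with logistic activations, squared-error loss, full-batch gradient
descent with learning rate 0.5 and momentum 0.9 on inputs min-max
scaled from the training subset. Samples are split 60/20/20 by a
largest-remainder rule (ties to the earlier subset: 18 samples give
11/4/3); a split whose training subset misses a class is redrawn, up to
100 times. Training stops when validation error has not improved for
`patience` (25) cycles or at `max_cycles` (300); the reported score is
the test error at the best-validation snapshot. The mean over
`n_resamples` (50) independent splits ranks the transcripts ascending;
ties break by standard deviation, then id. Learning rate, momentum,
patience and cycle budget are this package's choices, made once for
stable convergence of the tiny network on unit-scaled inputs.

The early-stopping criterion is "validation error fails to *decrease*
for a fixed number of cycles"; the literal alternative reading
(fails to increase) is selectable via `early_stop_mode` but is not the
default, as it rewards divergence.

Randomness is keyed per (transcript name, resample index) from the
master seed — via CRC32 of the transcript id — so rankings are
reproducible, independent of row order, and unchanged when unrelated
transcripts are added or removed. All (transcript × resample) networks
are trained simultaneously as one batched computation; this changes
nothing numerically, only the wall-clock.

Failed resamples (non-finite loss) are excluded from the mean and
counted per transcript.

**Interactions.** For each of the top-k markers, a (k−1) → 2 → 1
network predicts that marker (min-max scaled) from the rest; the
influence of marker i on j is the mean over samples of ∂ĵ/∂xᵢ at the
trained weights. These networks are function fits, not generalization
estimates, so they train on all samples and stop when the *training*
error plateaus (patience 50, max 500 cycles) — an early-stopped
validation split at n = 18 leaves the nets near initialization and the
gradients uninformative. Constant markers get zero rows/columns with a
warning. The 10 most positive and 10 most negative off-diagonal entries
form the reported edge list.

## Fold changes and enrichment

Signed fold change: r = 2^(mean log₂ treated − mean log₂ control),
reported as r if r ≥ 1 else −1/r, so no value lies in (−1, 1) and
no-change is exactly 1. The differential threshold is deliberately an
explicit argument (default |FC| ≥ 2 in the pipeline config) — the
appropriate cutoff is study-specific.

Enrichment: P(X ≥ k) for X ~ Hypergeometric(N, K, n) summed in log
space from `gammaln` terms; exact for all parameter sizes in use and
validated against integer enumeration. The background defaults to the
genes represented in the library and is overridable.
Benjamini–Hochberg step-up adjustment (via statsmodels) controls FDR;
significance is adjusted p < 0.05. The FDR procedure is isolated behind
one function so alternatives could be swapped.

## Synthetic data

The generator is a pure function of a `FixtureSpec`; identical specs
give byte-identical artifacts. Defaults define the study conditions:

- 200 genes, 1–3 transcripts each sharing a 600-nt core (variants add
  random 150-nt flanks); uniform base composition.
- 200 probe sets × 11 probe pairs, planted at tier proportions
  EXACT .56 / END_MM .12 / TANDEM .11 / RESCUE .05 / MULTI_GENE .08 /
  NO_HIT .08 (largest-remainder exact counts, dealt round-robin so
  every set gets a balanced mix). END_MM probes mutate 1–2 terminal
  bases; TANDEM probes mutate positions 2 and 24 (1-based), leaving a
  21-nt core with non-terminal mismatches; RESCUE probes mutate 4 + 3
  terminal bases (18-nt core, invisible to the default tiers);
  MULTI_GENE probes are copied into a second gene's transcript; NO_HIT
  probes are rejection-sampled to share no 16-mer with the final
  transcriptome on either strand, so not even the rescue tier can fire.
- 18 samples: 3 replicates × 2 time points × 3 dose groups
  (vehicle/low/high), class 0 = vehicle. 20 differential genes at
  ±1.5 log₂ (≈ 2.8-fold) at high dose, half effect at low dose —
  comfortably above the 2-fold selection default, because an effect
  planted exactly at the threshold would make selection a coin flip.
- log₂ PM intensity = gene baseline N(9, 1) + probe affinity N(0, 1) +
  dose-scaled effect + N(0, 0.25) noise, exponentiated; MM = PM/4.
  The model is purely multiplicative: the additive cell floor defaults
  to ≈ 1 intensity unit and every gene is expressed, so in the
  noiseless limit summarization recovers planted effects exactly.
  Consequently recovery experiments run with the background stage off —
  there is no additive background in the data to correct. A realistic
  variant (floor ≈ 60 ± 8, 65 % of genes expressed) exercises the full
  chain including background correction and shows the expected mild
  floor attenuation.
- 30 random 20-gene GMT sets plus one planted set holding 10
  differential genes (5× the background overlap expectation), filled
  with non-differential genes so the planted overlap is exact.

What the generator does *not* emulate: hybridization physics, GC and
sequence-specific affinity structure, spatial artifacts, batch effects,
cross-hybridization gradients, and real transcriptome redundancy
(paralogs, overlapping genes). Passing recovery tests therefore
demonstrate the correctness of the algorithms under the planted model,
not performance on real arrays.

For supervised-ranking studies a direct expression-matrix generator
plants informative transcripts at a 2-SD class shift on Gaussian noise
(2000 × 18 at 9 + 9 samples by default), bypassing the array layer.

## Problem sizes and determinism

The shipped tests run the matcher-versus-scanner comparison on 50
randomized fixtures (≈ 60–130 probes against 6–12 genes each, cycling
through four configurations), the full ranking study at 2000 × 18 with
50 resamples plus a label-shuffled control, and the end-to-end
pipeline twice to verify byte-identical artifacts; the whole suite
completes in a few minutes on one CPU. Every stochastic component takes
an explicit seed; stage seeds are derived from the master seed by stage
name so adding or skipping a stage never shifts another stage's
randomness.

## Known limitations

- Ungapped matching only: an ortholog diverged by an indel within the
  probe footprint is invisible at every tier.
- The plurality rule for "intermingling" probes is one consistent
  formalization of a procedure that was historically partly manual;
  alternatives (e.g., requiring unanimity) would be stricter.
- Single-transcript ranking ignores combinations: a pair of transcripts
  predictive only jointly ranks poorly.
- Interaction influences are first-order (mean gradients); symmetric
  dependencies appear in both directions and self-loops are undefined.
- The hypergeometric test treats genes as exchangeable; no correction
  for gene length, expression level or set overlap is attempted.
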