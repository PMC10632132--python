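# Methods

`mcakit` detects mosaic chromosomal alterations (mCAs) — megabase-scale
somatic gains, losses and copy-neutral loss of heterozygosity (CN-LOH)
present in a fraction of blood cells — from phased heterozygous-site
read counts in whole-genome sequencing, and provides the population
statistics built on such call sets. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## Signal model

Blood is modelled as a two-population mixture: a clone at cell fraction
`f` carrying the event, and diploid cells. Counting allele copies at a
heterozygous site gives the expected B-allele-frequency deviation
`b = |E[BAF] − 1/2|` and the expected relative coverage (diploid = 2):

| event  | bdev `b`          | relative coverage |
|--------|-------------------|-------------------|
| CN-LOH | `f / 2`           | `2`               |
| loss   | `f / (2 (2 − f))` | `2 − f`           |
| gain   | `f / (2 (2 + f))` | `2 + f`           |

These invert to the cell-fraction estimators `f = 2b` (CN-LOH),
`4b / (1 + 2b)` (loss) and `4b / (1 − 2b)` (gain, requiring `b < 1/2`).
The inversions are exact compositional identities; the test suite checks
them to 1e-12 and checks the forward formulas against brute-force allele
counting in a 10^6-cell mixture to 1e-9.

## Marker selection

Detection uses heterozygous sites only, filtered before anything else:
population MAF ≥ 1% (sites with no frequency record are removed —
conservative), at least 5 reads supporting *each* allele, position
outside a germline-CNV mask (1-based positions against 0-based half-open
BED intervals: `start < pos ≤ end`), then thinning to at most one marker
per 1,000 bp. Thinning is a greedy left-to-right scan keeping a marker
iff it lies ≥ 1,000 bp from the last kept marker; the keep-first rule is
a deterministic choice (any single representative works), and ties at
exactly 1,000 bp are kept. Both stages are idempotent.

## Detection

At retained marker *i* with alt depth `k_i` of `n_i` reads and phase
sign `s_i` (+1 when the alternate allele sits on haplotype 1), an
imbalance of deviation `b` favouring haplotype 1 makes
`k_i ~ Binomial(n_i, 1/2 + s_i b)`. Total coverage is deliberately not
used at detection time; it enters only at classification.

The hidden Markov model has a balanced null state and, for each `b` on a
grid (default: 30 log-spaced points on [0.001, 0.25]), two states of
opposite polarity. Transitions: null → imbalance with prior `p_event`
(default 1e-4 per marker, split uniformly over imbalance states),
imbalance → null with `p_event`, polarity flip within an event with
`p_switch`. Polarity flips absorb phase-switch errors of the input
haplotypes, so `p_switch` should match the data's switch rate (default
1e-3 per marker; see below). Maximal runs of non-null states on the
Viterbi path become candidate segments, reported at their outermost
supporting markers with no extension into flanking gaps.

Per segment, the deviation is re-estimated: for each grid `b`, a 2-state
polarity Viterbi (flip penalty `log p_switch`) gives the best polarity
path; the winning `b` is then refined by a bounded continuous 1-D
maximum-likelihood step inside its grid bracket with the polarity path
fixed, followed by one polarity re-fit. The continuous step matters: the
grid alone quantises cell fractions to ~10% relative error near the top
of the grid, versus ≲0.005 absolute after refinement. The LOD score is
the base-10 likelihood ratio of the polarity-resolved imbalance model
against Binomial(n, 1/2), summed over the segment's markers (emission
terms only — additive, and zero at `b = 0`).

Transition probabilities are fixed, not trained; a beta-binomial
overdispersion option exists in the generator but detection assumes pure
binomial sampling. Adjacent segments separated by at most a configurable
number of balanced markers and with deviations within a factor of 2 can
be merged and re-scored. chrX is analysed in females only.

### Detectability and the phase-switch rate

Hard-path decoding can track polarity only while the per-marker signal
information (~`2 n b²` nats at depth `n`) exceeds the per-marker cost of
polarity bookkeeping (~`H(p_switch)` nats). At 38x and `b = 0.01` the
signal is ~0.0076 nats/marker: a switch rate of 1e-2 (cost ~0.056
nats/marker) makes such clones undetectable in principle, while at 1e-3
(cost ~0.008) they are recovered with LOD ≈ 60 over 20,000 markers. The
default of 1e-3 per heterozygous marker reflects the ~0.1% switch error
typical of statistical phasing against large reference panels; cohorts
with poorer phasing should expect a correspondingly higher detectable-
deviation floor, and both the generator's `phase_switch_rate` and the
detector's `p_switch` are exposed for that reason.

## Classification and filtering

Relative coverage of a segment is `2 ×` the ratio of the in-segment
10%-trimmed mean marker depth to a genome-wide baseline: the 10%-trimmed
mean depth over markers *outside* any called segment (robust to the
events themselves), with the same trimming on both sides so the skewness
bias of Poisson-like depth cancels in the ratio. If fewer than 100
markers remain outside called segments, all markers are used instead. A
standard error comes from the per-marker depth variance.

Typing uses a z-rule (z = 3): coverage significantly above 2 → gain,
below → loss; consistent with 2 → CN-LOH only when the segment is at
least 1 Mb, else *undetermined* — below ~1 Mb the coverage signal cannot
separate the three classes, and no cell fraction is assigned (such calls
are excluded from CF-stratified statistics, whose formulas are
type-specific). The z/length rule is this package's stand-in for an
unpublished criterion; the categories and the <1 Mb failure mode are the
fixed points.

Final calls must survive five exclusions, applied as a pure conjunction
with strict boundaries exactly as stated: fewer than 2,000 informative
markers; LOD below 5; chrX in a sample of unknown sex; relative coverage
above 2.9; BAF deviation above 0.16 together with relative coverage
above 2.5 (the last two remove putative germline duplications). Calls
with defined cell fraction are stratified at CF ≥ 0.03 (high, boundary
inclusive). Lymphoid/myeloid lineage is a longest-overlap lookup against
a user-supplied (region, event-type) → lineage table; no table ships
with the package.

## Heterozygosity equalisation

Detection power scales with the number of heterozygous sites, so
cross-group rate comparisons first downsample each sample's marker count
through quantile matching: per (group, sex) stratum, the empirical
quantile function of marker counts uses mid-rank plotting positions
`(i − 1/2)/n` with linear interpolation (near-unbiased for modest
strata); a sample's count maps through its own stratum's inverse onto
the target stratum's quantile function, rounded; markers are then
removed uniformly at random genome-wide (not per-chromosome) until the
mapped count is reached. Samples at or below their mapped target are
untouched — markers are only ever removed. Detection is re-run from the
downsampled track; marker QC is not re-applied, since the surviving
subset of an already-filtered track still satisfies every site-level
rule except the thinning spacing, which downsampling can only relax.

## Downstream statistics

*Co-occurrence.* Carriers are assigned to categories — CHIP by mutated
gene, mCAs by (chromosome, arm, copy-number change), one sample possibly
in several — and categories with fewer than 10 carriers are dropped.
Each CHIP × mCA pair gets a 2×2 Wald test on the log odds ratio with
`SE = sqrt(Σ 1/cell)`; if any cell is zero, 0.5 is added to all four
cells first. Bonferroni correction runs over the evaluated pairs at
family α = 0.05.

*Allelic shift.* Among carriers heterozygous for a variant and carrying
an overlapping CN-LOH call of known duplicated haplotype, the count with
the tested allele on the duplicated haplotype is compared to
Binomial(n, 1/2) with an exact two-sided test (minimum-likelihood
convention, which reduces to 2·(1/2)^n at k ∈ {0, n}).

*Matching.* Cases draw up to 10 controls each, matching exactly on
study, sequencing phase and sex, and on age within ±2 years (the
matching covariates are named without a tolerance anywhere authoritative;
±2 is exposed in the API). Controls are never reused; cases are
processed in ascending id order for determinism, drawing uniformly from
the eligible remainder under the given seed. Cases with fewer than 10
eligible controls keep what exists, with a warning.

*Association and prevalence.* Logistic (and linear) association are
maximum-likelihood fits via statsmodels with two-sided Wald p-values;
perfect separation is flagged and no estimate returned. Prevalence
summaries use Wilson 95% intervals.

## Synthetic cohorts

The generator produces what the pipeline consumes: per-sample phased
heterozygous tracks with markers placed uniformly per chromosome
(proportional to length; no LD or recombination structure), depth
Poisson around 38x scaled by the event's relative coverage (optional
gamma-Poisson overdispersion), alt counts binomial at
`1/2 ± b` signed by the phased allele order and the affected haplotype,
Markov phase switches flipping the *reported* allele order downstream of
switch points while read counts follow the true phase, group-specific
heterozygosity (normal or quantile-table), log-uniform cell fractions on
[0.005, 0.5], and CHIP labels drawn to hit a configured CHIP–mCA odds
ratio at a configured marginal prevalence. Males and unknown-sex samples
carry no chrX het track, mirroring female-only chrX analysis. Everything
is reproducible from a seed and refuses to run without one.

What this does **not** emulate: real marker spacing and LD, reference
bias and mapping artifacts, depth waviness (GC), germline CNVs beyond
uniform mask intervals, multi-event karyotypes on one chromosome, or
realistic CHIP gene spectra. Passing tests therefore establish the
statistical machinery — segmentation optimality, estimator calibration,
filter semantics — not robustness to sequencing artifacts.

## Validation problem sizes

The test and acceptance workloads run at desk scale as a deliberate
design point: segmentation optimality is checked against exhaustive
enumeration of *all* hidden-state paths on 200 instances of 4–6 markers
with a 5-point grid (the enumeration is exact; its cost is S^m); cell-
fraction recovery on 200 simulated CN-LOH clones with ~5,000 in-event
markers; low-CF sensitivity at cf = 0.02 over 20,000 markers × 50
replicates; false-positive control on an event-free cohort of 10^4
samples × 10^4 markers; equalisation neutrality on two 60-sample groups
with a shared event spectrum. Cohort-scale quantities from the original
study population (tens of thousands of deeply sequenced genomes) are not
reproducible from synthetic data and are not claimed.

## Known limitations

- Typing relies on marker-depth relative coverage alone; small gains and
  losses at low cell fraction are frequently *undetermined*.
- The bdev grid floor (0.001) bounds the smallest representable
  deviation; clones below cf ≈ 0.2% (CN-LOH) are outside the model.
- The detector assumes binomial allele counts; strong allele-specific
  bias would inflate deviations symmetrically and is not modelled.
- Lineage classification is only as good as the supplied region table.
- One event per chromosome is assumed by the merge logic's bdev
  compatibility check; nested or adjacent distinct events may merge.
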