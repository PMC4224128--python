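# Methods

## The decomposition

Oligotyping operates on same-length reads of one taxonomic family.  Per
alignment column the Shannon entropy is computed in bits over the
five-letter alphabet {A, C, G, T, N} — N is a genuine fifth symbol, so
ambiguous base calls contribute entropy rather than vanishing silently.
Any logarithm base gives the same position ranking; bits are used for
reportability.

The initial partition uses the `n_initial_components` (default 2)
highest-entropy positions, ties broken toward the lower column index so
runs are reproducible.  Refinement then recurses on each group: while a
group's internal maximum column entropy exceeds the stop threshold, up
to five of its highest-entropy internal positions are appended to that
group's component list and the group is re-partitioned.  Refinement only
splits, never merges, so each pass is a proper partition refinement.
The original procedure this formalizes was supervised — an analyst
inspected recomputed entropy and abundance distributions and decided
which groups to split further.  Here that judgement is replaced by a
deterministic rule with one tunable: `entropy_stop_threshold` (default
0.2 bits).  The default is far above the entropy a 0.1%-per-base error
process leaves in a column (≈ 0.012 bits at p = 0.001) and far below the
entropy of a genuine polymorphism at any appreciable minor-allele
frequency (a 2% minor variant gives ≈ 0.14 bits; 5% gives ≈ 0.29), so
single-nucleotide variants separate cleanly at realistic error rates.
Columns where a true minor variant sits below roughly 3% within its
group can fall under the threshold; raising resolution means lowering
the threshold and accepting more error-driven splits for the M filter to
clean up.

The **minimum substantive abundance** filter (M, default 500 reads)
removes an oligotype unless its most abundant unique member sequence
reaches M.  The comparison is inclusive (≥ M survives) and deliberately
applies to the best member, not the group total: a group of thousands of
mutually distinct error derivatives has a large total but no substantive
member, while a genuine variant concentrates its reads on one exact
sequence.  Discarded reads are tallied per family.

Oligotype ids are assigned per family by descending total abundance
(`SynFamily01_oligo_001` …).  Component positions are 0-based internally
and 1-based in every output.  Counts matrices concatenate the per-family
observation matrices over the full sample manifest; percent matrices
normalize each sample column to 100 over retained oligotypes, with
all-zero columns left at zero and flagged.

## Taxonomy

Family classification of reads is a nearest-reference search: the best
ungapped identity of the read against every window of every reference;
ties assign a family only when all tied references agree.  This is a
deliberate, documented stand-in for heavier reference-based classifiers
(GAST-style): synthetic reads are exact windows of the reference
sequences, so sliding-window identity is sufficient and dependency-free;
on real data the margins would differ.  Species-level assignment of
oligotype representatives reports *all* references attaining the maximal
identity (a representative can be identical to several species'
reference fragments) and leaves queries below the 90% identity floor
unassigned.  Raising the floor can only move assignments to unassigned,
never the reverse.  Genome scans use local alignment with unit
match/mismatch/gap costs on both strands; identity is matches over
aligned columns.

## Trajectory statistics

Cross-correlation supports Pearson, Spearman, and Kendall on either the
counts or the percent matrix (both analyses are meaningful; percent
normalization introduces compositional coupling, counts keep sampling
depth in).  Significance for Pearson and Spearman uses the two-sided
Student-t transform t = r·√((n−2)/(1−r²)) with n−2 df; Kendall uses
tau-b with the asymptotic normal approximation.  Bonferroni correction
multiplies by `correction_n`, defaulting to the squared trajectory
count — the convention of correcting an entire correlation matrix, which
is conservative by about a factor of two relative to the number of
unordered pairs.  Pairs involving a zero-variance trajectory are flagged
and excluded from testing.  Missing days are *not* interpolated for
correlation (pairwise complete observations); interpolation is reserved
for the evenly spaced analyses.

Autocorrelation divides the raw lagged sum of the mean-centered series
by its lag-0 value (the biased estimator common in signal processing),
evaluated over lags −21…+21 days.  Periodograms use the standard
discrete-Fourier power spectrum on mean-removed, linearly interpolated
daily series; the peak frequency is reported with its fraction of total
power, with no significance claim attached.  Linear interpolation fills
unsampled days from flanking observations and holds edge values
constant.

Dominance switches are detected on within-group shares: an event fires
when the group's most abundant oligotype changes and the newcomer holds
more than `dominance_threshold` (default 0.5) of the group for at least
`min_persistence` (default 14) consecutive days; the switch day is the
first day of that run.  The threshold-and-persistence rule formalizes a
qualitative phenomenon (transient mixing followed by sustained
replacement); both knobs are configurable.

## Community comparison

Morisita–Horn dissimilarity, 1 − 2Σxᵢyᵢ/((dₓ+d_y)XY) with
dₓ = Σxᵢ²/X², depends only on relative abundances, so genus count
vectors are compared raw, without rarefaction.  Clustering is
agglomerative with average linkage (UPGMA) — the linkage is a package
choice, as is the flat-cluster cut height, which is parameterized rather
than fixed.  Paired-visit selection takes each subject's earliest two
samples with ≥ 600 reads and keeps the pair when the day gap lies in
[30, 359]; within-subject visit distances are compared against the
distribution of all between-subject sample pairs.

## The synthetic community generator

The generator emulates the statistical structure the analysis assumes,
not any mechanistic ecology.  Per variant v and day t the latent
log-abundance is

λ_v(t) = b_v + W_v(t) + s_v·F_g(t) + A_v·σ(k_v(t − t₀)),

with baseline b_v, a private AR(1) walk W_v (innovation sd
`fluctuation_sd`, coefficient `ar1_coeff`; 1.0 gives a pure random walk,
values below 1 a mean-reverting, stationary equilibrium), an optional
shared factor F_g entering with sign ±1 (the correlated /
anti-correlated pairs), and an optional logistic dominance ramp of
amplitude A_v log-units (default 6), rate k_v per day, centred on the
switch day.  Daily abundances are the softmax of λ across variants —
the simplest construction guaranteeing a valid composition.  Reads are
drawn multinomially at a fixed per-sample depth and emitted as exact 5′
windows of the variant sequences with i.i.d. substitution errors
(substitution-only: downstream reads are fixed-length and ungapped, so
indels are out of scope, as are chimeras, PCR bias, and quality scores).
Missing days are flagged in the truth table rather than omitted, so
interpolation is exercisable.  Output — per-sample FASTA, manifest TSV,
truth JSON — is byte-deterministic given the seed.

What this does *not* emulate: real 16S data have correlated
(homopolymer- and position-dependent) error profiles, chimeras, copy-
number variation, compositional effects of unobserved taxa, and
host-driven perturbations with no stated generative model.  Passing the
recovery benchmarks therefore demonstrates the pipeline's correctness
under its own assumptions, not field performance on real sequencing
runs.

### Frozen study conditions (`oligodyn.scenarios`)

* **Recovery**: 3 families × 3 variants differing at 1–3 positions,
  60 days, 5,000 reads/day, 0.1% per-base error, fluctuation sd 0.3
  with ar1 0.9 (stationary, so no variant drifts below the M filter).
  300,000 reads total — large enough that every variant's error-free
  sequence dominates its group by orders of magnitude over any single
  error derivative.
* **Planted pairs**: 10 variants, 60 days, depth 20,000.  The
  correlated pair shares factor 0 (sd 0.3, both +1) with no private
  noise, making their counts exactly proportional up to sampling noise.
  The anti-correlated pair shares factor 1 (sd 0.8, signs ±1) around a
  common baseline of 1.5 log-units, so the two jointly hold a large,
  stable share and trade it — giving a strong negative correlation that
  is not an artifact of compositional closure.  Six background variants
  fluctuate independently (sd 0.4).  All processes use ar1 0.85:
  with pure random walks, any two opposite-trending background variants
  reach spurious r ≈ −0.99 (the classic spurious-regression effect) and
  no planted pair can reliably attain the extreme ranks; a stationary
  equilibrium is also the phenomenon the generator is meant to mimic.
* **Dominance switch**: two variants, old dominant at baseline 3,
  newcomer ramping by amplitude 6 at rate 1/day around day 30 (the
  latents cross exactly at the ramp midpoint), private noise sd 0.15
  with ar1 0.9 so the stable-dominance control actually stays stable.
  Multinomial depth 5,000.
* **Null**: 100 independent i.i.d. standard-normal trajectories of
  60 days.  An i.i.d. null is the condition under which the Student-t
  p-value is exact; autocorrelated nulls (random walks) would break any
  correlation test's nominal calibration and test nothing about the
  Bonferroni machinery.

## Numerical and degenerate-input choices

* Entropy position ties → lower column index; oligotype id ties →
  label, then positions.
* A family with zero polymorphic positions degenerates to a single
  group; with fewer polymorphic positions than requested initial
  components, the polymorphic ones are used with a warning.
* Subsampling is uniform without replacement (standard rarefaction
  practice) with a per-sample substream derived from the global seed
  and a CRC-32 of the sample id, so adding or removing a sample never
  changes another sample's draw.  An optional canonical sort makes the
  retained multiset independent of input read order.
* Trimming takes the 5′ prefix — the convention for single-end reads
  of one amplicon orientation.
* Constant trajectories are flagged (correlation, autocorrelation)
  rather than producing NaN arithmetic downstream.
* Bonferroni caps at 1; p = 0 stays 0.
* Softmax compositions sum to 1 to machine precision; multinomial
  sampling renormalizes defensively.
* Reference-panel groups in the core-taxon report merge references that
  are mutually ≥ 98.5% identical (union-find on best-window identity),
  and each qualifying oligotype contributes its mean abundance to its
  single best-matching group only, so near-duplicate references never
  double-count coverage.

## Known limitations

* The nearest-reference classifier is not GAST; family counts on real
  data would differ at the margins, and no E-value statistics are
  provided.
* The refinement stop threshold replaces human supervision with one
  global constant; heterogeneous families (very different error or
  diversity structure) may want per-family thresholds.
* No compositionality-aware correlation (SparCC-style): plain
  correlation on counts or percents is the analysis reproduced here,
  with its known closure artifacts.
* Periodicity is reported (peak frequency and power fraction), not
  tested for significance.
* The generator's error model is i.i.d. substitution only.
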