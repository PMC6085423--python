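# Methods

## The problem being modelled

The rDNA operon (ITS1–5.8S–ITS2–LSU D1/D2 on the ~1.1–1.4 kb amplicon) is
present in well over a hundred tandem copies per yeast genome.  Concerted
evolution homogenises the copies toward a predominant variant, but the
homogenisation is incomplete: cloning individual repeats and Sanger
sequencing each clone in both directions reveals two distinct classes of
variation among copies — variants fixed in essentially every copy (which
are what distinguish two closely related species) and variants carried by
only ~2–4% of copies, with nothing in between.  `ribovar` implements the
full clone-library analysis of that heterogeneity and a generator that
reproduces its statistical structure with known ground truth.

## The synthetic repeat array

`simulate_repeat_array` draws a uniform-composition canonical sequence per
locus (defaults ITS1=180, 5.8S=160, ITS2=230, LSU=570 bp; total 1140 bp),
derives a second species by planting fixed differences (defaults 5/0/3/5
per locus), and plants low-frequency substitution variants (defaults
8/6/5/22 per locus) into carrier subsets of exactly `round(0.02 * C)` of
the `C = 120` copies.  Carrier counts are exact rather than Bernoulli by
default so that every planted frequency is a sharp ground truth for
recovery tests (a Bernoulli mode exists).  Variant positions are drawn
independently per locus and are disjoint between classes, so loci vary
independently by construction.  `simulate_sanger_reference` majority-calls
the copies into the strain's "reference" sequence and records sites whose
minority fraction reaches a detection floor (default 10%) as secondary
peaks — with 2% carriers nothing reaches the floor, which is precisely why
direct Sanger sequencing hides the minority variants.
`simulate_clone_reads` samples `n = 85` clones uniformly **with
replacement** and reads each twice (forward and reverse) with independent
per-base substitution errors (default rate 0).

What the generator does *not* emulate: the mechanism of concerted
evolution (only its outcome, the frequency structure), chromatogram
signal, read-quality gradients and end-trimming, PCR chimeras, indel
variation (available behind a flag, off by default because the observed
variation is substitutional), and realistic ITS base composition
(configurable).  Tests passing on this generator therefore demonstrate the
pipeline's correctness and the qualitative mechanisms, not the exact
numbers any particular real library would give.

## Consensus building

Forward and reverse reads are globally aligned and merged column by
column.  Disagreements are resolved by policy: `iupac` (ambiguity code of
the two bases), `fwd_wins`, or `reference_biased` — keep whichever base
matches the reference, falling back to the ambiguity code.  The
reference-biased policy models the common practice of cleaning a consensus
against the type strain; it is the mechanism by which consensus building
pulls clones toward the reference and hides variation.  Columns where one
read is gapped take the other read's base (an indel disagreement is not an
ambiguity).  The "original" sequence of a clone is its forward read by
default (configurable to reverse); which strand a real study's
non-consensus sequences were is generally not recoverable, so both are
exposed.

## Alignment

`align_to_reference` is a global Gotoh alignment with affine gaps
(defaults: match +1, mismatch −1, gap open −4, gap extend −1; a gap of
length k costs open + (k−1)·extend).  Ties are broken deterministically —
match/mismatch over gap-in-query over gap-in-reference — so repeated runs
give identical alignments.  The DP is banded for speed and escalates the
band until the banded optimum provably beats an upper bound on any
out-of-band path, so results are exact, not heuristic.  All downstream
coordinates are 0-based half-open positions on the reference; query
insertions are assigned to the locus of the left flanking reference
position and are dropped when sequences are projected into the reference
frame (pairwise deletion excludes them from distances regardless).

## Distances

Substitution distances are computed under pairwise deletion: any site with
a gap, N or IUPAC ambiguity in either member of a pair is excluded for
that pair only.  Three estimators: the raw p-distance; the Tamura–Nei
(1993) closed form, which separates purine (A↔G) and pyrimidine (C↔T)
transitions from transversions and allows unequal base frequencies; and a
composite TN93 (`tn93_mcl`) in which base frequencies are estimated once
from the counts pooled over all compared pairs while each pair keeps its
own substitution proportions — the shared-parameter reading of
composite-likelihood distance estimation, used for all figure-style
summaries.  With equal frequencies and equal rates TN93 collapses to
−(3/4)·ln(1 − 4p/3), which is verified to 1e−9 in the tests.  Pairs that
push a logarithm argument to zero or below are flagged saturated (NaN),
counted, and excluded from means with a warning — never silently dropped.
Distances are fractions internally and percentages in reports.

## SNP spectrum

Every reference-anchored site where clones vary or the two type strains
differ yields a record.  The variant allele is the most frequent clone
allele that differs from at least one type-strain allele; its category is
`vs_A_only`, `vs_B_only` or `vs_both`, and its frequency is the fraction
of called clones carrying it.  This single rule makes a fixed difference
score 1.0 (present in all clones — the high class) and a minority repeat
variant score its carrier fraction (the 2–4% low class).  Classes: high ≥
0.5, low ≤ 0.1, intermediate between — the cuts are configurable, and
intermediate records are reported rather than suppressed, because their
absence in data is a finding, not a rule.  Multi-allelic sites are
decomposed into one record per non-reference allele with the most frequent
flagged primary.

## Species thresholds and diversity overestimation

Published species-identification distance limits: 1% for LSU D1/D2, 1.59%
for ITS loci (5.8S, having no dedicated published limit, inherits the ITS
value), 0.69% for the whole-ITS barcode.  `threshold_exceedance` reports
the fraction of pairwise clone distances strictly above the limit;
`attribute_read` assigns single reads to type strain A, B, both (distance
within the limit of both) or neither (a "novel" spurious taxon); a
nearest-type-strain mode exists since real attribution procedures vary.
The alpha-diversity overestimate is formalised as the number of
single-linkage clusters of reads at the threshold minus one: all reads
derive from one strain, so every extra OTU is spurious.

## Locus independence

For each clone, the distance to the reference is computed per locus
(consensus and original separately); the six locus pairs are correlated
across clones with Pearson's r and a two-sided t-test p-value (n−2 df).
Raw p-values are reported; a Bonferroni column is emitted alongside,
clearly labelled, never substituted.  Clones with an incomparable locus
are dropped listwise.  Constant (zero-variance) loci raise a
degenerate-vector error at the operation level; the pipeline reports NaN
for such pairs with a warning, since small libraries routinely have an
invariant locus.

## Trees

NJ (Saitou–Nei) and UPGMA are implemented directly so their behaviour is
fully specified: agglomeration ties break on the lowest-index pair,
negative NJ branch lengths are clamped to zero and logged, UPGMA output is
ultrametric by construction.  Both recover generating additive /
ultrametric matrices exactly, which the tests assert against random trees
and against scikit-bio's NJ as an independent implementation.  Bootstrap
support resamples alignment columns with replacement, recomputes the
distance matrix and tree per replicate, and reports the percentage of
replicates containing each internal split of the point tree (clades for
rooted UPGMA, bipartitions for unrooted NJ).  Defaults: 1000 replicates
for NJ, 100 for UPGMA, both configurable; replicates that lose all
comparable sites for some pair are skipped and logged.

## Statistical behaviour of the study conditions

Two consequences of sampling 85 clones with replacement from 120 copies
deserve emphasis, because they bound what the idealised expectations can
claim:

* **Duplicate clones couple the loci.**  About a quarter of clone pairs
  share a source copy; duplicated clones have identical per-locus distance
  profiles, so the effective sample size of the locus correlation is below
  the nominal n = 85.  The correlation magnitudes stay small (95th
  percentile of |r| ≈ 0.27 across 500 seeded runs), but the t-based
  p-values are anti-conservative: their distribution under the null is
  measurably non-uniform (KS D ≈ 0.15 over 500 runs), and remains mildly
  non-uniform even without duplicates because the sparse, discrete
  distance data are far from normal.  Conclusions about locus independence
  should therefore rest on the magnitude of r, not on p-value calibration.
* **Observed variant frequencies have a resampling tail.**  A 2-carrier
  variant is expected in ~1.4 of 85 clones, but repeated draws of the same
  carrier copy occasionally push the observed count to 9+ (≈ 3e−5 per
  variant, ≈ 0.6 expected events per 500 default simulations), which
  crosses the 10% low/intermediate boundary.  The spectrum is bimodal in
  expectation, almost surely — not surely.

## Masking experiments and read errors

With error-free reads, forward and reverse strands agree everywhere, every
consensus policy returns the read itself, and the consensus-vs-original
comparison is an equality.  The masking *mechanism* — reference-biased
resolution of read disagreements — only engages when reads disagree, so
the dedicated masking experiment (driver 02, and the strict-inequality
test) uses a per-base read error rate of 0.003, a typical post-trim Sanger
figure.  Under it, the mean original-vs-reference distance exceeds the
consensus-vs-reference distance in every locus, and single original reads
spill past the species thresholds while consensus sequences stay inside —
the metagenomics single-read scenario.

## Problem sizes and determinism

The test suite and acceptance script run the oracle checks on 1000 random
pairs, tree recovery on 20+ random 4–8 taxon matrices, variant recovery on
500 seeded default simulations, masking on 100, and independence on
200–500; these sizes give stable statistics while keeping a full run in
minutes on one core.  Every source of randomness flows from an explicit
seed: one generator stream per simulated run, seeded bootstrap, and
seed-derived replicate streams, so any reported number is reproducible
bit for bit.
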