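# Methods notes

This note records the modelling assumptions, parameter choices and known
limitations behind `nbsomatic`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Copy-number calling

**Scale and coordinates.** Absolute copy units (2.0 = diploid), 1-based
inclusive segment coordinates (SEG convention).  Loaders can convert
BED-style half-open input (`zero_based=True`) and fill internal gaps at the
profile's length-weighted median so grids are gap-free.

**Recentering.** The presumed-diploid baseline is the *lowest* copy level
among non-LOH segments, because in an off-center profile the presumed
haploid and triploid levels obligately carry LOH.  Two numerical guards make
this automatic rather than a manual-inspection step: (1) segment levels are
clustered greedily along the sorted copy axis (gap threshold 0.25 copies),
so measurement noise around one biological level forms a single cluster
whose length-weighted center is used; (2) a cluster must carry ≥ 5% of the
non-LOH genomic length to anchor the baseline, so isolated noisy segments
cannot.  Offsets below half the cluster gap are treated as zero, which makes
recentering idempotent.  The applied offset is returned for audit.

**Grid and thresholds.** Copy is sampled every 250 kb; grids are anchored at
the arm's telomeric terminus and step inward, so the terminal base is always
sampled.  Gain: terminal-window median ≥ 2.3 with the control (opposing) arm
median ≥ 0.3 below the window median.  Loss: window median ≤ sample median −
0.3 with the control arm ≥ 0.3 above.  The sample median is taken over the
pooled 250 kb grid of all autosomal arms (grid pooling rather than
segment-length weighting; on gap-free grids the two agree to within one grid
cell).  The control-arm median is likewise computed on the grid.

**Acrocentric arms.** The q arms of 13, 14, 15, 21 and 22 use a 20 Mb
terminal window by default (configurable 15–25 Mb): their centromere-side
copy estimates are unreliable in practice, and a shorter window is the
conservative choice within the stated range.

**Relative calls in hyperdiploid samples.** The loss rule is anchored to the
*sample median*.  In a sample whose median ploidy is 3, a diploid 17p next
to a gained 17q satisfies the loss criteria — a loss *relative to ploidy*.
This is a faithful consequence of the thresholds, not an error; round-trip
tests against simulated truth treat such relative calls separately.

**Whole-chromosome classification.** Per-arm fraction of grid points at copy
≥ 2.25; an arm is gained at ≥ 80%, a chromosome when both arms are, and the
9+ WC class requires ≥ 9 gained chromosomes.  Focal amplification (MYCN)
requires a segment overlapping the locus with log2(copy/2) strictly above
2.0, i.e. > 8 copies.

## Structural-variant integration

Breakpoint-to-boundary matching uses a 5 kb window, inclusive; chain hops on
an intervening chromosome up to 15 Mb, inclusive.  Linkage is transitive
(path connectivity in a per-sample graph whose nodes are alterations and SV
breakpoints): the worked case is a t(11;17) joining the end of an 11q13.3
gain to the beginning of a 17q gain, which makes all three events one
non-independent set.  SNVs and indels never enter the graph and are
independent of everything.  t(11;17) itself is a translocation joining 17q
at ≥ 30 Mb to 11q within [60, 80] Mb (GRCh37), bounds inclusive, breakpoint
order irrelevant.

## Signature refitting

NNLS (`scipy.optimize.nnls`) over the full signature set, then greedy
backward elimination: while some non-forced signature can be removed at a
reconstruction-cosine cost < 0.01, remove the cheapest.  Forced signatures
(the pipeline forces the ubiquitous/flat ones, SBS1/3/5, when present in the
matrix) are never eliminated — flat definitions are partially in the span of
other signatures, so a sparsity rule alone would silently absorb them.
Exposures are rescaled to sum to the sample's SNV count; the reconstruction
cosine is unaffected by the rescale.

**Detection limit of the sparsifier.** Removing a component with relative
share w/n and residual fraction (1 − R²) against the remaining signatures
costs roughly (w/n)²(1 − R²)/2 in cosine.  At tolerance t = 0.01 this means
components below a relative share of about √(2t) ≈ 14% (≈ 140 mutations of
1000) can be eliminated *by design*.  Recovery guarantees therefore apply to
components above that limit; smaller activities may be reported as zero.
This mirrors the behaviour of single-sample refitting tools with sparsity
rules.

**Per-mutation attribution.** P(i|m) = s_i P[c,i] / Σ_k s_k P[c,k] over
detected signatures (s_k > 0).  A context producible by no detected
signature raises an explicit error rather than returning NaN.  Driver
attribution is limited to samples with reconstruction cosine ≥ 0.9, and
mutations whose best signature exceeds 50% probability are flagged.

**Bundled signature set.** `synthetic_signatures.py` builds a deterministic
96 × 5 set of *synthetic stand-ins* (SBS1/3/5/18/31-like).  The two
background signatures carry a few distinctive anchor peaks (pairwise cosine
≈ 0.27): fully flat definitions would be mutually unresolvable by any
refitting method and would make exposure recovery ill-posed, which is a
property of the definitions, not of the fitting code.  Real COSMIC v3
matrices load via `SignatureMatrix.from_tsv` and are used identically.

## Timing and clonality

E[VAF] = mρ/(Tρ + N(1−ρ)) uses the exact two-population mixture denominator
rather than literal proportional scaling; the two agree at ρ = 1, where all
the headline numbers live (0.33, 0.67, cutoff 0.5).  Purity is consumed as
an input column (ground truth in simulations); it is not re-estimated.

The timing model assumes equal per-allele mutation rates before and after a
single-copy gain: pre-gain mutations land on the duplicated chromosome with
probability 1/2 (multiplicity 2 of 3), post-gain mutations always have
multiplicity 1.  With pre-gain fraction f the expected single-allele
fraction is 1 − f/2, inverted as f̂ = 2(1 − observed fraction), clipped to
[0, 1] (observed fractions below 0.5 violate the model and clip to 1 with a
warning).  gain_early uses a strict > 0.75 threshold.  Only 3-copy regions
are timed — the most frequent gain level and the one with an unambiguous
allelic configuration; eligibility needs purity ≥ 0.70 and ≥ 20 such
mutations.

Clonality: a mutation is clonal when its VAF exceeds 0.8 × the expected
clonal VAF for its copy state (mutated copies = max(⌊T/2⌋, 1)).  At the
defaults this reproduces the > 0.4 rule for 2- and 4-copy loci and accepts
0.32 at 3 copies; the 0.8 factor is configurable because borderline relapse
VAFs (e.g. 0.22 at 3 copies) sit below it.

## Cohort statistics

Fisher 2×2 tests via `scipy.stats.fisher_exact`; the 2×3 age-group
prevalence test is an exact Fisher–Freeman–Halton enumeration over all
tables with the observed margins (log-gamma arithmetic, relative tie
tolerance 1e−7, as in R's `fisher.test`).  Wilcoxon rank-sum comparisons use
the large-sample z approximation (`scipy.stats.ranksums`), which returns
exactly p = 1 for identical samples; exact small-sample enumeration is not
reproduced.  ECDFs via `statsmodels`.  Bonferroni: α/n (0.05/17 =
2.94 × 10⁻³).  Independence filtering removes a sample from a pair's 2×2
table only when the pair co-occurs *and* is SV-linked in that sample, so
filtering can only reduce the co-occurrence cell.  Relapse samples are
excluded from age and co-occurrence analyses by default; a `stage4_only`
flag supports sensitivity reruns.  Degenerate tables (empty margin) report
p = 1 with a flag.  Raw pair p-values are reported with the pair count;
no cross-pair correction is applied.

Age groups: A < 1.5 y, 1.5 ≤ B ≤ 5 y, C > 5 y.  The placement of exactly
5.0 years is ambiguous between published phrasings ("5 or more" vs "> 5");
it is assigned to B here and controlled by a module constant.

## Synthetic cohort generator

The generator's defaults are the study conditions for the acceptance runs:

| parameter | default | rationale |
|---|---|---|
| coverage depth | 60 reads | deep Illumina WGS |
| purity | U(0.4, 1.0) | roughly half of samples pass the 0.70 timing filter, matching the observed eligible fraction |
| age-group weights | 0.30 / 0.47 / 0.23 | observed diagnosis-age group sizes |
| fraction pre-gain | 0.5 | equal molecular time before and after gains (the timing benchmark condition) |
| copy noise | Gaussian, sd 0.05/segment | no published noise model for segment means; small relative to the 0.3-copy decision margins |
| MYCN amp prevalence | 0.40 / 0.35 / 0.03 (A/B/C) | enriched in younger groups |
| ATRX prevalence | 0.00 / 0.07 / 0.45 | enriched in the oldest group |
| 17q gain / 11q del / 1p del | 0.55 / 0.15–0.35 / 0.25 | common segmental alterations, 11q del age-graded |
| 9+ WC gain | 0.65 / 0.50 / 0.35 | hyperdiploidy commoner in younger children; gains 9–14 chromosomes |
| t(11;17) | 0.08 | forces co-occurring 11q13.3 + 17q gains joined by the hotspot SV |
| signature activities | SBS1 U(30,120), SBS3 U(0,200), SBS5 U(80,300), SBS18 U(100,700) | SNV burdens of a few hundred to ~1300 with a dominant ROS-like component |

Whole-chromosome gains draw from autosomes other than 1, 2, 11 and 17 so
targeted events never contradict them.  A quarter of samples receive a
global centering offset from {−0.2, 0.3, 0.5, 0.7, 1.0} to exercise
recentering.  When an 11q deletion and a 17q gain co-occur, half the time a
single translocation joins their termini (an unbalanced-translocation
origin), giving the independence filter real work.  One global seed spawns
per-sample RNG substreams, so enlarging a cohort preserves earlier samples
byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: positional mutation-rate variation (positions are
uniform), indels and germline variation, subclonal structure beyond the
single pre/post-gain split, multiplicities above 1 outside 3-copy regions,
read-level artefacts, segmentation errors from real CNV callers (segments
are exact event boundaries plus level noise), and purity estimation (truth
purity is passed through).  Recovery rates measured here are therefore
upper bounds on real-data performance.

## Problem sizes used in the checks

Acceptance-scale runs use a 60-sample cohort (~45k SNVs) for the end-to-end
check, 200 simulated arms for caller sensitivity/specificity, 20 × 10⁶
draws for the attribution Monte-Carlo, n = 1000 multinomial spectra for
refit recovery, and ~1000 null alteration pairs (150 samples × 46
alterations) for type-I calibration — sizes at which every stochastic bound
tested has comfortable statistical margin.

## Known limitations

* The segmental caller reports ploidy-relative losses in hyperdiploid
  samples (see above); interpreting them requires the 9+ WC flag alongside.
* Exposure estimates for signatures below the sparsifier's detection limit
  are reported as zero rather than small numbers.
* The Freeman–Halton enumeration is exponential in the number of groups;
  it is intended for 2 × 3 tables at cohort sizes (≤ a few hundred samples
  per group), where it enumerates tens of thousands of tables in
  milliseconds.
* Arm-call boundaries feed the linkage graph as the boundaries of segments
  deviating ≥ 0.25 copies from diploid inside the called window; callers
  with very ragged segmentation may need the deviation threshold adjusted.
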