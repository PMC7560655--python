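# nbsomatic

Somatic-genomics analyses for neuroblastoma-style whole-genome tumor
cohorts: rule-based arm-level copy-number calling, whole-chromosome-gain
classification, mutational-signature refitting with per-mutation driver
attribution, purity-adjusted VAF modelling for evolutionary timing of copy
gains, SV-aware mutual-exclusivity testing and age-group association
statistics — together with a synthetic-cohort generator that produces all
of the inputs with complete ground truth, so every stage is testable
without access to controlled patient data.

Intended users: cancer-genomics analysts who already have segment tables,
SNV catalogs and SV breakpoints from standard callers and want the
*downstream* cohort analyses, and methods developers who need a
ground-truthed sandbox for them.

## The models

**Segmental arm calls.** Copy levels are absolute (2.0 = diploid).  After
recentering a profile so its presumed-diploid level (the lowest non-LOH copy
level) sits at 2.0, the copy level is sampled every 250 kb over the terminal
30 Mb of each autosomal arm (whole arm if shorter, 20 Mb for acrocentric q
arms).  An arm is **gained** when the window median is ≥ 2.3 and the
opposing (control) arm's median is at least 0.3 copies lower; **lost** when
the window median is at least 0.3 below the sample median and the control
arm at least 0.3 above.  The control criterion excludes whole-chromosome
events, which are classified separately: an arm counts as gained when ≥ 80%
of its grid is at copy ≥ 2.25, a chromosome when both arms are, and a sample
is *9+ WC gain* at nine or more gained chromosomes.  The 11q13.3 hotspot
gain uses the fixed window chr11:68.5–69.5 Mb (GRCh37) with the terminal
30 Mb of 11q as control, and MYCN amplification requires a focal segment
with log2(copy/2) > 2 (≈ 8 copies).

**Signature refitting and attribution.** SNVs are classified into the 96
trinucleotide classes (pyrimidine strand).  Known signature definitions
P ∈ R^(96×K) (columns sum to 1) are refit to a sample's spectrum by
non-negative least squares with greedy backward elimination (a non-forced
signature is dropped when removal costs < 0.01 reconstruction cosine);
exposures s_k are rescaled to sum to the sample's SNV count.  The
probability that a particular mutation at context c arose from signature i
is

    P(i | m) = s_i · P[c, i] / Σ_k s_k · P[c, k]

over the signatures detected in the sample.  Driver attribution is
restricted to samples with reconstruction cosine ≥ 0.9.

**Timing of copy gains.** For a mutation on m of T tumor copies at purity ρ
(normal copies N = 2),

    E[VAF] = m·ρ / (T·ρ + N·(1 − ρ))

so at ρ = 1 a 3-copy region gives 0.33 (m = 1) and 0.67 (m = 2); their
midpoint (0.5 at full purity) separates single- from multi-allele
mutations.  Under equal per-allele mutation rates, a fraction f of 3-copy
mutations predating the gain yields an expected single-allele fraction of
1 − f/2: 50% immediately after the duplication, 75% at equal molecular time
before and after.  A sample whose observed fraction exceeds 75% acquired its
gain early; eligibility requires purity ≥ 0.70 and ≥ 20 mutations in 3-copy
regions.

**Mutual exclusivity and age associations.** Alterations recurrent in ≥ 5
samples enter a samples × alterations matrix; each pair is tested with a
two-sided Fisher's exact test after *independence filtering*: samples in
which the pair co-occurs but is joined by SVs — directly (breakpoints within
5 kb of both alterations' boundaries) or through chains with ≤ 15 Mb hops —
are removed from that pair's table.  Age analyses use groups A (< 1.5 y),
B (1.5–5 y) and C (> 5 y): exact 2×3 Fisher–Freeman–Halton prevalence tests,
two-sided Wilcoxon rank-sum age/burden comparisons, ECDFs, and Bonferroni
control (0.05/17 = 2.94 × 10⁻³ for a 17-alteration family).

## Worked example

```python
import nbsomatic as nb
from nbsomatic.pipeline import run_cohort_analysis
from nbsomatic.association_stats import age_group_prevalence_test

cohort = nb.simulate_cohort(nb.CohortConfig(n_samples=40, seed=11))
result = run_cohort_analysis(
    cohort.profiles, cohort.snvs, cohort.svs, cohort.metadata, cohort.genome,
    signatures=nb.synthetic_signature_matrix(), gene_events=cohort.gene_events,
)

print("alterations kept (>=5 samples):", result.matrix.alterations)
timing = result.timing[result.timing.eligible]
print(f"eligible for timing: {len(timing)}/{len(result.timing)} samples")
print(f"mean single-allele fraction: {timing.fraction_single_allele.mean():.3f}")
print(f"mean estimated pre-gain fraction: {timing.pre_gain_fraction.mean():.3f}")
p, summary = age_group_prevalence_test(result.matrix, "MYCN_amp")
print(f"MYCN prevalence by age group (A/B/C): "
      f"{summary.prevalence.round(2).tolist()}, Fisher p = {p:.2e}")
```

prints

```
alterations kept (>=5 samples): ['MYCN_amp', 'del_11q', 'del_17p', 'del_1p', 'gain_17q', 'wc_9plus']
eligible for timing: 11/40 samples
mean single-allele fraction: 0.735
mean estimated pre-gain fraction: 0.529
MYCN prevalence by age group (A/B/C): [0.45, 0.26, 0.12], Fisher p = 2.93e-01
```

The 40-sample cohort was generated with a true pre-gain mutation fraction
of 0.5 (equal molecular time before and after each gain), and the pipeline
recovers it: the mean single-allele fraction sits near the theoretical 0.75
and inverting the timing model gives 0.53 ± sampling noise.  Eleven samples
pass both eligibility filters (purity ≥ 0.70, ≥ 20 three-copy mutations).
MYCN amplification is configured to be enriched in the younger age groups;
at n = 40 the prevalence gradient (45% → 26% → 12%) is visible but the exact
test is not yet significant — power arrives with larger cohorts.

The same pipeline is scriptable from the shell:

```sh
nbsomatic simulate --out cohort/ --seed 11 --n-samples 40
nbsomatic call-arms --segments cohort/segments.tsv --out arm_calls.tsv
nbsomatic analyze  --dir cohort/ --out analysis/
```

## Layout

- `src/nbsomatic/genome.py` — GRCh37 and toy autosome arm tables
- `src/nbsomatic/copy_number.py` — recentering, grid sampling, arm/WC/focal callers
- `src/nbsomatic/sv_integration.py` — SV–CNA matching, t(11;17), linkage graph
- `src/nbsomatic/signatures.py` — 96-class contexts, refitting, attribution
- `src/nbsomatic/synthetic_signatures.py` — bundled synthetic signature set
- `src/nbsomatic/timing_clonality.py` — VAF model, gain timing, clonality
- `src/nbsomatic/association_stats.py` — Fisher/Wilcoxon/ECDF/Bonferroni statistics
- `src/nbsomatic/synthetic_cohort.py` — ground-truthed cohort generator
- `src/nbsomatic/pipeline.py`, `cli.py`, `io.py` — orchestration and I/O

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
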