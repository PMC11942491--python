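# strtier

Two-tier characterization of short tandem repeat (STR) expansions for
neurogenetic diagnostics: read-level repeat-motif decomposition, allele
calling with somatic mosaicism, locus-aware clinical classification, CpG
methylation association, a short-read/long-read triage rule, and cohort
reporting — exercised end to end on synthetic reads.

## The problem

Over 50 neurological disorders (Huntington disease, Friedreich ataxia,
CANVAS, SCA27B, fragile X, ...) are caused by expansions of short tandem
repeats. Clinical interpretation needs more than a length: at loci such as
*RFC1* the pathogenic unit (AAGGG) differs from the benign one (AAAAG); at
*FGF14*, GAAGGA-dominant expansions are likely non-pathogenic; at *FMR1*,
pathogenicity of a full mutation is corroborated by CpG 5mC methylation and
modulated by AGG/TGG interruptions; and recessive loci (*FXN*, *RFC1*)
require exact biallelic lengths. Short 150 bp reads cannot size a repeat
tract beyond ~135–140 bp, so diagnostic workflows route such cases from
short-read WGS to confirmatory long-read sequencing.

`strtier` implements that workflow as a tested library:

* **Decomposition.** A repeat-region sequence is segmented into maximal runs
  of exactly matching catalog motifs plus interruption stretches by a dynamic
  program over (position, last motif) minimizing
  `interruption_penalty · #interruption_bases + switch_penalty · #motif_switches`
  (defaults 1 and 2), with deterministic tie-breaks. Output reads like
  `CTA×12 | CTG×84` or `AAGGG×10 | [GTA] | AAGGG×5`.
* **Allele calling.** Reads are anchored by 30 bp locus flanks
  (mismatch-tolerant Hamming scan); spanning reads give exact unit counts
  (region length / unit length), one-sided reads give lower bounds. Counts
  are clustered into 1–2 alleles by a largest-gap rule
  (`gap > max(5, 0.2·median)`), and each allele is reported as a mosaic
  count **range** with a median point estimate, motif composition, and
  methylation summary.
* **Classification.** A bundled 29-locus catalog encodes normal / mutable
  normal / intermediate / premutation / reduced-penetrance ranges and
  full-penetrance thresholds, normalized into a gap-free partition of the
  count axis. Length categories are refined by a composition gate
  (pathogenic-unit fraction ≥ 0.5 at motif-ambiguous loci) and interruption
  rules (e.g. *ATXN1* CAT-interrupted ranges); case significance follows
  dominant / recessive / X-linked logic, with methylation corroboration for
  male *FMR1* full mutations.
* **Triage.** From 150 bp reads alone, repeats are sized exactly when they
  fit between unique flank anchors inside one read, otherwise predicted
  statistically; rules R1–R5 (tract ≥ 135 bp, statistical prediction at a
  high-threshold locus, unresolvable composition, possible biallelic
  recessive expansion, methylation-dependent locus) decide whether long-read
  follow-up is required.
* **Synthetic data.** A seeded generator produces long reads (lognormal
  lengths, truncation inside the repeat, substitution/indel errors, per-read
  length mosaicism, crisp per-CpG methylation states) and tiled short reads,
  plus per-read truth tables and cohort disposition records.

## Worked example

```python
from strtier import (
    SyntheticAlleleSpec, SyntheticSampleSpec, simulate_reads,
    load_bundled_catalog, genotype_sample, classify_case,
)

catalog = load_bundled_catalog()
spec = SyntheticSampleSpec(
    locus_id="FXN",
    alleles=(SyntheticAlleleSpec(segments=(("GAA", 100),)),
             SyntheticAlleleSpec(segments=(("GAA", 700),))),
    coverage=20, substitution_rate=0.01, seed=42,
)
reads, truth = simulate_reads(spec, catalog)
gt, decomps, regions = genotype_sample([r.as_input() for r in reads],
                                       catalog["FXN"])
for a in gt.alleles:
    print(a.unit_count_min, a.point_estimate, a.unit_count_max, a.composition)
res = classify_case(gt, catalog["FXN"])
print(res.case_significance, [c.category.value for c in res.per_allele])
```

prints

```
100 100 100 {'GAA': 1.0}
700 700 700 {'GAA': 1.0}
pathogenic ['full_penetrance', 'full_penetrance']
```

— a biallelic GAA expansion at a recessive locus: both alleles recovered at
their simulated lengths (pure GAA composition), each beyond the 66-unit
full-penetrance threshold, so the case is pathogenic. With per-read jitter
(e.g. 6 and 120 units) the same pipeline reports mosaic ranges such as
`94–106` and `583–813`.

The `strtier` CLI exposes the same stages (`simulate`, `decompose`,
`genotype`, `classify`, `cohort-summary`); see `strtier --help`.

## Analysis scripts

`analysis/01...06` run the pipeline over a panel of representative synthetic
cases (biallelic *FXN*, mosaic and GAAGGA-dominant *FGF14*, biallelic
AAGGG *RFC1*, *FMR1* premutation and mosaic males, bipartite CTA/CTG
*ATXN8OS*), writing read sets under `scratch/sim/` and result tables under
`results/`: the sample manifest, worked per-read decompositions, genotypes
with classifications, the methylation–interruption association, short-read
triage decisions, and the cohort summary tables.

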