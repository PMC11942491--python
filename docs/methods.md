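# Methods

This note documents the models, conventions, and numerical choices behind
`strtier`, and what its synthetic benchmarks do and do not demonstrate.

## Locus catalog

The bundled catalog (`src/strtier/data/catalog.json`) encodes 29 clinically
reported STR loci with hg38 coordinates (0-based, half-open; 1-based inputs
are converted at the loader boundary only), the repeat-unit vocabulary
(reference motif, additional benign motifs, pathogenic motifs, motifs of
uncertain significance, interruption motifs — pairwise disjoint, with the
reference motif a member of exactly one of benign/pathogenic), the annotated
count ranges, and inheritance. Blank annotation cells are recorded as absent
rather than invented (*RFC1*, *FGF14*, *BEAN1* have no annotated normal
range). The flanks are fixed synthetic 30 bp anchors, deterministically
generated per locus and guaranteed free of that locus's motifs: the pipeline
is exercised entirely on synthetic reads, and real hg38 flanks can be
substituted via a custom catalog file.

`category_bounds` normalizes each locus's ranges into a total, gap-free,
non-overlapping partition of the count axis [0, ∞):

* unannotated gaps become `intermediate_uncertain` (including counts below
  an annotated normal floor, e.g. *FXN* counts 0–4);
* overlapping printed ranges are resolved by most-severe-category precedence
  (*C9ORF72*'s intermediate 25–60 vs reduced-penetrance 24–60; *TCF4* and
  *ZFHX3* normal/expanded overlaps at a single count);
* a missing full-penetrance threshold caps severity at reduced penetrance
  (*ATXN8OS*, whose reduced-penetrance range is open-ended at 54).

Two loci are intrinsically non-monotone in count severity because their
reduced-penetrance range stops short of the full-penetrance threshold,
leaving an uncertain gap between: *RFC1* (11–200 vs 400) and *DIP2B*
(139–206 vs 250). The property tests assert severity monotonicity above the
benign region for every other locus and this exact shape for these two.
*PABPN1* carries a homozygosity rule (11-unit alleles pathogenic only in two
copies) applied at case level. *ATXN1*'s CAT-interrupted ranges (normal
36–44, pathogenic ≥ 46) override the length category when interruption
motifs are present in an allele's composition.

## Motif decomposition

Decomposition is an exact dynamic program over states (position, last
motif). A motif unit is consumed only on an exact match; every other base is
an interruption base. The objective is

    interruption_penalty · (#interruption bases) + switch_penalty · (#motif changes)

with defaults 1 per base and 2 per change. The switch penalty being larger
than one interruption base but smaller than one motif unit keeps spurious
alternation between overlapping motifs (GAA/GGA) suppressed while leaving
genuine composite alleles detectable; both penalties are configurable. Ties
are broken deterministically — continue the current motif, else the
lexicographically smallest motif, else an interruption — so output is
reproducible and left-anchored. Motifs are matched in catalog phase; no
rotational matching. Exact-match consumption is deliberate: a substituted
base inside a unit surfaces as a short interruption instead of a fuzzy
match, keeping composition fractions and interruption statistics crisp. The
DP is validated against exhaustive enumeration of all segmentations on
random sequences (length ≤ 25, motif sets ≤ 2).

## Allele sizing and calling

Flanks are located by a vectorized full Hamming scan over every read offset
(leftmost best hit; at most `max_flank_mismatch_frac` = 0.1 mismatches by
default). Reads with neither flank are retained only if they contain a
tandem run (≥ 3 units) of a locus motif; such reads, and one-sided reads,
carry lower bounds.

A spanning read's unit count is `round(region_length / unit_length)` — the
*total expansion length* convention, counting interruption bases and
noncanonical units toward the allele size. This matches how composite
expansions are reported clinically (total length, with composition given
separately) and makes the count robust to substitution errors, which change
individual units but not the tract length. The decomposition's exact-match
unit sums are used for composition fractions, pathogenic-run lengths, and
interruption grouping.

Spanning counts are clustered into two alleles iff the largest adjacent gap
exceeds `max(min_gap_units=5, min_gap_frac=0.2 · median)` at ploidy 2. A gap
heuristic (rather than a mixture model) is appropriate because spanning
counts are few and real biallelic calls are well separated; tests verify the
gap split coincides with the exhaustive minimum within-cluster-variance
split on bimodal count sets. The point estimate is the cluster median
(half-up). Bounded reads are assigned to the largest compatible allele
without inflating its spanning-derived range; with no spanning evidence at
all, the bounds themselves are clustered and reported as "≥" alleles whose
point estimate is the **maximum** lower bound. A lone cluster at ploidy 2
raises a homozygous-or-dropout flag; case classification treats it as
homozygous and records the dropout caveat in the rationale. Hemizygous loci
(*AR*, *FMR1* in males) are called at ploidy 1 from a sample-sex setting.

## Classification

Per-allele categories come from the count partition at the point estimate
(at the minimum count, flagged minimum-severity, for bound-only alleles),
then:

* **Composition gate.** At loci whose vocabulary includes expandable units
  of unknown or no pathogenicity (*RFC1*, *FGF14*, *ATXN8OS*), an
  expanded-length allele keeps its length category only if its
  pathogenic-unit fraction is ≥ 0.5; otherwise `uncertain_composition`. The
  0.5 threshold is a package choice (no published cut-off exists) and is
  configurable; every rationale string records the fraction used.
* **Interruption override** where interrupted ranges are catalogued.
* **Boundary straddle** is flagged when an allele's mosaic range crosses a
  category boundary (e.g. an *RFC1* ">200" bound below the 400 threshold).

Case significance: dominant/X-linked cases take the most severe allele
(premutation and uncertain-composition alleles yield an uncertain case);
recessive cases are pathogenic only with both alleles at reduced penetrance
or beyond, one such allele being a carrier. A male *FMR1* full-mutation
length is corroborated by a methylated CpG fraction ≥ 0.2 on the expanded
allele's reads, else downgraded to uncertain; 0.2 is a package default
(published evidence is presence/absence) and configurable.

## Methylation

A CpG counts as methylated when its call probability ≥ 0.5 (configurable;
boundary behavior: cutoff 0 counts every call, cutoff 1 only certainty).
Per-read fractions are undefined (not zero) for CpG-free reads; the
aggregate is CpG-weighted. 5hmC calls are counted together with 5mC. Calls
within 100 bp of the repeat region are included. The interruption
association groups reads by presence of a contiguous run of ≥ 5 interruption
units and flags an absolute between-group mean difference ≥ 0.5 — the
crisp methylated-vs-unmethylated contrast seen in mosaic full-mutation
samples.

## Short-read estimation and triage

A 150 bp read sizes a repeat exactly when the tract plus two 7 bp unique
flank anchors fits in the read, i.e. tracts up to 136 bp — the practical
limit of this read length. Beyond that the expanded allele is predicted
statistically from (a) reads fully contained in repeat sequence,
`units = round(in_repeat_reads · read_length / (2 · flank_depth · unit_length))`
with depth measured from reads holding a complete 30 bp flank, and (b) the
longest visible one-anchored repeat extent when it exceeds what any
single-read-sizable allele could produce. Statistical predictions beyond
floor(135 / unit_length) units are flagged `beyond_reliable_range`; in the
synthetic benchmarks they underestimate long alleles substantially (e.g. a
350-unit *FGF14* allele predicted at ~75 units), which is precisely why such
estimates only ever route a case to long-read confirmation, never to a final
genotype.

Triage fires on any of: **R1** an allele tract ≥ 135 bp (the conservative
end of the 135–140 bp operating range — clinical false negatives cost more
than extra long-read runs); **R2** a statistical prediction above the normal
range at a locus whose pathogenic threshold exceeds the read length; **R3**
possible expansion at a composition-dependent locus; **R4** possible
biallelic expansion at a recessive locus; **R5** possible
premutation/expansion at a methylation-dependent locus. For loci with no
annotated normal range the normal ceiling is taken as 0 (any repeat content
routes to long reads). The decision is monotone: growing estimates never
turn the long-read requirement off.

## Synthetic data generator

The generator defines the study conditions for all tests:

* **Reads are molecules.** A sampled molecule length ≥ the construct
  (flank + repeat + flank) reads the whole construct and spans; shorter
  molecules fall uniformly within it, truncating inside the repeat and
  producing the one-sided and fully-in-repeat reads characteristic of very
  long expansions. Long lengths are lognormal (median 8 kb, σ = 0.5,
  typical of ligation preps; configurable); short mode tiles 150 bp reads
  over the construct embedded in 400 bp of deterministic per-locus padding
  so flank depth is measurable.
* **Mosaicism** is per-read uniform integer jitter on the largest segment —
  length variability concentrates in the expanded run — with compositional
  mosaicism modeled by mixing allele specs. Jitter defaults in the analysis
  panel (6 units on a 100-unit allele, 120 on a 700-unit allele) were chosen
  to reproduce the width of clinically reported mosaic ranges, not fitted.
* **Errors** are i.i.d. per-base substitutions/insertions/deletions
  (validated to ±10% of the configured rate over 10⁶ bases). No
  homopolymer-biased or chemistry-specific error structure is modeled.
* **Methylation** is emitted per CpG as probability 0.95 (methylated) or
  0.05 (unmethylated), drawn per site from the allele's methylation state —
  crisp binary-like states. Calls are assigned on the final read sequence.
* Everything is reproducible from the spec's integer seed; identical specs
  yield byte-identical outputs.

Benchmark problem sizes: the recovery study runs 50 seeded simulations per
scenario at coverage 20 (≈ 40 long reads/sample) with 1% substitution error;
the oracle-equivalence suite uses 1000 random sequences of length ≤ 25; the
partition and monotonicity sweeps are exhaustive over counts 0–2000 at all
29 loci.

**What passing tests show — and don't.** Recovery of 100/700-unit *FXN*
alleles within ±3 units under these conditions demonstrates the pipeline's
logic (anchoring, length-based counting, gap clustering, recessive
classification) is correct and robust to substitution error. It does not
demonstrate performance on real nanopore data, whose errors are indel-rich
and context-dependent, whose flanks are not motif-free by construction, and
whose somatic mosaicism need not be uniform jitter on one segment. The
cohort tables are accounting identities over synthesized disposition
records, not a diagnostic-yield model.

## I/O conventions

Reads round-trip as FASTA plus a methylation sidecar TSV
(`read_id, offset, probability`; offsets are the C of each CpG in read
orientation) or as unaligned BAM with standard MM (`C+m?`) / ML tags.
Catalogs round-trip as JSON (content-identical modulo key order) and export
to BED4 plus a ranges side table. Reverse-strand reads are recognized by
trying both orientations and keeping the one that anchors a flank; CpG call
offsets are re-coordinated under reverse complement (a CpG's C at offset i
maps to length − 2 − i).

## Known limitations

* No phasing against distant SNVs, no trio logic, no compound-heterozygote
  (STR + sequence variant) mechanism.
* Decomposition is phase-anchored; a motif occurring in a rotated phase is
  reported as interruptions plus shifted runs.
* The short-read statistical estimator is deliberately simple; its output is
  only ever used to route cases to long reads.
* *BEAN1* is catalogued but its simultaneous short+long sequencing workflow
  is out of scope.
* Severity ordering across category labels (e.g. premutation vs reduced
  penetrance) is a package convention for monotonicity checks, not a
  clinical claim.
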