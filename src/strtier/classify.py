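"""Clinical classification of repeat genotypes and two-tier triage.

Per-allele categories come from the locus's normalized count partition
(:func:`strtier.catalog.category_bounds`), refined by two sequence-level
rules the length axis cannot see:

* composition gate — at loci whose motif vocabulary contains units of
  unknown or no pathogenicity (RFC1, FGF14), an expanded-length allele is
  categorized by length only when at least half of its units are pathogenic
  motifs; otherwise it is ``uncertain_composition``.
* interruption rule — where the catalog defines interrupted ranges (ATXN1's
  CAT-interrupted alleles), the presence of interruption motifs switches to
  those bounds.

Case-level significance follows inheritance: dominant/X-linked cases take the
most severe allele; recessive loci are pathogenic only with BOTH alleles at
reduced penetrance or beyond, one such allele making a carrier. An FMR1 full
mutation in a male is corroborated by CpG methylation on the expanded reads.

The triage half implements the two-tier decision: given only 150 bp
short-read evidence over a locus, do we need long-read follow-up? Alleles
whose repeat tract approaches the read length (>= 135 bp), statistical
length predictions at high-threshold loci, unresolvable motif composition,
possible biallelic expansions at recessive loci, and methylation-dependent
loci all route the sample to long reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .calling import AlleleCall, Genotype, NoCallError, find_flank
from .catalog import SEVERITY, Category, Inheritance, RepeatLocus, category_at

__all__ = [
    "CaseSignificance",
    "AlleleClassification",
    "ClassificationResult",
    "ShortReadEstimate",
    "TriageDecision",
    "classify_allele",
    "classify_case",
    "estimate_from_short_reads",
    "triage",
    "COMPOSITION_GATE_FRACTION",
    "FMR1_METHYLATION_MIN",
    "LONG_READ_TRACT_BP",
    "SHORT_READ_LENGTH",
]

#: Minimum pathogenic-unit fraction for a length-based category to stand at
#: composition-gated loci.
COMPOSITION_GATE_FRACTION = 0.5
#: Minimum methylated CpG fraction corroborating a male FMR1 full mutation.
FMR1_METHYLATION_MIN = 0.2
#: Repeat-tract length (bp) beyond which 150 bp reads cannot size an allele
#: reliably; conservative end of the 135-140 bp operating range.
LONG_READ_TRACT_BP = 135
SHORT_READ_LENGTH = 150


class CaseSignificance:
    BENIGN = "benign"
    CARRIER = "carrier"
    UNCERTAIN = "uncertain"
    REDUCED_PENETRANCE = "reduced_penetrance"
    PATHOGENIC = "pathogenic"


_CASE_RANK = {
    CaseSignificance.BENIGN: 0,
    CaseSignificance.CARRIER: 1,
    CaseSignificance.UNCERTAIN: 2,
    CaseSignificance.REDUCED_PENETRANCE: 3,
    CaseSignificance.PATHOGENIC: 4,
}

#: Allele category -> dominant-case significance contribution.
_CATEGORY_TO_CASE = {
    Category.NORMAL: CaseSignificance.BENIGN,
    Category.MUTABLE_NORMAL: CaseSignificance.BENIGN,
    Category.INTERMEDIATE_UNCERTAIN: CaseSignificance.UNCERTAIN,
    Category.UNCERTAIN_COMPOSITION: CaseSignificance.UNCERTAIN,
    Category.PREMUTATION: CaseSignificance.UNCERTAIN,
    Category.REDUCED_PENETRANCE: CaseSignificance.REDUCED_PENETRANCE,
    Category.FULL_PENETRANCE: CaseSignificance.PATHOGENIC,
}

#: Categories counting as an expansion for recessive/carrier logic.
_EXPANDED = {Category.REDUCED_PENETRANCE, Category.FULL_PENETRANCE}


@dataclass
class AlleleClassification:
    category: Category
    rationale: str
    boundary_straddle: bool = False
    minimum_severity: bool = False  # category derived from a lower bound


@dataclass
class ClassificationResult:
    locus_id: str
    per_allele: list[AlleleClassification]
    case_significance: str
    rationale: str = ""


def _gate_applies(locus: RepeatLocus) -> bool:
    """Composition-gated loci: those cataloguing non-pathogenic or uncertain
    expandable units alongside (or instead of) the pathogenic motif."""
    if locus.uncertain_motifs:
        return True
    ref_benign = locus.benign_motifs | {locus.reference_motif}
    return bool(locus.pathogenic_motifs and locus.pathogenic_motifs != ref_benign
                and (ref_benign - locus.pathogenic_motifs))


def classify_allele(allele: AlleleCall, locus: RepeatLocus) -> AlleleClassification:
    """Category of one allele, with rationale and boundary flags."""
    count = allele.unit_count_min if allele.lower_bound_only else allele.point_estimate
    interruptions_present = any(
        m in locus.interruption_motifs and f > 0 for m, f in allele.composition.items()
    )

    category = category_at(locus, count)
    notes = [f"count {count}{'+' if allele.lower_bound_only else ''} -> {category.value}"]

    if interruptions_present and (
        locus.interrupted_normal is not None or locus.interrupted_pathogenic_min is not None
    ):
        if locus.interrupted_normal is not None and locus.interrupted_normal.contains(count):
            category = Category.NORMAL
            notes.append("interrupted-normal range applies")
        elif locus.interrupted_pathogenic_min is not None:
            if count >= locus.interrupted_pathogenic_min:
                category = Category.FULL_PENETRANCE
                notes.append(
                    f"interrupted pathogenic threshold {locus.interrupted_pathogenic_min} met"
                )
            elif SEVERITY[category] >= SEVERITY[Category.FULL_PENETRANCE]:
                category = Category.INTERMEDIATE_UNCERTAIN
                notes.append(
                    f"below interrupted pathogenic threshold {locus.interrupted_pathogenic_min}"
                )

    if (
        SEVERITY[category] > SEVERITY[Category.MUTABLE_NORMAL]
        and _gate_applies(locus)
        and allele.composition
    ):
        path_frac = sum(
            f for m, f in allele.composition.items() if m in locus.pathogenic_motifs
        )
        if path_frac < COMPOSITION_GATE_FRACTION:
            category = Category.UNCERTAIN_COMPOSITION
            notes.append(
                f"pathogenic-unit fraction {path_frac:.2f} < "
                f"{COMPOSITION_GATE_FRACTION} -> uncertain composition"
            )
        else:
            notes.append(
                f"pathogenic-unit fraction {path_frac:.2f} >= "
                f"{COMPOSITION_GATE_FRACTION}: length-based category stands"
            )

    straddle = category_at(locus, allele.unit_count_min) != category_at(
        locus, allele.unit_count_max
    )
    if straddle:
        notes.append(
            f"mosaic range [{allele.unit_count_min},{allele.unit_count_max}] "
            "straddles a category boundary"
        )
    return AlleleClassification(
        category=category,
        rationale="; ".join(notes),
        boundary_straddle=straddle,
        minimum_severity=allele.lower_bound_only,
    )


def classify_case(
    genotype: Genotype,
    locus: RepeatLocus,
    per_allele: Optional[Sequence[AlleleClassification]] = None,
) -> ClassificationResult:
    """Case-level significance under the locus's inheritance model."""
    if per_allele is None:
        per_allele = [classify_allele(a, locus) for a in genotype.alleles]
    per_allele = list(per_allele)
    if len(per_allele) != len(genotype.alleles):
        raise ValueError("one classification per allele required")

    cats = [c.category for c in per_allele]
    notes: list[str] = []

    # a lone cluster at ploidy 2 is treated as two copies of the same allele
    # (the dropout caveat is recorded in the rationale)
    effective = list(cats)
    if genotype.ploidy == 2 and len(cats) == 1:
        effective = cats * 2
        notes.append("single cluster at ploidy 2 treated as homozygous (dropout possible)")

    if locus.inheritance is Inheritance.RECESSIVE:
        n_expanded = sum(c in _EXPANDED for c in effective)
        if n_expanded >= 2:
            sig = (
                CaseSignificance.PATHOGENIC
                if any(c is Category.FULL_PENETRANCE for c in effective)
                else CaseSignificance.REDUCED_PENETRANCE
            )
            notes.append("biallelic expansion at recessive locus")
        elif n_expanded == 1:
            sig = CaseSignificance.CARRIER
            notes.append("single expanded allele at recessive locus")
        else:
            sig = max(
                (_CATEGORY_TO_CASE[c] for c in effective), key=_CASE_RANK.__getitem__
            )
    else:
        sig = max((_CATEGORY_TO_CASE[c] for c in effective), key=_CASE_RANK.__getitem__)

    # PABPN1-style homozygous rule: a count pathogenic only in two copies
    if (
        locus.homozygous_pathogenic_count is not None
        and genotype.ploidy == 2
        and len(genotype.alleles) >= 1
        and all(
            a.point_estimate == locus.homozygous_pathogenic_count
            for a in genotype.alleles
        )
    ):
        sig = CaseSignificance.PATHOGENIC
        notes.append(
            f"homozygous {locus.homozygous_pathogenic_count}-unit alleles are pathogenic"
        )

    # methylation corroboration of a male FMR1-style full mutation
    if (
        locus.methylation_relevant
        and locus.inheritance is Inheritance.X_LINKED
        and genotype.ploidy == 1
        and any(c is Category.FULL_PENETRANCE for c in cats)
    ):
        fracs = [
            a.methylated_fraction
            for a, c in zip(genotype.alleles, per_allele)
            if c.category is Category.FULL_PENETRANCE
        ]
        known = [f for f in fracs if f is not None]
        if not known or max(known) < FMR1_METHYLATION_MIN:
            sig = CaseSignificance.UNCERTAIN
            notes.append(
                "full-mutation length without corroborating CpG methylation "
                f"(requires >= {FMR1_METHYLATION_MIN}) -> uncertain"
            )
        else:
            notes.append(
                f"expanded-read methylated fraction {max(known):.2f} corroborates"
            )

    return ClassificationResult(
        locus_id=locus.locus_id,
        per_allele=per_allele,
        case_significance=sig,
        rationale="; ".join(notes),
    )


@dataclass
class ShortReadEstimate:
    """Allele-length evidence obtainable from 150 bp reads alone."""

    locus_id: str
    allele_unit_estimates: list[int]
    statistical: list[bool]  # per estimate: statistical prediction vs exact
    spanning_read_count: int
    in_repeat_read_count: int
    flanking_read_count: int
    read_length: int = SHORT_READ_LENGTH
    beyond_reliable_range: bool = False

    def reliability_ceiling(self, unit_length: int) -> int:
        return math.floor(LONG_READ_TRACT_BP / unit_length)


#: Unique-anchor length used when sizing repeats inside single short reads.
#: A 150 bp read can hold a repeat of up to read_length - 2*anchor bp between
#: two anchors, i.e. 136 bp -- the practical sizing limit of this read length.
SHORT_READ_ANCHOR = 7


def estimate_from_short_reads(
    reads: Sequence[tuple[str, str]],
    locus: RepeatLocus,
    read_length: int = SHORT_READ_LENGTH,
    min_gap_units: int = 5,
    anchor_len: int = SHORT_READ_ANCHOR,
) -> ShortReadEstimate:
    """Genotype prediction from short reads over a locus.

    Reads holding both flank anchors give exact repeat lengths; these are
    clustered by a simple gap rule into up to two exact allele counts. When
    spanning evidence accounts for fewer than two alleles, the missing (long)
    allele is predicted statistically from the remaining read classes:

    * reads fully contained in repeat sequence, via
      ``units = round(in_repeat_bases / (2 * mean_flank_depth * unit_length))``
      (expanded repeat bases over flank-derived depth, in units), and/or
    * one-anchored reads whose visible repeat extent exceeds what any
      single-read-sizable repeat could produce (a lower bound on the tract).

    Statistical predictions beyond ``floor(135 / unit_length)`` units exceed
    what this read length supports and are flagged ``beyond_reliable_range``.
    """
    left_anchor = locus.left_flank[-anchor_len:]
    right_anchor = locus.right_flank[:anchor_len]
    probes = [m * max(2, math.ceil(20 / len(m))) for m in locus.all_motifs]

    spanning_lengths: list[int] = []
    in_repeat = 0
    flanking = 0
    n_left_full = 0
    n_right_full = 0
    max_visible_bp = 0
    for _, seq in reads:
        lpos = seq.find(left_anchor)
        rsearch = lpos + anchor_len if lpos >= 0 else 0
        rpos = seq.find(right_anchor, rsearch)
        if lpos >= 0 and rpos >= 0:
            spanning_lengths.append(
                round((rpos - lpos - anchor_len) / locus.unit_length)
            )
            flanking += 1
        elif lpos >= 0:
            flanking += 1
            max_visible_bp = max(max_visible_bp, len(seq) - lpos - anchor_len)
        elif rpos >= 0:
            flanking += 1
            max_visible_bp = max(max_visible_bp, rpos)
        elif any(p in seq for p in probes):
            in_repeat += 1
            continue
        else:
            continue
        if locus.left_flank in seq:
            n_left_full += 1
        if locus.right_flank in seq:
            n_right_full += 1
    if not spanning_lengths and not in_repeat and not flanking:
        raise NoCallError(f"{locus.locus_id}: no short reads over locus")

    estimates: list[int] = []
    statistical: list[bool] = []
    if spanning_lengths:
        spanning_lengths.sort()
        gaps = [
            spanning_lengths[i + 1] - spanning_lengths[i]
            for i in range(len(spanning_lengths) - 1)
        ]
        if gaps and max(gaps) > min_gap_units:
            cut = gaps.index(max(gaps))
            groups = [spanning_lengths[: cut + 1], spanning_lengths[cut + 1 :]]
        else:
            groups = [spanning_lengths]
        for g in groups[:2]:
            estimates.append(int(round(float(np.median(g)))))
            statistical.append(False)

    beyond = False
    ceiling = math.floor(LONG_READ_TRACT_BP / locus.unit_length)
    sizable_bp = read_length - 2 * anchor_len
    if len(estimates) < 2:
        candidates: list[int] = []
        if in_repeat > 0:
            # diploid depth from reads holding a complete 30 bp flank
            flank_len = len(locus.left_flank)
            depth = (
                (n_left_full + n_right_full)
                * read_length
                / (2.0 * max(read_length - flank_len + 1, 1))
            )
            depth = max(depth, 1.0)
            candidates.append(
                int(
                    round(
                        in_repeat
                        * read_length
                        / (2 * depth * locus.unit_length)
                    )
                )
            )
        if max_visible_bp > sizable_bp:
            # a visible tract no sizable allele could produce: lower bound
            candidates.append(max_visible_bp // locus.unit_length)
        if candidates:
            stat = max(candidates)
            estimates.append(stat)
            statistical.append(True)
            beyond = stat > ceiling
    if len(estimates) == 1:
        # no evidence for a distinct second allele
        estimates.append(estimates[0])
        statistical.append(statistical[0])

    order = np.argsort(estimates, kind="stable")
    estimates = [estimates[i] for i in order]
    statistical = [statistical[i] for i in order]

    return ShortReadEstimate(
        locus_id=locus.locus_id,
        allele_unit_estimates=estimates[:2],
        statistical=statistical[:2],
        spanning_read_count=len(spanning_lengths),
        in_repeat_read_count=in_repeat,
        flanking_read_count=flanking,
        read_length=read_length,
        beyond_reliable_range=beyond,
    )


@dataclass
class TriageDecision:
    needs_long_read: bool
    reasons: list[tuple[str, str]] = field(default_factory=list)

    def rule_ids(self) -> list[str]:
        return [r for r, _ in self.reasons]


def triage(estimate: ShortReadEstimate, locus: RepeatLocus) -> TriageDecision:
    """Decide whether a case needs long-read follow-up (rules R1-R5).

    R1  an allele's repeat tract reaches 135 bp, the sizing limit of 150 bp
        reads;
    R2  a statistical (non-spanning) prediction above the normal range at a
        locus whose pathogenic threshold lies beyond the read length;
    R3  possible expansion at a locus whose pathogenicity depends on motif
        composition, which short reads cannot resolve;
    R4  possible biallelic expansion at a recessive locus (allele phasing and
        exact lengths required);
    R5  possible premutation/expansion at a methylation-dependent locus.
    """
    reasons: list[tuple[str, str]] = []
    ul = locus.unit_length
    ests = estimate.allele_unit_estimates
    normal_hi = locus.normal_ceiling

    for units in ests:
        if units * ul >= LONG_READ_TRACT_BP:
            reasons.append(
                (
                    "R1",
                    f"allele of {units} units spans {units * ul} bp >= "
                    f"{LONG_READ_TRACT_BP} bp sizing limit",
                )
            )
            break

    if locus.pathogenic_min is not None and locus.pathogenic_min * ul > estimate.read_length:
        if any(
            s and u > normal_hi for u, s in zip(ests, estimate.statistical)
        ):
            reasons.append(
                (
                    "R2",
                    "statistical length prediction above normal range at a "
                    f"locus with pathogenic threshold {locus.pathogenic_min} units "
                    f"({locus.pathogenic_min * ul} bp > read length)",
                )
            )

    if _gate_applies(locus) and any(u > normal_hi for u in ests):
        reasons.append(
            ("R3", "expanded estimate at a composition-dependent locus; "
                   "motif makeup unresolvable from short reads")
        )

    if locus.inheritance is Inheritance.RECESSIVE and all(u > normal_hi for u in ests) and len(ests) >= 2:
        reasons.append(
            ("R4", "both alleles above normal range at a recessive locus; "
                   "exact biallelic lengths required")
        )

    if locus.methylation_relevant:
        trigger = None
        if locus.premutation is not None:
            trigger = locus.premutation.lo
        elif locus.reduced_penetrance is not None:
            trigger = locus.reduced_penetrance.lo
        elif locus.pathogenic_min is not None:
            trigger = locus.pathogenic_min
        if trigger is not None and any(u >= trigger for u in ests):
            reasons.append(
                ("R5", f"estimate at/beyond {trigger} units at a methylation-"
                       "dependent locus; epigenetic status required")
            )

    return TriageDecision(needs_long_read=bool(reasons), reasons=reasons)
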