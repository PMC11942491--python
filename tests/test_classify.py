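"""Clinical classification, short-read estimation, and triage rules."""

import pytest

from strtier.calling import AlleleCall, Genotype
from strtier.catalog import SEVERITY, Category, Inheritance, category_at
from strtier.classify import (
    CaseSignificance,
    ShortReadEstimate,
    classify_allele,
    classify_case,
    estimate_from_short_reads,
    triage,
)
from strtier.simulate import (
    ReadLengthModel,
    SyntheticAlleleSpec,
    SyntheticSampleSpec,
    simulate_reads,
)


def allele(point, lo=None, hi=None, composition=None, lower_bound=False,
           methylated_fraction=None):
    lo = point if lo is None else lo
    hi = point if hi is None else hi
    return AlleleCall(
        unit_count_min=lo,
        unit_count_max=hi,
        point_estimate=point,
        lower_bound_only=lower_bound,
        supporting_reads=[],
        composition=composition or {},
        methylated_fraction=methylated_fraction,
    )


class TestClassifyAllele:
    def test_fxn_threshold(self, fxn):
        c = classify_allele(allele(66, composition={"GAA": 1.0}), fxn)
        assert c.category is Category.FULL_PENETRANCE
        c = classify_allele(allele(65, composition={"GAA": 1.0}), fxn)
        assert c.category is Category.INTERMEDIATE_UNCERTAIN

    def test_fmr1_premutation(self, fmr1):
        c = classify_allele(allele(130, composition={"CGG": 1.0}), fmr1)
        assert c.category is Category.PREMUTATION

    def test_htt_reduced_penetrance(self, catalog):
        c = classify_allele(allele(36), catalog["HTT"])
        assert c.category is Category.REDUCED_PENETRANCE

    def test_fgf14_composition_gate(self, catalog):
        fgf14 = catalog["FGF14"]
        gaaggadominant = {"GAAGGA": 0.95, "GAA": 0.05}
        c = classify_allele(allele(330, composition=gaaggadominant), fgf14)
        assert c.category is Category.UNCERTAIN_COMPOSITION
        assert "0.05" in c.rationale or "fraction" in c.rationale
        c2 = classify_allele(allele(330, composition={"GAA": 1.0}), fgf14)
        assert c2.category is Category.FULL_PENETRANCE

    def test_rfc1_pathogenic_composition_required(self, catalog):
        rfc1 = catalog["RFC1"]
        c = classify_allele(allele(500, composition={"AAGGG": 0.9, "AAAAG": 0.1}), rfc1)
        assert c.category is Category.FULL_PENETRANCE
        c2 = classify_allele(allele(500, composition={"AAAAG": 1.0}), rfc1)
        assert c2.category is Category.UNCERTAIN_COMPOSITION

    def test_atxn1_interruption_rule(self, catalog):
        atxn1 = catalog["ATXN1"]
        # 40 units: pathogenic if pure CAG, normal when CAT-interrupted
        pure = classify_allele(allele(40, composition={"CAG": 1.0}), atxn1)
        assert pure.category is Category.FULL_PENETRANCE
        interrupted = classify_allele(
            allele(40, composition={"CAG": 0.9, "CAT": 0.1}), atxn1
        )
        assert interrupted.category is Category.NORMAL
        # above the interrupted-pathogenic threshold, interruptions do not save
        big = classify_allele(allele(46, composition={"CAG": 0.9, "CAT": 0.1}), atxn1)
        assert big.category is Category.FULL_PENETRANCE
        # between interrupted-normal and interrupted threshold: uncertain
        mid = classify_allele(allele(45, composition={"CAG": 0.9, "CAT": 0.1}), atxn1)
        assert mid.category is Category.INTERMEDIATE_UNCERTAIN

    def test_boundary_straddle_flag(self, fxn):
        c = classify_allele(
            allele(64, lo=60, hi=70, composition={"GAA": 1.0}), fxn
        )
        assert c.boundary_straddle

    def test_lower_bound_category_is_minimum_severity(self, catalog):
        rfc1 = catalog["RFC1"]
        c = classify_allele(
            allele(830, lo=830, hi=910, composition={"AAGGG": 1.0}, lower_bound=True),
            rfc1,
        )
        assert c.category is Category.FULL_PENETRANCE
        assert c.minimum_severity

    def test_classification_follows_partition_for_every_locus(self, catalog):
        # For fixed pathogenic-dominant composition, classify_allele returns
        # exactly the partition category at every count; severity is
        # non-decreasing above the benign region except at loci whose printed
        # reduced-penetrance range stops short of the full threshold (RFC1
        # 11-200 vs 400, DIP2B 139-206 vs 250), where the gap is uncertain.
        for locus in catalog:
            comp = {
                m: 1.0 / max(1, len(locus.pathogenic_motifs))
                for m in (locus.pathogenic_motifs or {locus.reference_motif})
            }
            benign_hi = locus.normal_ceiling
            if locus.mutable_normal is not None and locus.mutable_normal.hi is not None:
                benign_hi = max(benign_hi, locus.mutable_normal.hi)
            printed_dip = (
                locus.reduced_penetrance is not None
                and locus.reduced_penetrance.hi is not None
                and locus.pathogenic_min is not None
                and locus.pathogenic_min > locus.reduced_penetrance.hi + 1
            )
            last = -1
            for count in range(0, 2001):
                cat = classify_allele(allele(count, composition=comp), locus).category
                assert cat is category_at(locus, count), (locus.locus_id, count)
                if not printed_dip and count > benign_hi:
                    assert SEVERITY[cat] >= last, (locus.locus_id, count)
                    last = SEVERITY[cat]
        assert {
            l.locus_id
            for l in catalog
            if l.reduced_penetrance is not None
            and l.reduced_penetrance.hi is not None
            and l.pathogenic_min is not None
            and l.pathogenic_min > l.reduced_penetrance.hi + 1
        } == {"RFC1", "DIP2B"}


class TestClassifyCase:
    def test_fxn_biallelic_pathogenic(self, fxn):
        gt = Genotype(
            locus_id="FXN",
            alleles=[
                allele(100, composition={"GAA": 1.0}),
                allele(700, composition={"GAA": 1.0}),
            ],
            ploidy=2,
        )
        res = classify_case(gt, fxn)
        assert res.case_significance == CaseSignificance.PATHOGENIC

    def test_fxn_single_expansion_is_carrier(self, fxn):
        gt = Genotype(
            locus_id="FXN",
            alleles=[
                allele(30, composition={"GAA": 1.0}),
                allele(700, composition={"GAA": 1.0}),
            ],
            ploidy=2,
        )
        assert classify_case(gt, fxn).case_significance == CaseSignificance.CARRIER

    def test_rfc1_bounded_biallelic_pathogenic(self, catalog):
        rfc1 = catalog["RFC1"]
        comp = {"AAGGG": 0.9, "AAAAG": 0.1}
        gt = Genotype(
            locus_id="RFC1",
            alleles=[
                allele(830, lo=830, hi=910, composition=comp, lower_bound=True),
                allele(450, lo=450, hi=500, composition=comp, lower_bound=True),
            ],
            ploidy=2,
        )
        res = classify_case(gt, rfc1)
        assert res.case_significance == CaseSignificance.PATHOGENIC

    def test_dominant_takes_most_severe_allele(self, catalog):
        htt = catalog["HTT"]
        gt = Genotype(
            locus_id="HTT", alleles=[allele(18), allele(44)], ploidy=2
        )
        assert classify_case(gt, htt).case_significance == CaseSignificance.PATHOGENIC
        gt2 = Genotype(
            locus_id="HTT", alleles=[allele(18), allele(37)], ploidy=2
        )
        assert (
            classify_case(gt2, htt).case_significance
            == CaseSignificance.REDUCED_PENETRANCE
        )

    def test_fmr1_full_mutation_requires_methylation_in_males(self, fmr1):
        expanded = allele(
            250, composition={"CGG": 1.0}, methylated_fraction=0.8
        )
        gt = Genotype(locus_id="FMR1", alleles=[expanded], ploidy=1)
        assert classify_case(gt, fmr1).case_significance == CaseSignificance.PATHOGENIC

        unmeth = allele(250, composition={"CGG": 1.0}, methylated_fraction=0.05)
        gt2 = Genotype(locus_id="FMR1", alleles=[unmeth], ploidy=1)
        assert classify_case(gt2, fmr1).case_significance == CaseSignificance.UNCERTAIN

    def test_pabpn1_homozygous_eleven_is_pathogenic(self, catalog):
        pab = catalog["PABPN1"]
        gt = Genotype(
            locus_id="PABPN1", alleles=[allele(11), allele(11)], ploidy=2
        )
        assert classify_case(gt, pab).case_significance == CaseSignificance.PATHOGENIC
        het = Genotype(
            locus_id="PABPN1", alleles=[allele(8), allele(11)], ploidy=2
        )
        assert (
            classify_case(het, pab).case_significance
            != CaseSignificance.PATHOGENIC
        )

    def test_recessive_never_pathogenic_with_single_expanded_allele(self, catalog):
        # soundness sweep: one expanded + one normal-range allele
        for locus in (catalog["FXN"], catalog["RFC1"], catalog["CSTB"], catalog["GLS"]):
            comp = {m: 1.0 for m in list(locus.pathogenic_motifs)[:1]}
            normal_count = locus.normal.lo if locus.normal else 0
            for expanded_count in (100, 500, 1000, 2000):
                gt = Genotype(
                    locus_id=locus.locus_id,
                    alleles=[
                        allele(normal_count, composition=comp),
                        allele(expanded_count, composition=comp),
                    ],
                    ploidy=2,
                )
                res = classify_case(gt, locus)
                n_expanded = sum(
                    c.category in (Category.REDUCED_PENETRANCE, Category.FULL_PENETRANCE)
                    for c in res.per_allele
                )
                if n_expanded < 2:
                    assert res.case_significance != CaseSignificance.PATHOGENIC

    def test_atxn8os_severity_caps_at_reduced_penetrance(self, catalog):
        a8 = catalog["ATXN8OS"]
        gt = Genotype(
            locus_id="ATXN8OS",
            alleles=[allele(20), allele(96, composition={"CTG": 0.875, "CTA": 0.125})],
            ploidy=2,
        )
        res = classify_case(gt, a8)
        assert res.per_allele[1].category is Category.REDUCED_PENETRANCE
        assert res.case_significance == CaseSignificance.REDUCED_PENETRANCE


class TestShortReadEstimate:
    def _short_reads(self, catalog, locus_id, counts, coverage=30, seed=3):
        spec = SyntheticSampleSpec(
            locus_id=locus_id,
            alleles=tuple(
                SyntheticAlleleSpec(
                    segments=((catalog[locus_id].reference_motif, c),)
                )
                for c in counts
            ),
            coverage=coverage,
            read_length_model=ReadLengthModel(kind="short"),
            seed=seed,
            strand_flip=False,
        )
        reads, _ = simulate_reads(spec, catalog)
        return [(r.read_id, r.sequence) for r in reads]

    def test_short_alleles_called_exactly_from_spanning_reads(self, catalog):
        reads = self._short_reads(catalog, "FXN", (30, 30))
        est = estimate_from_short_reads(reads, catalog["FXN"])
        assert est.allele_unit_estimates == [30, 30]
        assert est.statistical == [False, False]
        assert est.spanning_read_count > 0
        assert not est.beyond_reliable_range

    def test_long_expansion_flagged_statistical_and_unreliable(self, catalog):
        reads = self._short_reads(catalog, "RFC1", (20, 600), seed=4)
        est = estimate_from_short_reads(reads, catalog["RFC1"])
        assert any(est.statistical)
        assert est.in_repeat_read_count > 0
        assert est.beyond_reliable_range

    def test_reliability_ceiling_in_units(self, catalog):
        est = ShortReadEstimate(
            locus_id="HTT",
            allele_unit_estimates=[18, 40],
            statistical=[False, False],
            spanning_read_count=10,
            in_repeat_read_count=0,
            flanking_read_count=10,
        )
        assert est.reliability_ceiling(3) == 45
        assert est.reliability_ceiling(5) == 27


def estimate_for(locus_id, units, statistical=None):
    units = list(units)
    return ShortReadEstimate(
        locus_id=locus_id,
        allele_unit_estimates=units,
        statistical=statistical or [False] * len(units),
        spanning_read_count=10,
        in_repeat_read_count=0,
        flanking_read_count=10,
    )


class TestTriage:
    def test_htt_47_units_exceeds_sizing_limit(self, catalog):
        d = triage(estimate_for("HTT", [18, 47]), catalog["HTT"])
        assert d.needs_long_read and "R1" in d.rule_ids()

    def test_htt_40_units_resolves_on_short_reads(self, catalog):
        d = triage(estimate_for("HTT", [18, 40]), catalog["HTT"])
        assert not d.needs_long_read and d.reasons == []

    def test_fgf14_statistical_estimate_triggers_followup(self, catalog):
        d = triage(
            estimate_for("FGF14", [36, 105], statistical=[False, True]),
            catalog["FGF14"],
        )
        assert d.needs_long_read and "R2" in d.rule_ids()

    def test_rfc1_biallelic_composition_rules(self, catalog):
        d = triage(estimate_for("RFC1", [30, 30]), catalog["RFC1"])
        assert "R3" in d.rule_ids() and "R4" in d.rule_ids()

    def test_fmr1_premutation_range_needs_methylation(self, catalog):
        d = triage(estimate_for("FMR1", [30, 60]), catalog["FMR1"])
        assert "R5" in d.rule_ids()
        d2 = triage(estimate_for("FMR1", [30, 40]), catalog["FMR1"])
        assert not d2.needs_long_read

    def test_triage_monotone_in_estimates_for_every_locus(self, catalog):
        for locus in catalog:
            fired = False
            for units in range(0, 301, 5):
                d = triage(estimate_for(locus.locus_id, [10, units]), locus)
                if fired:
                    assert d.needs_long_read, (locus.locus_id, units)
                fired = fired or d.needs_long_read
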