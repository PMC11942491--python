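"""Region extraction, flank anchoring, and allele clustering."""

import itertools
import random

import numpy as np
import pytest

from strtier.calling import (
    NoCallError,
    call_alleles,
    extract_region,
    find_flank,
    genotype_sample,
    reverse_complement,
)
from strtier.decompose import ReadDecomposition
from strtier.simulate import (
    ReadLengthModel,
    SyntheticAlleleSpec,
    SyntheticSampleSpec,
    simulate_reads,
)


def hamming_scan(read, flank, allowed):
    """Independent oracle: best flank offset by direct Hamming comparison."""
    best_off, best_mm = None, allowed + 1
    for off in range(len(read) - len(flank) + 1):
        mm = sum(a != b for a, b in zip(read[off : off + len(flank)], flank))
        if mm < best_mm:
            best_off, best_mm = off, mm
    return best_off


class TestExtractRegion:
    def test_exact_construction_spans_both_flanks(self, fxn):
        read = fxn.left_flank + "GAA" * 10 + fxn.right_flank
        region = extract_region(read, fxn)
        assert region.spans_left and region.spans_right
        assert region.sequence == "GAA" * 10

    def test_truncated_read_spans_left_only(self, fxn):
        read = (fxn.left_flank + "GAA" * 500)[: len(fxn.left_flank) + 900]
        region = extract_region(read, fxn)
        assert region.spans_left and not region.spans_right
        assert region.sequence == "GAA" * 300

    def test_flank_with_two_substitutions_still_anchors(self, fxn):
        flank = list(fxn.left_flank)
        flank[7] = "A" if flank[7] != "A" else "C"
        flank[22] = "G" if flank[22] != "G" else "T"
        mutated = "".join(flank)
        pad = "TGCA" * 10
        read = pad + mutated + "GAA" * 20 + fxn.right_flank
        found = find_flank(read, fxn.left_flank, max_mismatch_frac=0.2)
        assert found == hamming_scan(read, fxn.left_flank, allowed=6) == len(pad)
        region = extract_region(read, fxn, max_flank_mismatch_frac=0.2)
        assert region.spanning and region.sequence == "GAA" * 20

    def test_read_without_flanks_kept_only_with_motif_content(self, fxn):
        in_repeat = "GAA" * 60
        region = extract_region(in_repeat, fxn)
        assert region is not None
        assert not region.spans_left and not region.spans_right
        unrelated = "TGCATGCA" * 30
        assert extract_region(unrelated, fxn) is None

    def test_reverse_complement_read_is_recovered(self, fxn):
        read = fxn.left_flank + "GAA" * 25 + fxn.right_flank
        region = extract_region(reverse_complement(read), fxn)
        assert region.spanning
        assert region.sequence == "GAA" * 25
        assert region.strand == "-"


def make_decomp(read_id, units, unit_length=3, spanning=True):
    d = ReadDecomposition(
        read_id=read_id, segments=[], region_length=units * unit_length
    )
    d.segments = []
    d.spans_left = spanning
    d.spans_right = spanning
    return d


class TestCallAlleles:
    def test_biallelic_mosaic_ranges(self, fxn):
        counts = [92, 95, 100, 104, 649, 700, 830, 901]
        decs = [make_decomp(f"r{i}", c) for i, c in enumerate(counts)]
        gt = call_alleles(decs, fxn, ploidy=2)
        assert len(gt.alleles) == 2
        a1, a2 = gt.alleles
        assert (a1.unit_count_min, a1.unit_count_max) == (92, 104)
        assert (a2.unit_count_min, a2.unit_count_max) == (649, 901)
        assert not gt.homozygous_or_dropout
        assert a1.unit_count_max < a2.unit_count_min  # never overlapping

    def test_identical_counts_raise_homozygous_or_dropout_flag(self, fxn):
        decs = [make_decomp(f"r{i}", 10) for i in range(6)]
        gt = call_alleles(decs, fxn, ploidy=2)
        assert len(gt.alleles) == 1
        assert gt.alleles[0].unit_count_min == gt.alleles[0].unit_count_max == 10
        assert gt.homozygous_or_dropout

    def test_no_reads_is_a_no_call(self, fxn):
        with pytest.raises(NoCallError):
            call_alleles([], fxn)

    def test_bounds_only_reads_give_lower_bound_alleles(self, catalog):
        rfc1 = catalog["RFC1"]
        counts = [200, 230, 260, 830, 870, 910]
        decs = [
            make_decomp(f"r{i}", c, unit_length=5, spanning=False)
            for i, c in enumerate(counts)
        ]
        gt = call_alleles(decs, rfc1, ploidy=2)
        assert len(gt.alleles) == 2
        assert all(a.lower_bound_only for a in gt.alleles)
        # the reported point is the maximum lower bound in each cluster
        assert gt.alleles[0].point_estimate == 260
        assert gt.alleles[1].point_estimate == 910

    def test_bounded_reads_never_inflate_spanning_ranges(self, fxn):
        decs = [make_decomp(f"s{i}", c) for i, c in enumerate([100, 102, 700, 705])]
        decs.append(make_decomp("b0", 400, spanning=False))
        decs.append(make_decomp("b1", 720, spanning=False))
        gt = call_alleles(decs, fxn, ploidy=2)
        assert gt.alleles[1].unit_count_max == 705  # bound did not inflate
        assert "b1" in gt.alleles[1].supporting_reads
        assert "b0" in gt.alleles[1].supporting_reads  # highest compatible

    def test_gap_split_matches_exhaustive_min_variance_split(self, fxn):
        # bimodal counts, the regime the gap rule is designed for
        rng = random.Random(7)
        for _ in range(200):
            n1 = rng.randint(1, 6)
            n2 = rng.randint(1, 6)
            mu1 = rng.randint(10, 60)
            mu2 = mu1 + rng.randint(40, 500)
            counts = sorted(
                [mu1 + rng.randint(-5, 5) for _ in range(n1)]
                + [mu2 + rng.randint(-5, 5) for _ in range(n2)]
            )
            decs = [make_decomp(f"r{i}", c) for i, c in enumerate(counts)]
            gt = call_alleles(decs, fxn, ploidy=2)
            if len(gt.alleles) != 2:
                continue  # gap rule did not fire
            split_at = gt.alleles[0].unit_count_max

            def within_ss(groups):
                return sum(
                    sum((x - np.mean(g)) ** 2 for x in g) for g in groups if g
                )

            best = min(
                range(1, len(counts)),
                key=lambda k: within_ss([counts[:k], counts[k:]]),
            )
            assert counts[best - 1] == split_at

    def test_ploidy_one_always_single_allele(self, fmr1):
        decs = [make_decomp(f"r{i}", c) for i, c in enumerate([130, 131, 132])]
        gt = call_alleles(decs, fmr1, ploidy=1)
        assert len(gt.alleles) == 1 and not gt.homozygous_or_dropout


class TestGenotypeSample:
    def test_error_free_sample_recovers_exact_counts(self, catalog):
        spec = SyntheticSampleSpec(
            locus_id="FXN",
            alleles=(
                SyntheticAlleleSpec(segments=(("GAA", 100),)),
                SyntheticAlleleSpec(segments=(("GAA", 700),)),
            ),
            coverage=20,
            seed=11,
        )
        reads, _ = simulate_reads(spec, catalog)
        gt, decomps, regions = genotype_sample(
            [r.as_input() for r in reads], catalog["FXN"]
        )
        assert [a.point_estimate for a in gt.alleles] == [100, 700]
        assert all(a.composition.get("GAA", 0) == pytest.approx(1.0) for a in gt.alleles)

    def test_one_percent_error_stays_within_three_units(self, catalog):
        spec = SyntheticSampleSpec(
            locus_id="FXN",
            alleles=(
                SyntheticAlleleSpec(segments=(("GAA", 100),)),
                SyntheticAlleleSpec(segments=(("GAA", 700),)),
            ),
            coverage=20,
            substitution_rate=0.01,
            seed=12,
        )
        reads, _ = simulate_reads(spec, catalog)
        gt, *_ = genotype_sample([r.as_input() for r in reads], catalog["FXN"])
        points = [a.point_estimate for a in gt.alleles]
        assert abs(points[0] - 100) <= 3 and abs(points[1] - 700) <= 3

    def test_fmr1_male_single_allele(self, catalog):
        spec = SyntheticSampleSpec(
            locus_id="FMR1",
            alleles=(SyntheticAlleleSpec(segments=(("CGG", 130),)),),
            coverage=15,
            seed=13,
        )
        reads, _ = simulate_reads(spec, catalog)
        gt, *_ = genotype_sample([r.as_input() for r in reads], catalog["FMR1"], ploidy=1)
        assert len(gt.alleles) == 1
        assert gt.alleles[0].point_estimate == 130

    def test_truncation_yields_lower_bounds_not_inflated_calls(self, catalog):
        # all reads shorter than the construct: only bounded evidence
        spec = SyntheticSampleSpec(
            locus_id="FXN",
            alleles=(SyntheticAlleleSpec(segments=(("GAA", 700),)),),
            coverage=15,
            read_length_model=ReadLengthModel(
                kind="long", median_bp=900, sigma=0.1, min_bp=400
            ),
            seed=14,
        )
        reads, _ = simulate_reads(spec, catalog)
        gt, *_ = genotype_sample([r.as_input() for r in reads], catalog["FXN"], ploidy=1)
        a = gt.alleles[0]
        assert a.lower_bound_only
        assert a.point_estimate <= 700  # a bound, never an inflated exact call
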