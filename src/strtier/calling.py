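"""Repeat-region extraction and allele calling from long reads.

Reads are anchored to a locus by their 30 bp flank sequences (mismatch-
tolerant Hamming scan over all offsets); the sequence between the anchors is
the repeat region. Reads that capture both flanks ("spanning") yield exact
repeat-unit counts; reads entering the repeat from one side give lower
bounds; reads lying entirely inside a long expansion (no flank at all, but
unmistakable motif content) are kept as bounded evidence too.

Spanning-read counts are clustered into one or two alleles with a largest-gap
rule, and each allele is reported as a count *range* — the clinically
meaningful object for mosaic expansions such as "92-104" vs "649-901" — plus
a median point estimate, motif composition, and optional methylation summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .catalog import RepeatLocus
from .decompose import (
    DEFAULT_INTERRUPTION_PENALTY,
    DEFAULT_SWITCH_PENALTY,
    ReadDecomposition,
    decompose,
)

__all__ = [
    "MethCall",
    "ExtractedRegion",
    "AlleleCall",
    "Genotype",
    "NoCallError",
    "find_flank",
    "extract_region",
    "call_alleles",
    "genotype_sample",
    "reverse_complement",
    "DEFAULT_MIN_GAP_UNITS",
    "DEFAULT_MIN_GAP_FRAC",
    "DEFAULT_MAX_FLANK_MISMATCH_FRAC",
]

DEFAULT_MIN_GAP_UNITS = 5
DEFAULT_MIN_GAP_FRAC = 0.2
DEFAULT_MAX_FLANK_MISMATCH_FRAC = 0.1
#: Methylation calls within this many bp outside the repeat region are kept
#: (offsets may be negative or exceed the region length).
METH_FLANK_PAD = 100

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


#: (offset, probability) of a CpG 5mC call; offset is the C of the CpG in
#: region coordinates. The methylated flag is derived at a cutoff downstream.
MethCall = tuple[int, float]


@dataclass
class ExtractedRegion:
    """The repeat-region slice of one read, with anchor flags."""

    read_id: str
    sequence: str
    spans_left: bool
    spans_right: bool
    methylation_calls: Optional[list[MethCall]] = None
    strand: str = "+"

    @property
    def spanning(self) -> bool:
        return self.spans_left and self.spans_right


@dataclass
class AlleleCall:
    """One allele as a mosaic repeat-count range with supporting evidence."""

    unit_count_min: int
    unit_count_max: int
    point_estimate: int
    lower_bound_only: bool
    supporting_reads: list[str] = field(default_factory=list)
    composition: dict[str, float] = field(default_factory=dict)
    methylated_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.unit_count_min <= self.point_estimate <= self.unit_count_max):
            raise ValueError("point_estimate outside [min, max]")

    @property
    def mosaic_span(self) -> int:
        return self.unit_count_max - self.unit_count_min


@dataclass
class Genotype:
    locus_id: str
    alleles: list[AlleleCall]
    ploidy: int
    homozygous_or_dropout: bool = False

    def __post_init__(self) -> None:
        if len(self.alleles) > self.ploidy:
            raise ValueError("more alleles than ploidy")
        self.alleles.sort(key=lambda a: a.point_estimate)


class NoCallError(RuntimeError):
    """No usable reads at the locus."""


def find_flank(read: str, flank: str, max_mismatch_frac: float) -> Optional[int]:
    """Best-scoring occurrence of ``flank`` in ``read`` (leftmost on ties).

    Vectorized Hamming scan over every offset; a hit requires at most
    ``max_mismatch_frac * len(flank)`` mismatches. Returns the start offset
    or None.
    """
    L = len(flank)
    if len(read) < L:
        return None
    allowed = int(math.floor(max_mismatch_frac * L))
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    f = np.frombuffer(flank.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(r, L)
    mismatches = (windows != f).sum(axis=1)
    best = int(mismatches.argmin())
    if mismatches[best] <= allowed:
        return best
    return None


def _has_motif_content(read: str, locus: RepeatLocus, min_units: int = 3) -> bool:
    """Does the read contain a tandem run of any locus motif?"""
    return any(m * min_units in read for m in locus.all_motifs)


def _slice_meth(
    calls: Optional[Sequence[MethCall]], start: int, end: int
) -> Optional[list[MethCall]]:
    if calls is None:
        return None
    lo, hi = start - METH_FLANK_PAD, end + METH_FLANK_PAD
    return [(off - start, p) for off, p in calls if lo <= off < hi]


def _flip_meth(
    calls: Optional[Sequence[MethCall]], read_len: int
) -> Optional[list[MethCall]]:
    """Re-coordinate CpG calls after reverse-complementing a read.

    A CpG's C at offset i pairs with a G at i+1; on the reverse complement
    the CpG's C sits at read_len - 2 - i.
    """
    if calls is None:
        return None
    return sorted((read_len - 2 - off, p) for off, p in calls)


def extract_region(
    read_seq: str,
    locus: RepeatLocus,
    max_flank_mismatch_frac: float = DEFAULT_MAX_FLANK_MISMATCH_FRAC,
    methylation_calls: Optional[Sequence[MethCall]] = None,
    read_id: str = "",
    orientation: str = "auto",
) -> Optional[ExtractedRegion]:
    """Locate the repeat region of ``read_seq`` at ``locus``.

    Tries the given orientation(s); for ``auto`` the forward read is tried
    first and the reverse complement wins only if it anchors a flank the
    forward read does not. Returns None for reads with neither flank nor any
    locus motif content (not evidence for this locus). Absence of flanks on a
    kept read is a value, not an error: the region is then bounded by the
    read's ends.
    """
    candidates = []
    if orientation in ("auto", "+"):
        candidates.append(("+", read_seq, methylation_calls))
    if orientation in ("auto", "-"):
        candidates.append(
            ("-", reverse_complement(read_seq), _flip_meth(methylation_calls, len(read_seq)))
        )

    best: Optional[ExtractedRegion] = None
    best_rank = -1
    for strand, seq, meth in candidates:
        left = find_flank(seq, locus.left_flank, max_flank_mismatch_frac)
        # the right flank must lie right of the left anchor when both exist
        search_from = left + len(locus.left_flank) if left is not None else 0
        right = find_flank(seq[search_from:], locus.right_flank, max_flank_mismatch_frac)
        if right is not None:
            right += search_from
        spans_left = left is not None
        spans_right = right is not None
        if not spans_left and not spans_right:
            if not _has_motif_content(seq, locus):
                continue
            region = ExtractedRegion(
                read_id=read_id,
                sequence=seq,
                spans_left=False,
                spans_right=False,
                methylation_calls=_slice_meth(meth, 0, len(seq)),
                strand=strand,
            )
            rank = 0
        else:
            start = left + len(locus.left_flank) if spans_left else 0
            end = right if spans_right else len(seq)
            if end < start:  # degenerate anchor placement
                continue
            region = ExtractedRegion(
                read_id=read_id,
                sequence=seq[start:end],
                spans_left=spans_left,
                spans_right=spans_right,
                methylation_calls=_slice_meth(meth, start, end),
                strand=strand,
            )
            rank = int(spans_left) + int(spans_right)
        if rank > best_rank:
            best, best_rank = region, rank
        if rank == 2:
            break
    return best


def _largest_gap_split(counts: list[int], min_gap_units: int, min_gap_frac: float):
    """Index after which to split sorted ``counts``, or None."""
    if len(counts) < 2:
        return None
    med = float(np.median(counts))
    gaps = [counts[i + 1] - counts[i] for i in range(len(counts) - 1)]
    gap = max(gaps)
    if gap > max(min_gap_units, min_gap_frac * med):
        return gaps.index(gap)
    return None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _allele_from_counts(
    members: list[tuple[int, str]], lower_bound_only: bool
) -> AlleleCall:
    counts = [c for c, _ in members]
    ids = [r for _, r in members]
    point = (
        max(counts) if lower_bound_only else _round_half_up(float(np.median(counts)))
    )
    return AlleleCall(
        unit_count_min=min(counts),
        unit_count_max=max(counts),
        point_estimate=point,
        lower_bound_only=lower_bound_only,
        supporting_reads=ids,
    )


def call_alleles(
    decompositions: Sequence[ReadDecomposition],
    locus: RepeatLocus,
    ploidy: int = 2,
    min_gap_units: int = DEFAULT_MIN_GAP_UNITS,
    min_gap_frac: float = DEFAULT_MIN_GAP_FRAC,
) -> Genotype:
    """Cluster per-read repeat counts into a genotype.

    Spanning reads carry exact counts (region length in units); their sorted
    counts are split into two alleles iff the largest adjacent gap exceeds
    ``max(min_gap_units, min_gap_frac * median)`` and ploidy is 2. Non-
    spanning reads carry lower bounds: with spanning support they are
    assigned to the largest compatible allele without inflating its range;
    with no spanning support at all the bounds themselves are clustered and
    reported as ">=" alleles (point estimate = the maximum lower bound). A
    lone cluster at ploidy 2 raises the homozygous-or-dropout flag.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    spanning = sorted(
        (
            (d.length_units(locus.unit_length), d.read_id)
            for d in decompositions
            if d.spanning
        ),
    )
    bounded = sorted(
        (
            (d.length_units(locus.unit_length), d.read_id)
            for d in decompositions
            if not d.spanning
        ),
    )
    if not spanning and not bounded:
        raise NoCallError(f"{locus.locus_id}: no usable reads")

    primary = spanning if spanning else bounded
    lower_bound_only = not spanning
    counts = [c for c, _ in primary]

    split = None
    if ploidy == 2:
        split = _largest_gap_split(counts, min_gap_units, min_gap_frac)

    if split is None:
        alleles = [_allele_from_counts(primary, lower_bound_only)]
    else:
        alleles = [
            _allele_from_counts(primary[: split + 1], lower_bound_only),
            _allele_from_counts(primary[split + 1 :], lower_bound_only),
        ]

    if spanning and bounded:
        # bounds support the largest allele whose max accommodates them,
        # falling back to the largest allele; ranges stay spanning-derived.
        for bound, rid in bounded:
            target = alleles[-1]
            for a in alleles:
                if a.unit_count_max >= bound:
                    target = a
                    break
            target.supporting_reads.append(rid)

    return Genotype(
        locus_id=locus.locus_id,
        alleles=alleles,
        ploidy=ploidy,
        homozygous_or_dropout=(ploidy == 2 and len(alleles) == 1),
    )


def _attach_composition_and_methylation(
    genotype: Genotype,
    decompositions: dict[str, ReadDecomposition],
    regions: dict[str, ExtractedRegion],
    probability_cutoff: float = 0.5,
) -> None:
    from .decompose import MotifSegment  # local to avoid cycle noise

    for allele in genotype.alleles:
        units: dict[str, int] = {}
        n_cpg = 0
        n_meth = 0
        any_calls = False
        for rid in allele.supporting_reads:
            d = decompositions.get(rid)
            if d is not None:
                for seg in d.segments:
                    if isinstance(seg, MotifSegment):
                        units[seg.motif] = units.get(seg.motif, 0) + seg.unit_count
            r = regions.get(rid)
            if r is not None and r.methylation_calls is not None:
                any_calls = True
                for _, p in r.methylation_calls:
                    n_cpg += 1
                    n_meth += int(p >= probability_cutoff)
        total = sum(units.values())
        if total:
            allele.composition = {m: c / total for m, c in sorted(units.items())}
        if any_calls and n_cpg:
            allele.methylated_fraction = n_meth / n_cpg


def genotype_sample(
    reads: Sequence[tuple[str, str] | tuple[str, str, Optional[list[MethCall]]]],
    locus: RepeatLocus,
    ploidy: int = 2,
    max_flank_mismatch_frac: float = DEFAULT_MAX_FLANK_MISMATCH_FRAC,
    interruption_penalty: float = DEFAULT_INTERRUPTION_PENALTY,
    switch_penalty: float = DEFAULT_SWITCH_PENALTY,
    min_gap_units: int = DEFAULT_MIN_GAP_UNITS,
    min_gap_frac: float = DEFAULT_MIN_GAP_FRAC,
) -> tuple[Genotype, list[ReadDecomposition], list[ExtractedRegion]]:
    """Extract -> decompose -> call, end to end for one sample at one locus.

    ``reads`` are ``(read_id, sequence)`` or ``(read_id, sequence,
    methylation_calls)`` tuples (read-orientation CpG calls). Deterministic
    for fixed inputs and parameters. Returns the genotype together with the
    retained per-read decompositions and extracted regions.
    """
    regions: list[ExtractedRegion] = []
    for item in reads:
        rid, seq = item[0], item[1]
        meth = item[2] if len(item) > 2 else None  # type: ignore[misc]
        region = extract_region(
            seq,
            locus,
            max_flank_mismatch_frac=max_flank_mismatch_frac,
            methylation_calls=meth,
            read_id=rid,
        )
        if region is not None:
            regions.append(region)
    decomps: list[ReadDecomposition] = []
    for region in regions:
        d = decompose(
            region.sequence,
            locus.all_motifs,
            interruption_penalty=interruption_penalty,
            switch_penalty=switch_penalty,
            read_id=region.read_id,
        )
        d.spans_left = region.spans_left
        d.spans_right = region.spans_right
        decomps.append(d)
    genotype = call_alleles(
        decomps,
        locus,
        ploidy=ploidy,
        min_gap_units=min_gap_units,
        min_gap_frac=min_gap_frac,
    )
    _attach_composition_and_methylation(
        genotype,
        {d.read_id: d for d in decomps},
        {r.read_id: r for r in regions},
    )
    return genotype, decomps, regions
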