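"""Repeat-region motif decomposition.

Segments a repeat-region DNA sequence into maximal runs of exactly matching
catalog motifs plus interruption stretches, the per-read structural annotation
behind calls like ``CTA×12 | CTG×84`` for a complex CTA/CTG locus or
``AAGGG×10 | AAAGG×2 | AAGGG×5`` for a mosaic pentanucleotide expansion.

The segmentation is a dynamic program over (position, last motif) that
minimizes

    interruption_penalty * (# interruption bases)
    + switch_penalty * (# motif changes)

where a motif unit is consumed only on an exact match; any base not covered by
a motif unit is an interruption base. Substituted bases inside a unit
therefore surface as short interruptions rather than fuzzy matches, keeping
mosaicism and composition metrics crisp. Ties are broken deterministically:
continue the current motif, else the lexicographically smallest motif, else an
interruption base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

__all__ = [
    "MotifSegment",
    "Interruption",
    "ReadDecomposition",
    "CompositionSummary",
    "decompose",
    "render_decomposition",
    "parse_rendering",
    "composition_summary",
    "build_sequence",
    "DEFAULT_INTERRUPTION_PENALTY",
    "DEFAULT_SWITCH_PENALTY",
]

#: Cost per interruption base. 1 per base with a switch cost of 2 keeps
#: spurious alternation between overlapping motifs (e.g. GAA/GGA) more
#: expensive than a short interruption while leaving genuine composite
#: alleles detectable.
DEFAULT_INTERRUPTION_PENALTY = 1.0
DEFAULT_SWITCH_PENALTY = 2.0

_ACGT = set("ACGT")


@dataclass(frozen=True)
class MotifSegment:
    """A maximal run of ``unit_count`` exact copies of ``motif``."""

    motif: str
    unit_count: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.unit_count < 1:
            raise ValueError("unit_count must be >= 1")
        if self.end - self.start != self.unit_count * len(self.motif):
            raise ValueError("segment span inconsistent with unit_count")


@dataclass(frozen=True)
class Interruption:
    """A stretch matching no catalog motif."""

    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty interruption")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length inconsistent with span")


Segment = Union[MotifSegment, Interruption]


@dataclass
class ReadDecomposition:
    """Ordered segments tiling one read's repeat region."""

    read_id: str
    segments: list[Segment]
    region_length: int
    spans_left: bool = False
    spans_right: bool = False

    @property
    def total_units(self) -> int:
        """Sum of exact-match motif units (interruption bases excluded)."""
        return sum(s.unit_count for s in self.segments if isinstance(s, MotifSegment))

    def length_units(self, unit_length: int) -> int:
        """Region length expressed in repeat units (interruptions included).

        This is the 'total expansion length' convention used for allele
        sizing: a substitution inside a unit does not shrink the allele.
        """
        return round(self.region_length / unit_length)

    @property
    def spanning(self) -> bool:
        return self.spans_left and self.spans_right

    def validate(self) -> None:
        """Assert the tiling and merge invariants."""
        pos = 0
        prev: Optional[Segment] = None
        for seg in self.segments:
            if seg.start != pos:
                raise AssertionError(f"segment gap/overlap at {pos}")
            pos = seg.end
            if prev is not None:
                if isinstance(prev, MotifSegment) and isinstance(seg, MotifSegment):
                    if prev.motif == seg.motif:
                        raise AssertionError("adjacent segments share a motif")
                if isinstance(prev, Interruption) and isinstance(seg, Interruption):
                    raise AssertionError("adjacent interruptions not merged")
            prev = seg
        if pos != self.region_length:
            raise AssertionError("segments do not tile the region")


def decompose(
    sequence: str,
    motifs: Sequence[str] | set[str] | frozenset[str],
    interruption_penalty: float = DEFAULT_INTERRUPTION_PENALTY,
    switch_penalty: float = DEFAULT_SWITCH_PENALTY,
    read_id: str = "",
) -> ReadDecomposition:
    """Minimum-cost segmentation of ``sequence`` over ``motifs``.

    Returns a :class:`ReadDecomposition` with spanning flags unset (they are
    the extractor's concern). Motifs are matched in the phase given — no
    rotation — so output reproduces left-anchored annotations
    deterministically.
    """
    motif_list = sorted(set(motifs))
    if not motif_list:
        raise ValueError("motifs must be non-empty")
    for m in motif_list:
        if not m or not set(m) <= _ACGT:
            raise ValueError(f"motif {m!r} not over ACGT")
    n = len(sequence)
    if n == 0:
        return ReadDecomposition(read_id=read_id, segments=[], region_length=0)
    bad = set(sequence) - _ACGT
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")

    m = len(motif_list)
    lens = [len(x) for x in motif_list]
    # match[k] is a bytearray: does motif k match at position i?
    match = [
        bytearray(sequence.startswith(motif_list[k], i) for i in range(n))
        for k in range(m)
    ]

    NONE = m  # 'no motif seen yet' state
    INF = float("inf")
    # cost[i][last]: minimal cost to decompose sequence[i:] given the most
    # recent motif (interruptions do not reset it). choice[i][last]: k for
    # consuming motif k, -1 for an interruption base.
    cost = [[INF] * (m + 1) for _ in range(n + 1)]
    choice = [[-2] * (m + 1) for _ in range(n + 1)]
    cost[n] = [0.0] * (m + 1)

    for i in range(n - 1, -1, -1):
        row_c = cost[i]
        row_ch = choice[i]
        for last in range(m + 1):
            # preference order: continue current motif, lex-smaller motifs,
            # interruption; strict improvement keeps the first preference.
            best = interruption_penalty + cost[i + 1][last]
            pick = -1
            order = ([last] if last != NONE else []) + [
                k for k in range(m) if k != last
            ]
            for k in order:
                if match[k][i]:
                    c = cost[i + lens[k]][k]
                    if last != NONE and k != last:
                        c += switch_penalty
                    if c < best:
                        best = c
                        pick = k
            # prefer a motif over an interruption on exact ties
            if pick == -1:
                for k in order:
                    if match[k][i]:
                        c = cost[i + lens[k]][k]
                        if last != NONE and k != last:
                            c += switch_penalty
                        if c == best:
                            best = c
                            pick = k
                            break
            row_c[last] = best
            row_ch[last] = pick

    # traceback
    segments: list[Segment] = []
    i, last = 0, NONE
    while i < n:
        k = choice[i][last]
        if k == -1:
            j = i
            while j < n and choice[j][last] == -1:
                j += 1
            segments.append(Interruption(start=i, end=j, sequence=sequence[i:j]))
            i = j
        else:
            motif, L = motif_list[k], lens[k]
            j = i
            count = 0
            while j < n and choice[j][last if count == 0 else k] == k:
                j += L
                count += 1
            segments.append(
                MotifSegment(motif=motif, unit_count=count, start=i, end=j)
            )
            i = j
            last = k

    d = ReadDecomposition(read_id=read_id, segments=segments, region_length=n)
    d.validate()
    return d


def decomposition_cost(
    d: ReadDecomposition,
    interruption_penalty: float = DEFAULT_INTERRUPTION_PENALTY,
    switch_penalty: float = DEFAULT_SWITCH_PENALTY,
) -> float:
    """Cost of a decomposition under the DP objective (used by tests)."""
    cost = 0.0
    last: Optional[str] = None
    for seg in d.segments:
        if isinstance(seg, Interruption):
            cost += interruption_penalty * (seg.end - seg.start)
        else:
            if last is not None and seg.motif != last:
                cost += switch_penalty
            last = seg.motif
    return cost


def render_decomposition(d: ReadDecomposition) -> str:
    """One-line text annotation, e.g. ``AAGGG×10 | [GTA] | AAGGG×5``."""
    parts = []
    for seg in d.segments:
        if isinstance(seg, MotifSegment):
            parts.append(f"{seg.motif}×{seg.unit_count}")
        else:
            parts.append(f"[{seg.sequence}]")
    return " | ".join(parts)


def parse_rendering(text: str, read_id: str = "") -> ReadDecomposition:
    """Inverse of :func:`render_decomposition` (round-trip checks)."""
    segments: list[Segment] = []
    pos = 0
    if text.strip():
        for token in text.split(" | "):
            token = token.strip()
            if token.startswith("["):
                seq = token[1:-1]
                segments.append(Interruption(start=pos, end=pos + len(seq), sequence=seq))
                pos += len(seq)
            else:
                motif, _, count = token.partition("×")
                n = int(count)
                segments.append(
                    MotifSegment(motif=motif, unit_count=n, start=pos, end=pos + n * len(motif))
                )
                pos += n * len(motif)
    return ReadDecomposition(read_id=read_id, segments=segments, region_length=pos)


def build_sequence(segments: Sequence[tuple[str, int] | str]) -> str:
    """Concatenate ``(motif, count)`` pairs (or literal strings) into DNA."""
    parts = []
    for seg in segments:
        if isinstance(seg, str):
            parts.append(seg)
        else:
            motif, count = seg
            parts.append(motif * count)
    return "".join(parts)


@dataclass
class CompositionSummary:
    """Per-motif unit fractions plus pathogenic-run and interruption counts."""

    unit_fractions: dict[str, float] = field(default_factory=dict)
    total_units: int = 0
    longest_pathogenic_run: int = 0
    interruption_count: int = 0

    def fraction(self, motifs: set[str] | frozenset[str]) -> float:
        return sum(f for m, f in self.unit_fractions.items() if m in motifs)


def composition_summary(
    d: ReadDecomposition,
    pathogenic_motifs: set[str] | frozenset[str] = frozenset(),
) -> CompositionSummary:
    """Summarize a decomposition's motif makeup.

    Fractions are over exact-match units and sum to 1 when any unit exists;
    with zero units the fraction table is empty (undefined). The longest
    pathogenic run is the maximal total unit count over consecutive
    motif segments whose motifs are all pathogenic.
    """
    units: dict[str, int] = {}
    run = 0
    longest = 0
    interruptions = 0
    for seg in d.segments:
        if isinstance(seg, Interruption):
            interruptions += 1
            run = 0
            continue
        units[seg.motif] = units.get(seg.motif, 0) + seg.unit_count
        if seg.motif in pathogenic_motifs:
            run += seg.unit_count
            longest = max(longest, run)
        else:
            run = 0
    total = sum(units.values())
    fractions = (
        {m: c / total for m, c in sorted(units.items())} if total > 0 else {}
    )
    return CompositionSummary(
        unit_fractions=fractions,
        total_units=total,
        longest_pathogenic_run=longest,
        interruption_count=interruptions,
    )
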