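"""Per-read CpG methylation summaries over repeat regions.

Long-read basecalling emits a 5mC probability for each CpG; here a CpG
counts as methylated when its probability reaches ``probability_cutoff``
(default 0.5). Summaries are per read and aggregate (weighted by CpG count),
and reads can be contrasted by repeat structure: at loci like FMR1, 5mC is
expected on expanded canonical repeats but absent from reads carrying long
interruption stretches — a pattern the association comparison flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .calling import ExtractedRegion
from .catalog import RepeatLocus
from .decompose import MotifSegment, ReadDecomposition

__all__ = [
    "ReadMethylation",
    "MethylationProfile",
    "GroupComparison",
    "methylation_summary",
    "associate_methylation_with_interruptions",
    "DEFAULT_PROBABILITY_CUTOFF",
    "DEFAULT_MIN_INTERRUPTION_RUN",
    "ASSOCIATION_FLAG_DIFFERENCE",
]

DEFAULT_PROBABILITY_CUTOFF = 0.5
#: Units of contiguous interruption motif needed to call a read 'interrupted'.
DEFAULT_MIN_INTERRUPTION_RUN = 5
#: Absolute between-group mean difference that raises the association flag.
ASSOCIATION_FLAG_DIFFERENCE = 0.5


@dataclass(frozen=True)
class ReadMethylation:
    n_cpg: int
    n_methylated: int

    @property
    def fraction(self) -> Optional[float]:
        """Methylated fraction; undefined (None) for CpG-free reads."""
        return self.n_methylated / self.n_cpg if self.n_cpg else None


@dataclass
class MethylationProfile:
    per_read: dict[str, ReadMethylation] = field(default_factory=dict)

    @property
    def aggregate_fraction(self) -> Optional[float]:
        """CpG-weighted mean: sum(methylated) / sum(CpG) over all reads."""
        n = sum(r.n_cpg for r in self.per_read.values())
        if n == 0:
            return None
        return sum(r.n_methylated for r in self.per_read.values()) / n


@dataclass
class GroupComparison:
    """Mean per-read methylated fraction, interrupted vs non-interrupted."""

    group_means: dict[str, Optional[float]]
    group_sizes: dict[str, int]
    flag: bool


def methylation_summary(
    regions: Sequence[ExtractedRegion],
    probability_cutoff: float = DEFAULT_PROBABILITY_CUTOFF,
) -> MethylationProfile:
    """Summarize CpG 5mC states per read and in aggregate.

    Regions without methylation calls contribute nothing (absence of calls is
    an undefined profile, not an error). At ``probability_cutoff=0`` every
    called CpG counts as methylated; at 1 only probability-1.0 calls do.
    """
    profile = MethylationProfile()
    for region in regions:
        if region.methylation_calls is None:
            continue
        n = len(region.methylation_calls)
        meth = sum(1 for _, p in region.methylation_calls if p >= probability_cutoff)
        prev = profile.per_read.get(region.read_id)
        if prev is not None:  # split records for one read accumulate
            n += prev.n_cpg
            meth += prev.n_methylated
        profile.per_read[region.read_id] = ReadMethylation(n_cpg=n, n_methylated=meth)
    return profile


def _is_interrupted(
    d: ReadDecomposition, interruption_motifs: frozenset[str], min_run: int
) -> bool:
    run = 0
    for seg in d.segments:
        if isinstance(seg, MotifSegment) and seg.motif in interruption_motifs:
            run += seg.unit_count
            if run >= min_run:
                return True
        else:
            run = 0
    return False


def associate_methylation_with_interruptions(
    profile: MethylationProfile,
    decompositions: dict[str, ReadDecomposition],
    locus: RepeatLocus,
    min_interruption_run: int = DEFAULT_MIN_INTERRUPTION_RUN,
) -> GroupComparison:
    """Contrast methylation between interrupted and non-interrupted reads.

    A read is 'interrupted' when its decomposition contains a contiguous run
    of >= ``min_interruption_run`` units of the locus's interruption motifs.
    Means are over per-read fractions (CpG-free reads excluded); a group with
    no reads has an undefined (None) mean. The flag is raised when both means
    are defined and differ by >= 0.5 in absolute value.
    """
    groups: dict[str, list[float]] = {"interrupted": [], "non_interrupted": []}
    sizes = {"interrupted": 0, "non_interrupted": 0}
    for rid, rm in profile.per_read.items():
        d = decompositions.get(rid)
        if d is None:
            continue
        key = (
            "interrupted"
            if _is_interrupted(d, locus.interruption_motifs, min_interruption_run)
            else "non_interrupted"
        )
        sizes[key] += 1
        if rm.fraction is not None:
            groups[key].append(rm.fraction)

    means: dict[str, Optional[float]] = {
        k: (sum(v) / len(v) if v else None) for k, v in groups.items()
    }
    a, b = means["interrupted"], means["non_interrupted"]
    flag = a is not None and b is not None and abs(a - b) >= ASSOCIATION_FLAG_DIFFERENCE
    return GroupComparison(group_means=means, group_sizes=sizes, flag=flag)
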