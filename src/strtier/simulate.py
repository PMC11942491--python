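"""Synthetic read generator for STR pipelines.

Stands in for patient sequencing data (which repeat-expansion studies cannot
share): given a locus and 1-2 allele specifications — ordered motif segments,
per-read length mosaicism, a CpG methylation state — it emits long reads
(lognormal lengths, optional truncation inside the repeat), or tiled 150 bp
short reads for the two-tier triage contrast, with configurable
substitution/indel error and a per-read truth table.

Read model: a read is a sequenced molecule. When the sampled molecule length
is at least the construct (flank + repeat + flank) the whole construct is
read and the read spans both flanks; shorter molecules fall uniformly within
the construct and may truncate inside the repeat, yielding the one-sided and
in-repeat reads typical of very long expansions. Length mosaicism is a
per-read integer jitter on the largest segment — matching expansions whose
somatic variability concentrates in the long run — and compositional
mosaicism is modeled by mixing allele specs. Methylation is emitted as crisp
per-CpG probabilities (0.95 methylated / 0.05 unmethylated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calling import MethCall, reverse_complement
from .catalog import RepeatCatalog, RepeatLocus
from .cohort import CaseRecord

__all__ = [
    "SyntheticAlleleSpec",
    "ReadLengthModel",
    "SyntheticSampleSpec",
    "SimulatedRead",
    "build_allele_sequence",
    "simulate_reads",
    "simulate_cohort",
    "METH_PROB_HIGH",
    "METH_PROB_LOW",
]

#: Emitted per-CpG probabilities for methylated / unmethylated states.
METH_PROB_HIGH = 0.95
METH_PROB_LOW = 0.05

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticAlleleSpec:
    """Generative description of one allele.

    ``segments`` are ordered (motif, unit_count) pairs; ``jitter`` is the
    half-width of a uniform integer count perturbation applied per read to
    the largest segment; ``methylation_state`` is the fraction of CpGs
    methylated on reads from this allele (None: no methylation emitted).
    """

    segments: tuple[tuple[str, int], ...]
    jitter: int = 0
    methylation_state: Optional[float] = None

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        for motif, count in self.segments:
            if count < 0:
                raise ValueError(f"negative unit count for {motif}")
        if self.methylation_state is not None and not (
            0.0 <= self.methylation_state <= 1.0
        ):
            raise ValueError("methylation_state must be in [0, 1]")

    @property
    def total_units(self) -> int:
        return sum(c for _, c in self.segments)


@dataclass(frozen=True)
class ReadLengthModel:
    """Long (lognormal, bp) or short (fixed-length tiled) reads."""

    kind: str = "long"  # "long" | "short"
    median_bp: float = 8000.0
    sigma: float = 0.5
    min_bp: int = 300
    short_bp: int = 150

    def __post_init__(self) -> None:
        if self.kind not in ("long", "short"):
            raise ValueError("kind must be 'long' or 'short'")


@dataclass(frozen=True)
class SyntheticSampleSpec:
    locus_id: str
    alleles: tuple[SyntheticAlleleSpec, ...]
    coverage: float = 20.0
    read_length_model: ReadLengthModel = field(default_factory=ReadLengthModel)
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0
    strand_flip: bool = True

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("1 or 2 alleles required")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must be in [0, 0.2]")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    allele_index: int
    true_units: int
    strand: str = "+"
    methylation_calls: Optional[list[MethCall]] = None

    def as_input(self):
        """Tuple accepted by :func:`strtier.calling.genotype_sample`."""
        return (self.read_id, self.sequence, self.methylation_calls)


def build_allele_sequence(spec: SyntheticAlleleSpec, locus: RepeatLocus) -> str:
    """Deterministic construct: left flank + motif segments + right flank."""
    body = "".join(motif * count for motif, count in spec.segments)
    return locus.left_flank + body + locus.right_flank


#: Genomic-context padding placed around short-read constructs so that flank
#: depth is measurable from tiled 150 bp reads.
SHORT_PAD_BP = 400


def _locus_padding(locus: RepeatLocus, n_bp: int = SHORT_PAD_BP) -> tuple[str, str]:
    """Deterministic per-locus padding free of locus motifs and flank k-mers."""
    import hashlib

    # forbid flank anchor k-mers and tandem motif runs (single motif copies
    # are unavoidable in 400 bp of random sequence and harmless)
    taboo = {m * 3 for m in locus.all_motifs}
    taboo |= {locus.left_flank[-8:], locus.right_flank[:8]}

    def make(side: str) -> str:
        h = hashlib.sha256(f"{locus.locus_id}-pad-{side}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(h[:4], "big"))
        while True:
            pad = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n_bp))
            if not any(t in pad for t in taboo):
                return pad

    return make("left"), make("right")


def _jittered_segments(
    spec: SyntheticAlleleSpec, rng: np.random.Generator
) -> tuple[tuple[str, int], ...]:
    if spec.jitter == 0 or not spec.segments:
        return spec.segments
    counts = [c for _, c in spec.segments]
    i = int(np.argmax(counts))
    delta = int(rng.integers(-spec.jitter, spec.jitter + 1))
    new = max(0, counts[i] + delta)
    return tuple(
        (m, new if k == i else c) for k, (m, c) in enumerate(spec.segments)
    )


def _apply_errors(
    seq: str,
    rng: np.random.Generator,
    sub: float,
    ins: float,
    dele: float,
) -> str:
    if sub == ins == dele == 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    if sub > 0:
        hits = np.nonzero(rng.random(n) < sub)[0]
        if hits.size:
            # substitute with one of the three other bases
            offsets = rng.integers(1, 4, size=hits.size)
            idx = np.searchsorted(_BASES, arr[hits])
            arr[hits] = _BASES[(idx + offsets) % 4]
    if ins == 0.0 and dele == 0.0:
        return arr.tobytes().decode()
    out = bytearray()
    u = rng.random(n)
    v = rng.random(n)
    for i in range(n):
        if u[i] < dele:
            continue
        out.append(arr[i])
        if v[i] < ins:
            out.append(_BASES[rng.integers(0, 4)])
    return out.decode()


def _meth_calls(
    seq: str, state: Optional[float], rng: np.random.Generator
) -> Optional[list[MethCall]]:
    if state is None:
        return None
    calls: list[MethCall] = []
    pos = seq.find("CG")
    while pos != -1:
        p = METH_PROB_HIGH if rng.random() < state else METH_PROB_LOW
        calls.append((pos, p))
        pos = seq.find("CG", pos + 1)
    return calls


def simulate_reads(
    spec: SyntheticSampleSpec, catalog: RepeatCatalog
) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Generate reads and a per-read truth table for one sample.

    Reproducible for a fixed spec (including seed). The truth table records
    each read's allele of origin, realized (jittered) unit count, placement
    in the construct, and strand.
    """
    locus = catalog[spec.locus_id]
    rng = np.random.default_rng(spec.seed)
    model = spec.read_length_model
    reads: list[SimulatedRead] = []
    truth_rows: list[dict] = []

    for ai, allele in enumerate(spec.alleles):
        if model.kind == "long":
            n_reads = max(1, int(rng.poisson(spec.coverage)))
        else:
            ref_len = len(build_allele_sequence(allele, locus)) + 2 * SHORT_PAD_BP
            n_reads = max(1, round(spec.coverage * ref_len / model.short_bp))
        pad_left, pad_right = (
            _locus_padding(locus) if model.kind == "short" else ("", "")
        )
        for ri in range(n_reads):
            segments = _jittered_segments(allele, rng)
            construct = (
                pad_left
                + locus.left_flank
                + "".join(m * c for m, c in segments)
                + locus.right_flank
                + pad_right
            )
            true_units = sum(c for _, c in segments)
            if model.kind == "long":
                length = int(
                    max(
                        model.min_bp,
                        round(
                            rng.lognormal(np.log(model.median_bp), model.sigma)
                        ),
                    )
                )
            else:
                length = model.short_bp
            if length >= len(construct):
                start, fragment = 0, construct
            else:
                start = int(rng.integers(0, len(construct) - length + 1))
                fragment = construct[start : start + length]
            fragment = _apply_errors(
                fragment,
                rng,
                spec.substitution_rate,
                spec.insertion_rate,
                spec.deletion_rate,
            )
            strand = "+"
            if spec.strand_flip and rng.random() < 0.5:
                strand = "-"
                fragment = reverse_complement(fragment)
            meth = _meth_calls(fragment, allele.methylation_state, rng)
            rid = f"{spec.locus_id}_a{ai}_r{ri}"
            reads.append(
                SimulatedRead(
                    read_id=rid,
                    sequence=fragment,
                    allele_index=ai,
                    true_units=true_units,
                    strand=strand,
                    methylation_calls=meth,
                )
            )
            truth_rows.append(
                {
                    "read_id": rid,
                    "allele_index": ai,
                    "true_units": true_units,
                    "construct_start": start,
                    "read_length": len(fragment),
                    "strand": strand,
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "allele_index",
            "true_units",
            "construct_start",
            "read_length",
            "strand",
        ],
    )
    return reads, truth


def simulate_cohort(
    counts: tuple[int, int, int, int, int], seed: int = 0
) -> list[CaseRecord]:
    """Synthesize case-disposition records for cohort summaries.

    ``counts`` = (STR without long read, STR with long read, other-variant
    without long read, other-variant with long read, negative). Exactly the
    requested number of records per cell, in seed-shuffled order.
    """
    n_str_no_lr, n_str_lr, n_other_no_lr, n_other_lr, n_negative = counts
    if min(counts) < 0:
        raise ValueError("counts must be >= 0")
    records: list[CaseRecord] = []
    cells = [
        (n_str_no_lr, frozenset({"STR"}), False),
        (n_str_lr, frozenset({"STR"}), True),
        (n_other_no_lr, frozenset({"other"}), False),
        (n_other_lr, frozenset({"other"}), True),
        (n_negative, frozenset(), False),
    ]
    i = 0
    for n, vtypes, lr in cells:
        for _ in range(n):
            records.append(
                CaseRecord(
                    case_id=f"case_{i:05d}",
                    has_reportable=bool(vtypes),
                    variant_types=vtypes,
                    required_long_read=lr,
                )
            )
            i += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[int(k)] for k in order]
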