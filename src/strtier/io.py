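"""Read/write helpers: FASTA, methylation sidecar TSV, unaligned BAM.

Simulated reads round-trip through three representations:

* FASTA (+ optional sidecar TSV ``read_id, offset, probability`` for CpG
  calls) — the plain-text path;
* unaligned BAM with standard base-modification tags (MM ``C+m?`` deltas and
  ML probabilities), readable by any modern tool chain.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from .calling import MethCall
from .simulate import SimulatedRead

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_meth_tsv",
    "read_meth_tsv",
    "write_unaligned_bam",
    "read_unaligned_bam",
    "per_read_table",
]


def write_fasta(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n")
            for i in range(0, len(r.sequence), 80):
                fh.write(r.sequence[i : i + 80] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_meth_tsv(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\toffset\tprobability\n")
        for r in reads:
            for off, p in r.methylation_calls or []:
                fh.write(f"{r.read_id}\t{off}\t{p}\n")


def read_meth_tsv(path: str | Path) -> dict[str, list[MethCall]]:
    calls: dict[str, list[MethCall]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError("expected header read_id/offset/probability")
        for line in fh:
            rid, off, p = line.rstrip("\n").split("\t")
            calls.setdefault(rid, []).append((int(off), float(p)))
    return calls


def _mm_ml_tags(seq: str, calls: Sequence[MethCall]) -> tuple[str, list[int]]:
    """Base-modification tags for 5mC calls at C positions of ``seq``."""
    c_positions = [i for i, b in enumerate(seq) if b == "C"]
    call_map = dict(calls)
    deltas: list[int] = []
    probs: list[int] = []
    skipped = 0
    for pos in c_positions:
        if pos in call_map:
            deltas.append(skipped)
            probs.append(min(255, int(call_map[pos] * 256)))
            skipped = 0
        else:
            skipped += 1
    mm = "C+m?," + ",".join(map(str, deltas)) + ";" if deltas else "C+m?;"
    return mm, probs


def write_unaligned_bam(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """Unaligned BAM with MM/ML CpG 5mC tags (binary; scratch output only)."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"}}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 4  # unmapped
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.sequence))
            if r.methylation_calls is not None:
                mm, ml = _mm_ml_tags(r.sequence, r.methylation_calls)
                a.set_tag("MM", mm)
                a.set_tag("ML", ml)
            bam.write(a)


def read_unaligned_bam(
    path: str | Path,
) -> list[tuple[str, str, Optional[list[MethCall]]]]:
    """Read (read_id, sequence, methylation_calls) from an unaligned BAM."""
    import pysam

    out: list[tuple[str, str, Optional[list[MethCall]]]] = []
    with pysam.AlignmentFile(str(path), "rb", check_sq=False) as bam:
        for a in bam.fetch(until_eof=True):
            calls: Optional[list[MethCall]] = None
            mods = a.modified_bases
            if mods:
                calls = []
                for (base, _strand, mod), entries in mods.items():
                    if base == "C" and mod == "m":
                        calls.extend((pos, (qual + 0.5) / 256) for pos, qual in entries)
                calls.sort()
            out.append((a.query_name, a.query_sequence, calls))
    return out


def per_read_table(decompositions, regions) -> "pd.DataFrame":  # noqa: F821
    """Per-read TSV payload: id, spanning flags, units, rendering."""
    import pandas as pd

    from .decompose import render_decomposition

    region_by_id = {r.read_id: r for r in regions}
    rows = []
    for d in decompositions:
        r = region_by_id.get(d.read_id)
        rows.append(
            {
                "read_id": d.read_id,
                "spans_left": d.spans_left,
                "spans_right": d.spans_right,
                "region_length": d.region_length,
                "total_units": d.total_units,
                "strand": r.strand if r else "",
                "rendering": render_decomposition(d),
            }
        )
    return pd.DataFrame(rows)
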