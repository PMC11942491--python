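"""STR locus catalog: data model, loader, and category partitioning.

A :class:`RepeatCatalog` holds one :class:`RepeatLocus` per disease-associated
short tandem repeat, carrying the clinically annotated repeat-count ranges
(normal, mutable normal, intermediate/uncertain, premutation, reduced
penetrance) and the full-penetrance threshold, together with the motif
vocabulary needed to decompose reads over the locus: the reference-strand
canonical motif, additional benign motifs, pathogenic motifs, motifs of
uncertain significance, and known interruption motifs.

The bundled fixture (``data/catalog.json``) encodes 29 loci commonly assayed
in movement-disorder and dementia diagnostics (AR, ATXN1..10, ATXN8OS,
C9ORF72, FGF14, FMR1, FXN, HTT, RFC1, ...). Coordinates are hg38, 0-based
half-open; flanks are fixed synthetic 30 bp anchors (the pipeline is exercised
on synthetic reads; real-flank substitution is a configuration choice).

:func:`category_bounds` normalizes a locus's printed ranges into a total,
gap-free, non-overlapping partition of the count axis [0, inf): printed gaps
become ``intermediate_uncertain``, printed overlaps are resolved by
most-severe-category precedence.
"""

from __future__ import annotations

import json
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

__all__ = [
    "Category",
    "SEVERITY",
    "Inheritance",
    "RepeatRange",
    "RepeatLocus",
    "RepeatCatalog",
    "CatalogError",
    "load_catalog",
    "write_catalog",
    "bundled_catalog_path",
    "load_bundled_catalog",
    "category_bounds",
    "category_at",
]

_DATA_DIR = Path(__file__).parent / "data"


class Category(str, Enum):
    """Clinical category of a repeat allele."""

    NORMAL = "normal"
    MUTABLE_NORMAL = "mutable_normal"
    INTERMEDIATE_UNCERTAIN = "intermediate_uncertain"
    PREMUTATION = "premutation"
    REDUCED_PENETRANCE = "reduced_penetrance"
    FULL_PENETRANCE = "full_penetrance"
    # assigned by the classifier when length says "expanded" but the motif
    # composition does not support pathogenicity; never part of a length
    # partition
    UNCERTAIN_COMPOSITION = "uncertain_composition"


#: Ordering used both for overlap precedence (most severe wins) and for the
#: classifier's monotonicity guarantees. ``uncertain_composition`` ranks with
#: intermediate/uncertain.
SEVERITY: dict[Category, int] = {
    Category.NORMAL: 0,
    Category.MUTABLE_NORMAL: 1,
    Category.INTERMEDIATE_UNCERTAIN: 2,
    Category.UNCERTAIN_COMPOSITION: 2,
    Category.PREMUTATION: 3,
    Category.REDUCED_PENETRANCE: 4,
    Category.FULL_PENETRANCE: 5,
}


class Inheritance(str, Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    X_LINKED = "x_linked"


_ACGT = set("ACGT")


class RepeatRange(BaseModel):
    """Inclusive repeat-unit count interval; ``hi=None`` means unbounded."""

    model_config = ConfigDict(frozen=True)

    lo: int
    hi: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "RepeatRange":
        if self.lo < 0:
            raise ValueError(f"lo must be >= 0, got {self.lo}")
        if self.hi is not None and self.hi < self.lo:
            raise ValueError(f"hi < lo ({self.hi} < {self.lo})")
        return self

    def contains(self, count: int) -> bool:
        return count >= self.lo and (self.hi is None or count <= self.hi)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.lo},{'inf' if self.hi is None else self.hi}]"


class RepeatLocus(BaseModel):
    """One catalogued STR locus with ranges, motifs, and flank anchors."""

    model_config = ConfigDict(frozen=True)

    locus_id: str
    chrom: str
    start: int
    end: int
    unit_length: int
    reference_motif: str
    benign_motifs: frozenset[str] = frozenset()
    pathogenic_motifs: frozenset[str] = frozenset()
    uncertain_motifs: frozenset[str] = frozenset()
    interruption_motifs: frozenset[str] = frozenset()
    normal: Optional[RepeatRange] = None
    mutable_normal: Optional[RepeatRange] = None
    intermediate: Optional[RepeatRange] = None
    premutation: Optional[RepeatRange] = None
    reduced_penetrance: Optional[RepeatRange] = None
    pathogenic_min: Optional[int] = None
    interrupted_normal: Optional[RepeatRange] = None
    interrupted_pathogenic_min: Optional[int] = None
    homozygous_pathogenic_count: Optional[int] = None
    inheritance: Inheritance = Inheritance.DOMINANT
    methylation_relevant: bool = False
    left_flank: str = ""
    right_flank: str = ""
    notes: str = ""

    @model_validator(mode="after")
    def _check(self) -> "RepeatLocus":
        errs: list[str] = []
        if self.unit_length != len(self.reference_motif):
            errs.append(
                f"unit_length {self.unit_length} != len(reference_motif "
                f"{self.reference_motif!r})"
            )
        if self.end < self.start:
            errs.append("end < start")
        sets = {
            "benign_motifs": self.benign_motifs,
            "pathogenic_motifs": self.pathogenic_motifs,
            "uncertain_motifs": self.uncertain_motifs,
            "interruption_motifs": self.interruption_motifs,
        }
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                common = sets[a] & sets[b]
                if common:
                    errs.append(f"{a} and {b} overlap: {sorted(common)}")
        for name, s in sets.items():
            for m in s:
                if not m or not set(m) <= _ACGT:
                    errs.append(f"{name} motif {m!r} not over ACGT")
        if self.reference_motif not in (self.benign_motifs | self.pathogenic_motifs):
            errs.append("reference_motif must be listed benign or pathogenic")
        if (
            self.pathogenic_min is not None
            and self.normal is not None
            and self.normal.hi is not None
            and self.pathogenic_min <= self.normal.hi
        ):
            errs.append(
                f"pathogenic_min {self.pathogenic_min} <= normal.hi {self.normal.hi}"
            )
        for side, flank in (("left_flank", self.left_flank), ("right_flank", self.right_flank)):
            if len(flank) < 30:
                errs.append(f"{side} shorter than 30 bp")
            if not set(flank) <= _ACGT:
                errs.append(f"{side} not over ACGT")
        if errs:
            raise ValueError("; ".join(errs))
        return self

    @property
    def all_motifs(self) -> frozenset[str]:
        """Full motif vocabulary used when decomposing reads at this locus."""
        return (
            frozenset({self.reference_motif})
            | self.benign_motifs
            | self.pathogenic_motifs
            | self.uncertain_motifs
            | self.interruption_motifs
        )

    @property
    def normal_ceiling(self) -> int:
        """Largest count resolvable as unambiguously normal-range.

        Loci whose Normal Range cell is blank (RFC1, FGF14, BEAN1) get 0:
        with no annotated normal range any repeat content is treated as
        potentially reportable by the short-read triage rules.
        """
        if self.normal is not None and self.normal.hi is not None:
            return self.normal.hi
        return 0


class CatalogError(ValueError):
    """Raised on schema violations; message enumerates every violation."""


class RepeatCatalog(BaseModel):
    model_config = ConfigDict(frozen=True)

    loci: dict[str, RepeatLocus]

    @model_validator(mode="after")
    def _check(self) -> "RepeatCatalog":
        bad = [k for k, v in self.loci.items() if k != v.locus_id]
        if bad:
            raise ValueError(f"locus_id key mismatch for {bad}")
        return self

    def __iter__(self) -> Iterator[RepeatLocus]:  # type: ignore[override]
        return iter(self.loci.values())

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, locus_id: str) -> RepeatLocus:
        return self.loci[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.loci

    def to_bed(self) -> str:
        """BED4 text (chrom, start, end, locus_id), catalog order."""
        lines = [
            f"{l.chrom}\t{l.start}\t{l.end}\t{l.locus_id}" for l in self
        ]
        return "\n".join(lines) + "\n"

    def ranges_table(self) -> "pd.DataFrame":  # noqa: F821 - lazy import
        """Side-table of the per-locus ranges as a tidy DataFrame."""
        import pandas as pd

        def fmt(r: Optional[RepeatRange]) -> str:
            if r is None:
                return ""
            return f"{r.lo}-{'' if r.hi is None else r.hi}"

        rows = []
        for l in self:
            rows.append(
                {
                    "locus_id": l.locus_id,
                    "normal": fmt(l.normal),
                    "mutable_normal": fmt(l.mutable_normal),
                    "intermediate": fmt(l.intermediate),
                    "premutation": fmt(l.premutation),
                    "reduced_penetrance": fmt(l.reduced_penetrance),
                    "pathogenic_min": "" if l.pathogenic_min is None else l.pathogenic_min,
                    "unit_length": l.unit_length,
                    "inheritance": l.inheritance.value,
                }
            )
        return pd.DataFrame(rows)


def _format_pydantic_error(locus_id: str, err: ValidationError | ValueError) -> list[str]:
    if isinstance(err, ValidationError):
        out = []
        for e in err.errors():
            loc = ".".join(str(x) for x in e["loc"]) or "<locus>"
            out.append(f"{locus_id}: {loc}: {e['msg']}")
        return out
    return [f"{locus_id}: {err}"]


def load_catalog(path: str | Path) -> RepeatCatalog:
    """Load and validate a JSON locus catalog.

    The file holds ``{"loci": [ {locus object}, ... ]}`` (a bare list is also
    accepted). Validation does not stop at the first problem: every violation
    across all loci is collected and reported in one :class:`CatalogError`
    naming the locus and field.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    entries = raw["loci"] if isinstance(raw, dict) else raw
    loci: dict[str, RepeatLocus] = {}
    problems: list[str] = []
    for entry in entries:
        lid = entry.get("locus_id", "<missing locus_id>")
        try:
            locus = RepeatLocus.model_validate(entry)
        except (ValidationError, ValueError) as err:
            problems.extend(_format_pydantic_error(lid, err))
            continue
        if locus.locus_id in loci:
            problems.append(f"{lid}: duplicate locus_id")
        loci[locus.locus_id] = locus
    if problems:
        raise CatalogError(
            f"{path.name}: {len(problems)} violation(s):\n  " + "\n  ".join(problems)
        )
    return RepeatCatalog(loci=loci)


def write_catalog(catalog: RepeatCatalog, path: str | Path) -> None:
    """Write a catalog back to the documented JSON schema."""
    entries = []
    for locus in catalog:
        d = locus.model_dump(mode="json", exclude_none=True, exclude_defaults=True)
        # frozensets serialize in arbitrary order; keep files diff-stable
        for key in (
            "benign_motifs",
            "pathogenic_motifs",
            "uncertain_motifs",
            "interruption_motifs",
        ):
            if key in d:
                d[key] = sorted(d[key])
        entries.append(d)
    Path(path).write_text(json.dumps({"loci": entries}, indent=1) + "\n")


def bundled_catalog_path() -> Path:
    return _DATA_DIR / "catalog.json"


def load_bundled_catalog() -> RepeatCatalog:
    """The 29-locus catalog fixture shipped with the package."""
    return load_catalog(bundled_catalog_path())


# keyed by id(); the strong reference to the locus keeps ids from being reused
_BOUNDS_CACHE: dict[int, tuple[RepeatLocus, list[tuple[Category, RepeatRange]]]] = {}


def category_bounds(locus: RepeatLocus) -> list[tuple[Category, RepeatRange]]:
    """Normalize a locus's ranges into a total partition of [0, inf).

    Returns ordered ``(category, range)`` pairs covering every non-negative
    count exactly once. Counts not claimed by any printed range are
    ``intermediate_uncertain``; where printed ranges overlap, the most severe
    category wins (e.g. C9ORF72's printed intermediate 25-60 vs reduced
    penetrance 24-60). The final interval is unbounded.
    """
    cached = _BOUNDS_CACHE.get(id(locus))
    if cached is not None and cached[0] is locus:
        return cached[1]
    candidates: list[tuple[Category, int, Optional[int]]] = []

    def add(cat: Category, rng: Optional[RepeatRange]) -> None:
        if rng is not None:
            candidates.append((cat, rng.lo, rng.hi))

    add(Category.NORMAL, locus.normal)
    add(Category.MUTABLE_NORMAL, locus.mutable_normal)
    add(Category.INTERMEDIATE_UNCERTAIN, locus.intermediate)
    add(Category.PREMUTATION, locus.premutation)
    add(Category.REDUCED_PENETRANCE, locus.reduced_penetrance)
    if locus.pathogenic_min is not None:
        candidates.append((Category.FULL_PENETRANCE, locus.pathogenic_min, None))

    points = {0}
    for _, lo, hi in candidates:
        points.add(lo)
        if hi is not None:
            points.add(hi + 1)
    cuts = sorted(points)

    def category_of(count: int) -> Category:
        best: Optional[Category] = None
        for cat, lo, hi in candidates:
            if count >= lo and (hi is None or count <= hi):
                if best is None or SEVERITY[cat] > SEVERITY[best]:
                    best = cat
        return best if best is not None else Category.INTERMEDIATE_UNCERTAIN

    raw: list[tuple[Category, int, Optional[int]]] = []
    for i, lo in enumerate(cuts):
        hi = cuts[i + 1] - 1 if i + 1 < len(cuts) else None
        raw.append((category_of(lo), lo, hi))

    merged: list[tuple[Category, int, Optional[int]]] = []
    for cat, lo, hi in raw:
        if merged and merged[-1][0] == cat:
            pcat, plo, _ = merged[-1]
            merged[-1] = (pcat, plo, hi)
        else:
            merged.append((cat, lo, hi))
    result = [(cat, RepeatRange(lo=lo, hi=hi)) for cat, lo, hi in merged]
    _BOUNDS_CACHE[id(locus)] = (locus, result)
    return result


def category_at(locus: RepeatLocus, count: int) -> Category:
    """Length-only category of a repeat-unit count at this locus."""
    if count < 0:
        raise ValueError("count must be >= 0")
    for cat, rng in category_bounds(locus):
        if rng.contains(count):
            return cat
    raise AssertionError("category_bounds no longer total")  # pragma: no cover
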