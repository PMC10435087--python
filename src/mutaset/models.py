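"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
All intervals are stored internally as 0-based half-open ``[start, end)``.
GTF input is 1-based inclusive and VCF/TSV mutation positions are 1-based;
the readers in :mod:`mutaset.io` perform the mapping.  The one deliberate
exception is :attr:`GeneModel.gene_length`, which is computed as
``end - start`` on the *original 1-based inclusive* GTF coordinates (one
nucleotide less than the inclusive span); this matches how the covariate is
defined in the burden analysis and is kept consistent everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class MutationRecord:
    """A single-nucleotide substitution in one subclone.

    ``pos`` is 1-based.  ``ref_allele`` and ``alt_allele`` must be single,
    distinct, unambiguous bases: only substitutions are modelled.
    """

    subclone_id: str
    exposure_class: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    chemical: str | None = None

    def __post_init__(self) -> None:
        if self.ref_allele not in NUCLEOTIDES:
            raise ValueError(f"ref allele {self.ref_allele!r} is not one of A/C/G/T")
        if self.alt_allele not in NUCLEOTIDES:
            raise ValueError(f"alt allele {self.alt_allele!r} is not one of A/C/G/T")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (got {self.pos})")


@dataclass
class GeneModel:
    """A gene with merged CDS intervals and sequence covariates.

    ``start``/``end`` are 0-based half-open; ``cds_intervals`` are disjoint,
    sorted, 0-based half-open and contained in ``[start, end)``.
    ``gene_length`` is GTF ``end - start`` (see module docstring);
    ``cds_length`` is the summed width of the merged CDS intervals.
    ``gene_gc``/``cds_gc`` are fractions in [0, 1] (``None`` when the
    sequence is entirely ambiguous); ``expression`` is RPKM or ``None``
    when the gene is absent from the expression table.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    gene_gc: float | None = None
    cds_gc: float | None = None
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for s, e in self.cds_intervals:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"{self.gene_id}: CDS interval [{s},{e}) outside gene span"
                )

    @property
    def gene_length(self) -> int:
        # end - start on the original 1-based inclusive coordinates equals
        # the half-open width minus one.
        return (self.end - self.start) - 1

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


@dataclass(frozen=True)
class GeneSet:
    """A named disease gene set (duplicates collapsed, never empty)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name, symbols) -> "GeneSet":
        return cls(name=name, members=frozenset(symbols))

    def __len__(self) -> int:
        return len(self.members)


class SubcloneManifest:
    """Maps subclone id -> (exposure class, chemical)."""

    def __init__(self, entries: dict[str, tuple[str, str | None]]):
        if not entries:
            raise ValueError("manifest has no subclones")
        self._entries = dict(entries)

    @classmethod
    def from_records(cls, rows) -> "SubcloneManifest":
        """Build from an iterable of (subclone_id, exposure_class[, chemical])."""
        entries = {}
        for row in rows:
            sid, cls_, *rest = row
            entries[str(sid)] = (str(cls_), rest[0] if rest else None)
        return cls(entries)

    def __contains__(self, subclone_id: str) -> bool:
        return subclone_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def subclones(self) -> list[str]:
        return list(self._entries)

    @property
    def classes(self) -> list[str]:
        seen = []
        for cls_, _ in self._entries.values():
            if cls_ not in seen:
                seen.append(cls_)
        return seen

    def exposure_class(self, subclone_id: str) -> str:
        return self._entries[subclone_id][0]

    def chemical(self, subclone_id: str) -> str | None:
        return self._entries[subclone_id][1]

    def subclones_of(self, exposure_class: str) -> list[str]:
        return [s for s, (c, _) in self._entries.items() if c == exposure_class]

    def n_subclones(self, exposure_class: str) -> int:
        n = len(self.subclones_of(exposure_class))
        if n == 0:
            raise ValueError(f"no subclones in exposure class {exposure_class!r}")
        return n


@dataclass
class SignalTrack:
    """A sorted, non-overlapping coverage track (0-based half-open).

    ``intervals`` maps chromosome -> (starts, ends, values) arrays sorted by
    start; values are non-negative depth-normalised counts.
    """

    intervals: dict[str, tuple["object", "object", "object"]]

    def chroms(self) -> list[str]:
        return list(self.intervals)

    def __len__(self) -> int:
        return sum(len(s) for s, _, _ in self.intervals.values())
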