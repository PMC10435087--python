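"""Readers, writers and mutation-to-gene assignment.

Input formats are the field's plain-text standards: TSV mutation tables or
VCF, GTF gene annotation, FASTA genome, one-symbol-per-line gene sets, a
two-column RPKM expression table, and 4-column bedGraph signal tracks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .models import NUCLEOTIDES, GeneModel, GeneSet, MutationRecord, SubcloneManifest

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ["subclone_id", "exposure_class", "chemical", "chrom", "pos", "ref", "alt"]


@dataclass
class LoadReport:
    """Bookkeeping for a mutation-catalog load."""

    n_loaded: int = 0
    n_skipped_non_snv: int = 0
    n_rejected_unknown_subclone: int = 0


def read_mutation_table(
    path, manifest: SubcloneManifest, report: LoadReport | None = None
) -> list[MutationRecord]:
    """Load a substitution catalog from TSV or VCF.

    TSV requires columns subclone_id, chrom, pos, ref, alt (exposure_class
    and chemical are taken from the manifest).  Indels/MNVs are skipped with
    a warning count; rows naming subclones absent from the manifest are
    rejected and counted.  Malformed rows raise with the line number.
    """
    path = Path(path)
    if report is None:
        report = LoadReport()
    if path.suffix.lower() in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        records = _read_vcf(path, manifest, report)
    else:
        records = _read_tsv(path, manifest, report)
    if report.n_skipped_non_snv:
        warnings.warn(
            f"{report.n_skipped_non_snv} non-SNV rows skipped in {path.name}",
            stacklevel=2,
        )
    if report.n_rejected_unknown_subclone:
        warnings.warn(
            f"{report.n_rejected_unknown_subclone} rows with subclones missing "
            f"from the manifest rejected in {path.name}",
            stacklevel=2,
        )
    report.n_loaded = len(records)
    return records


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in NUCLEOTIDES and alt in NUCLEOTIDES and ref != alt


def _read_tsv(path: Path, manifest: SubcloneManifest, report: LoadReport) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"subclone_id", "chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if not _is_snv(ref, alt):
            report.n_skipped_non_snv += 1
            continue
        sid = str(row.subclone_id)
        if sid not in manifest:
            report.n_rejected_unknown_subclone += 1
            continue
        try:
            pos = int(row.pos)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {i}: bad position {row.pos!r}") from exc
        try:
            records.append(
                MutationRecord(
                    subclone_id=sid,
                    exposure_class=manifest.exposure_class(sid),
                    chemical=manifest.chemical(sid),
                    chrom=str(row.chrom),
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return records


def _read_vcf(path: Path, manifest: SubcloneManifest, report: LoadReport) -> list[MutationRecord]:
    """Multi-sample VCF: sample columns are subclone ids; a record counts for
    every sample carrying a non-reference genotype."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            for alt in rec.alts or ():
                if not _is_snv(rec.ref.upper(), alt.upper()):
                    report.n_skipped_non_snv += 1
                    continue
                for sid in samples:
                    gt = rec.samples[sid].get("GT")
                    if gt is None or not any(a not in (0, None) for a in gt):
                        continue
                    if sid not in manifest:
                        report.n_rejected_unknown_subclone += 1
                        continue
                    records.append(
                        MutationRecord(
                            subclone_id=sid,
                            exposure_class=manifest.exposure_class(sid),
                            chemical=manifest.chemical(sid),
                            chrom=str(rec.chrom),
                            pos=int(rec.pos),
                            ref_allele=rec.ref.upper(),
                            alt_allele=alt.upper(),
                        )
                    )
    return records


def write_mutation_table(records, path) -> None:
    """Write records to the canonical TSV layout (round-trips exactly)."""
    df = pd.DataFrame(
        [
            {
                "subclone_id": r.subclone_id,
                "exposure_class": r.exposure_class,
                "chemical": r.chemical if r.chemical is not None else "",
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref_allele,
                "alt": r.alt_allele,
            }
            for r in records
        ],
        columns=MUTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> SubcloneManifest:
    """TSV with columns subclone_id, exposure_class[, chemical]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows = []
    for row in df.itertuples(index=False):
        chem = getattr(row, "chemical", None)
        if chem is not None and (pd.isna(chem) or chem == ""):
            chem = None
        rows.append((row.subclone_id, row.exposure_class, chem))
    return SubcloneManifest.from_records(rows)


def write_manifest(manifest: SubcloneManifest, path) -> None:
    df = pd.DataFrame(
        [
            {
                "subclone_id": s,
                "exposure_class": manifest.exposure_class(s),
                "chemical": manifest.chemical(s) or "",
            }
            for s in manifest.subclones
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def compute_gc(sequence: str) -> float | None:
    """GC fraction: (#G + #C) / (#A + #C + #G + #T).

    Ambiguous bases (N and IUPAC codes) are excluded from both numerator and
    denominator; an all-ambiguous sequence has undefined GC and returns None.
    """
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_gene_models(
    gtf_path, genome_path=None, expression_path=None
) -> list[GeneModel]:
    """Parse a GTF into one GeneModel per gene.

    CDS intervals of all transcripts of a gene are merged (union).  GC
    content is computed from the genome when provided; expression is joined
    by symbol (case-sensitive exact match) from a (symbol, rpkm) TSV.
    A gene whose CDS extends outside its span, or a gene on a chromosome
    missing from the FASTA, is a hard error.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    expr = None
    if expression_path is not None:
        etab = pd.read_csv(expression_path, sep="\t")
        expr = dict(zip(etab.iloc[:, 0].astype(str), etab.iloc[:, 1].astype(float)))

    fasta = Fasta(str(genome_path)) if genome_path is not None else None

    cds_by_gene: dict[str, list[tuple[int, int]]] = {}
    for cds in db.features_of_type("CDS"):
        gid = cds.attributes["gene_id"][0]
        cds_by_gene.setdefault(gid, []).append((cds.start - 1, cds.end))

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gid = g.attributes["gene_id"][0]
        symbol = g.attributes.get("gene_name", [gid])[0]
        start0, end0 = g.start - 1, g.end
        merged = merge_intervals(cds_by_gene.get(gid, []))
        for s, e in merged:
            if not (start0 <= s < e <= end0):
                raise ValueError(f"gene {gid}: CDS [{s},{e}) outside gene span")
        gene_gc = cds_gc = None
        if fasta is not None:
            if g.seqid not in fasta:
                raise ValueError(f"gene {gid}: chromosome {g.seqid!r} not in FASTA")
            seq = str(fasta[g.seqid][start0:end0])
            gene_gc = compute_gc(seq)
            if merged:
                cds_seq = "".join(str(fasta[g.seqid][s:e]) for s, e in merged)
                cds_gc = compute_gc(cds_seq)
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=symbol,
                chrom=g.seqid,
                strand=g.strand if g.strand in "+-" else "+",
                start=start0,
                end=end0,
                cds_intervals=merged,
                gene_gc=gene_gc,
                cds_gc=cds_gc,
                expression=expr.get(symbol) if expr is not None else None,
            )
        )
    return genes


def gene_table(genes) -> pd.DataFrame:
    """Flatten GeneModels into a covariate DataFrame (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "symbol": [g.symbol for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "gene_length": [g.gene_length for g in genes],
            "cds_length": [g.cds_length for g in genes],
            "gene_gc": [g.gene_gc for g in genes],
            "cds_gc": [g.cds_gc for g in genes],
            "expression": [g.expression for g in genes],
        }
    )


def read_gene_sets(directory) -> list[GeneSet]:
    """Each *.txt file in `directory` is one set: one symbol per line, file
    stem is the set name."""
    sets = []
    for p in sorted(Path(directory).glob("*.txt")):
        symbols = [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]
        sets.append(GeneSet.from_iterable(p.stem, symbols))
    return sets


@dataclass
class AssignmentResult:
    """Per-(subclone, gene) mutation counts at gene and CDS level.

    ``counts`` holds only non-zero rows (columns: subclone_id, gene_id,
    n_gene, n_cds); intergenic mutations are tallied per subclone in
    ``unassigned``.
    """

    counts: pd.DataFrame
    unassigned: dict[str, int] = field(default_factory=dict)

    @property
    def n_gene_total(self) -> int:
        return int(self.counts["n_gene"].sum())

    @property
    def n_cds_total(self) -> int:
        return int(self.counts["n_cds"].sum())

    def class_gene_totals(
        self, manifest: SubcloneManifest, exposure_class: str, genes, level: str = "gene"
    ) -> pd.Series:
        """Total mutations per gene across the class's subclones, indexed by
        gene_id over the full gene universe (zeros included)."""
        col = {"gene": "n_gene", "cds": "n_cds"}[level]
        subclones = set(manifest.subclones_of(exposure_class))
        sub = self.counts[self.counts["subclone_id"].isin(subclones)]
        totals = sub.groupby("gene_id")[col].sum()
        index = pd.Index([g.gene_id for g in genes], name="gene_id")
        return totals.reindex(index, fill_value=0).astype(int)


def assign_mutations(records, genes) -> AssignmentResult:
    """Assign each substitution to every overlapping gene (and, at CDS level,
    to genes whose merged CDS contains it).

    A mutation at 1-based position p falls in a gene when the gene's
    half-open span contains p-1; overlapping genes each receive the count
    and single genes may accumulate multiple mutations.  Intergenic
    mutations land in the per-subclone unassigned bucket.
    """
    trees: dict[str, IntervalTree] = {}
    cds_trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
        for s, e in g.cds_intervals:
            cds_trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)

    gene_counts: dict[tuple[str, str], int] = {}
    cds_counts: dict[tuple[str, str], int] = {}
    unassigned: dict[str, int] = {}
    for r in records:
        p0 = r.pos - 1
        hits = trees.get(r.chrom, IntervalTree())[p0]
        if not hits:
            unassigned[r.subclone_id] = unassigned.get(r.subclone_id, 0) + 1
            continue
        for iv in hits:
            gene_counts[(r.subclone_id, iv.data)] = (
                gene_counts.get((r.subclone_id, iv.data), 0) + 1
            )
        for iv in cds_trees.get(r.chrom, IntervalTree())[p0]:
            cds_counts[(r.subclone_id, iv.data)] = (
                cds_counts.get((r.subclone_id, iv.data), 0) + 1
            )

    keys = sorted(set(gene_counts) | set(cds_counts))
    counts = pd.DataFrame(
        {
            "subclone_id": [k[0] for k in keys],
            "gene_id": [k[1] for k in keys],
            "n_gene": [gene_counts.get(k, 0) for k in keys],
            "n_cds": [cds_counts.get(k, 0) for k in keys],
        }
    )
    return AssignmentResult(counts=counts, unassigned=unassigned)


def read_bedgraph(path):
    """Read a 4-column bedGraph into a validated SignalTrack.

    Intervals are sorted per chromosome; overlap or negative values are hard
    errors.
    """
    from .models import SignalTrack

    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    if (df["value"] < 0).any():
        raise ValueError(f"{path}: negative signal values")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: zero- or negative-width intervals")
    intervals = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"{path}: overlapping intervals on {chrom}")
        intervals[chrom] = (starts, ends, grp["value"].to_numpy(dtype=float))
    return SignalTrack(intervals=intervals)
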