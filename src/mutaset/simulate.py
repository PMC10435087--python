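"""Synthetic study generator: toy genome, annotation, subclones, mutation
catalogs, expression, and damage tracks with known ground truth.

The generator emulates the minimal statistical structure the analyses
assume: non-overlapping genes whose per-gene, per-subclone substitution
rate is log-linear in length, GC fraction and expression; exposure classes
that scale that rate multiplicatively; disease sets whose member genes
carry an extra multiplicative excess delta; and a per-gene-constant damage
signal with set-specific means.  Defaults are desk-scale (4 chromosomes of
1 Mb, 400 genes, 3 exposure classes of 10 subclones each, base rates near
0.05 mutations per gene per subclone — the order of magnitude seen for
strong mutagen classes) so the whole pipeline runs in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import NUCLEOTIDES, GeneModel, GeneSet, MutationRecord, SubcloneManifest

_BASES = np.array(list(NUCLEOTIDES))


@dataclass
class ExposureClassConfig:
    name: str
    n_subclones: int = 10
    multiplier: float = 1.0  # class-level rate scale


@dataclass
class SetConfig:
    name: str
    size: int = 40
    enrichment: float = 1.0  # delta: extra rate multiplier for member genes
    length_biased: bool = False  # sample members with weight ~ gene length
    damage_mean: float | None = None  # per-gene damage-signal mean


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 1_000_000
    background_gc: float = 0.5
    n_genes: int = 400
    # gene lengths ~ LogNormal(meanlog, sdlog), floored at min_gene_length
    length_meanlog: float = math.log(3000.0)
    length_sdlog: float = 0.6
    min_gene_length: int = 300
    # per-gene GC fraction ~ Beta(a, b)
    gc_beta_a: float = 6.0
    gc_beta_b: float = 6.0
    # expression (RPKM) ~ LogNormal
    expression_meanlog: float = 1.0
    expression_sdlog: float = 1.0
    # log-linear rate model: lambda = mult * delta * exp(b0 + bl*len + bgc*gc + be*expr)
    beta0: float = -3.5
    beta_length: float = 1e-4
    beta_gc: float = 0.5
    beta_expression: float = 0.002
    overdispersion: float | None = None  # negative-binomial size; None = Poisson
    classes: list[ExposureClassConfig] = field(
        default_factory=lambda: [
            ExposureClassConfig("radiation", 10, 1.5),
            ExposureClassConfig("PAH", 10, 1.2),
            ExposureClassConfig("aromatic_amines", 10, 1.0),
        ]
    )
    sets: list[SetConfig] = field(
        default_factory=lambda: [
            SetConfig("NDD_like", size=40, enrichment=2.0, length_biased=True, damage_mean=1.5),
            SetConfig("control_like", size=40, enrichment=1.0, damage_mean=1.0),
        ]
    )
    damage_background_mean: float = 1.0
    damage_noise_sd: float = 0.3


@dataclass
class SimulationTruth:
    """Ground truth of one realisation, for parameter-recovery checks."""

    betas: dict[str, float]
    class_multipliers: dict[str, float]
    set_enrichments: dict[str, float]
    rates: pd.DataFrame  # gene_id x class: lambda per gene per subclone
    seed: int


def generate_genome(config: SimulationConfig, rng=None) -> dict[str, np.ndarray]:
    """Per-chromosome base arrays with the configured background GC."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    gc = config.background_gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"chr{i + 1}": rng.choice(_BASES, size=config.chrom_length, p=p)
        for i in range(config.n_chromosomes)
    }


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def generate_annotation(
    config: SimulationConfig, genome: dict[str, np.ndarray], rng
) -> tuple[list[GeneModel], list[GeneSet], pd.DataFrame]:
    """Place non-overlapping genes, write per-gene-GC sequence into the
    genome, pick 1-3 CDS sub-intervals per gene, and draw disease sets
    (optionally length-biased) and an expression table."""
    chroms = list(genome)
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        clen = len(genome[chrom])
        lengths = np.maximum(
            rng.lognormal(config.length_meanlog, config.length_sdlog, n_here),
            config.min_gene_length,
        ).astype(int)
        total = lengths.sum()
        slack = clen - total - 2 * n_here  # at least 2 nt between genes
        if slack < 0:
            raise ValueError(
                f"chromosome of {clen} nt cannot hold {n_here} genes "
                f"totalling {total} nt; increase chrom_length or shrink genes"
            )
        # random gaps summing to <= slack (Dirichlet-ish via sorted uniforms)
        cuts = np.sort(rng.integers(0, slack + 1, size=n_here))
        gaps = np.diff(np.concatenate([[0], cuts])) + 2
        cursor = 0
        for L, gap in zip(lengths, gaps):
            start = cursor + int(gap)
            end = start + int(L)
            cursor = end
            gid += 1
            gc = float(rng.beta(config.gc_beta_a, config.gc_beta_b))
            genome[chrom][start:end] = _random_sequence(rng, int(L), gc)
            seq = genome[chrom][start:end]
            realized_gc = float(np.isin(seq, ["G", "C"]).mean())
            n_cds = int(rng.integers(1, 4))
            bounds = np.linspace(start, end, n_cds + 1).astype(int)
            cds = []
            for k in range(n_cds):
                seg_s, seg_e = int(bounds[k]), int(bounds[k + 1])
                width = max((seg_e - seg_s) // 4, 10)
                width = min(width, seg_e - seg_s - 2)
                if width <= 0:
                    continue
                s = int(rng.integers(seg_s, seg_e - width))
                cds.append((s, s + width))
            cds_seq = np.concatenate([genome[chrom][s:e] for s, e in cds]) if cds else None
            symbol = f"G{gid:04d}"
            genes.append(
                GeneModel(
                    gene_id=f"GENE{gid:04d}",
                    symbol=symbol,
                    chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    start=start,
                    end=end,
                    cds_intervals=cds,
                    gene_gc=realized_gc,
                    cds_gc=float(np.isin(cds_seq, ["G", "C"]).mean()) if cds_seq is not None else None,
                )
            )

    expression = rng.lognormal(
        config.expression_meanlog, config.expression_sdlog, len(genes)
    )
    for g, e in zip(genes, expression):
        g.expression = float(e)
    expr_table = pd.DataFrame(
        {"symbol": [g.symbol for g in genes], "rpkm": [g.expression for g in genes]}
    )

    symbols = np.array([g.symbol for g in genes])
    lengths = np.array([g.gene_length for g in genes], dtype=float)
    gene_sets: list[GeneSet] = []
    taken: set[str] = set()
    for sc in config.sets:
        avail = np.array([s not in taken for s in symbols])
        pool = symbols[avail]
        w = lengths[avail]
        if sc.length_biased:
            probs = w / w.sum()
        else:
            probs = None
        members = rng.choice(pool, size=sc.size, replace=False, p=probs)
        taken.update(members)
        gene_sets.append(GeneSet.from_iterable(sc.name, members))
    return genes, gene_sets, expr_table


def make_manifest(config: SimulationConfig) -> SubcloneManifest:
    rows = []
    for cc in config.classes:
        for i in range(cc.n_subclones):
            rows.append((f"{cc.name}_sc{i + 1:02d}", cc.name, f"{cc.name}_chem"))
    return SubcloneManifest.from_records(rows)


def expected_rates(config: SimulationConfig, genes, gene_sets) -> pd.DataFrame:
    """True lambda (mutations per gene per subclone) for every gene x class."""
    delta_by_symbol: dict[str, float] = {}
    enr = {sc.name: sc.enrichment for sc in config.sets}
    for gs in gene_sets:
        d = enr.get(gs.name, 1.0)
        for s in gs.members:
            delta_by_symbol[s] = delta_by_symbol.get(s, 1.0) * d
    base = np.array(
        [
            math.exp(
                config.beta0
                + config.beta_length * g.gene_length
                + config.beta_gc * (g.gene_gc or 0.0)
                + config.beta_expression * (g.expression or 0.0)
            )
            * delta_by_symbol.get(g.symbol, 1.0)
            for g in genes
        ]
    )
    return pd.DataFrame(
        {cc.name: base * cc.multiplier for cc in config.classes},
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )


def draw_counts(rng, lam: np.ndarray, overdispersion: float | None = None) -> np.ndarray:
    """Poisson counts, or gamma-Poisson (negative binomial with size r) when
    overdispersion is configured: variance = lambda (1 + lambda / r)."""
    lam = np.asarray(lam, dtype=float)
    if overdispersion is None:
        return rng.poisson(lam)
    r = float(overdispersion)
    mix = rng.gamma(shape=r, scale=lam / r)
    return rng.poisson(mix)


def simulate_mutations(
    config: SimulationConfig,
    genes,
    manifest: SubcloneManifest,
    genome: dict[str, np.ndarray],
    gene_sets,
    rng,
) -> tuple[list[MutationRecord], SimulationTruth]:
    """Draw per-(gene, subclone) counts from the rate model and place each
    mutation uniformly within its gene with the reference base read from
    the genome and a uniform alternative base."""
    rates = expected_rates(config, genes, gene_sets)
    records: list[MutationRecord] = []
    for cc in config.classes:
        lam = rates[cc.name].to_numpy()
        for sid in manifest.subclones_of(cc.name):
            counts = draw_counts(rng, lam, config.overdispersion)
            for g, c in zip(genes, counts):
                if c == 0:
                    continue
                positions = rng.integers(g.start, g.end, size=int(c))
                for p0 in positions:
                    ref = str(genome[g.chrom][p0])
                    alts = [b for b in NUCLEOTIDES if b != ref]
                    alt = alts[int(rng.integers(0, 3))]
                    records.append(
                        MutationRecord(
                            subclone_id=sid,
                            exposure_class=cc.name,
                            chemical=manifest.chemical(sid),
                            chrom=g.chrom,
                            pos=int(p0) + 1,
                            ref_allele=ref,
                            alt_allele=alt,
                        )
                    )
    truth = SimulationTruth(
        betas={
            "intercept": config.beta0,
            "gene_length": config.beta_length,
            "gene_gc": config.beta_gc,
            "expression": config.beta_expression,
        },
        class_multipliers={cc.name: cc.multiplier for cc in config.classes},
        set_enrichments={sc.name: sc.enrichment for sc in config.sets},
        rates=rates,
        seed=config.seed,
    )
    return records, truth


def generate_damage_track(
    config: SimulationConfig, genes, gene_sets, rng
) -> pd.DataFrame:
    """Per-gene-constant signal: set mean (background for unassigned genes)
    plus Gaussian noise truncated at 0; one bedGraph row per gene."""
    mean_by_symbol: dict[str, float] = {}
    for sc in config.sets:
        if sc.damage_mean is None:
            continue
        gs = next((g for g in gene_sets if g.name == sc.name), None)
        if gs is None:
            continue
        for s in gs.members:
            mean_by_symbol[s] = sc.damage_mean
    rows = []
    for g in genes:
        mean = mean_by_symbol.get(g.symbol, config.damage_background_mean)
        value = max(mean + rng.normal(0.0, config.damage_noise_sd), 0.0)
        rows.append({"chrom": g.chrom, "start": g.start, "end": g.end, "value": value})
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def write_fasta(genome: dict[str, np.ndarray], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_gtf(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tmutaset_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.cds_intervals:
                fh.write(
                    f"{g.chrom}\tmutaset_sim\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f'{attrs} transcript_id "{g.gene_id}.t1";\n'
                )


def write_gene_sets(gene_sets, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for gs in gene_sets:
        (directory / f"{gs.name}.txt").write_text(
            "\n".join(sorted(gs.members)) + "\n"
        )


def write_bedgraph(track_df: pd.DataFrame, path) -> None:
    track_df.to_csv(path, sep="\t", header=False, index=False)


class Simulation:
    """One reproducible realisation of the full synthetic study."""

    def __init__(self, config: SimulationConfig | None = None):
        self.config = config or SimulationConfig()
        rng = np.random.default_rng(self.config.seed)
        self.genome = generate_genome(self.config, rng)
        self.genes, self.gene_sets, self.expression = generate_annotation(
            self.config, self.genome, rng
        )
        self.manifest = make_manifest(self.config)
        self.records, self.truth = simulate_mutations(
            self.config, self.genes, self.manifest, self.genome, self.gene_sets, rng
        )
        self.damage_track = generate_damage_track(
            self.config, self.genes, self.gene_sets, rng
        )

    def genome_str(self) -> dict[str, str]:
        """Genome as plain strings (sliceable like an indexed FASTA)."""
        return {c: "".join(seq) for c, seq in self.genome.items()}

    def write(self, outdir) -> dict[str, Path]:
        """Emit every artifact as the plain-text formats the readers accept."""
        from . import io as mio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "mutations": outdir / "mutations.tsv",
            "manifest": outdir / "manifest.tsv",
            "expression": outdir / "expression.tsv",
            "sets": outdir / "gene_sets",
            "damage": outdir / "damage.bedGraph",
        }
        write_fasta(self.genome, paths["genome"])
        write_gtf(self.genes, paths["gtf"])
        mio.write_mutation_table(self.records, paths["mutations"])
        mio.write_manifest(self.manifest, paths["manifest"])
        self.expression.to_csv(paths["expression"], sep="\t", index=False)
        write_gene_sets(self.gene_sets, paths["sets"])
        write_bedgraph(self.damage_track, paths["damage"])
        return paths
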