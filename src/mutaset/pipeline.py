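"""End-to-end orchestration: simulate/load -> assign -> enrich -> glm ->
context -> damage -> report, with a reproducibility manifest.

Every stochastic stage derives its seed from the single top-level seed, and
the run manifest records the config hash, per-stage seeds, input digests
and the analysis-decision flags, so a run can be reproduced bitwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx
import yaml

from . import __version__, context as ctx, damage as dmg, enrichment as enr, glm, io as mio
from .simulate import (
    ExposureClassConfig,
    SetConfig,
    Simulation,
    SimulationConfig,
)

logger = logging.getLogger(__name__)

DECISION_FLAGS = {
    "binomial_tail_method": "minimum_likelihood",
    "binomial_trials": "n_genes_x_n_subclones",
    "montecarlo_pseudocount": "none (2/N resolution flagged)",
    "kmer_strand_policy": "reference_strand_no_pyrimidine_centering",
    "spectrum_strand_policy": "pyrimidine_collapsed_cosmic",
    "dunn_adjustment": "fdr_bh",
    "gene_universe": "all_annotated_genes",
    "overlapping_genes": "count_once_per_overlapping_gene",
    "gene_length_definition": "gtf_end_minus_start",
    "glm_response": "counts_pooled_over_all_subclones_no_offset",
}


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    classes = [ExposureClassConfig(**c) for c in d.pop("classes", [])] or None
    sets = [SetConfig(**s) for s in d.pop("sets", [])] or None
    cfg = SimulationConfig(**d)
    if classes is not None:
        cfg.classes = classes
    if sets is not None:
        cfg.sets = sets
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages; returns a dict of result objects and
    writes TSV/JSON outputs plus MANIFEST.json under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    root_rng = np.random.default_rng(seed)
    stage_seeds = {
        name: int(root_rng.integers(0, 2**31 - 1))
        for name in ("simulate", "null_sets", "montecarlo", "sweep", "context")
    }

    # --- inputs: simulate or load -------------------------------------
    if "inputs" in config:
        paths = {k: Path(v) for k, v in config["inputs"].items()}
    else:
        sim_cfg = simulation_config_from_dict(config.get("simulate", {}))
        sim_cfg.seed = stage_seeds["simulate"]
        sim = Simulation(sim_cfg)
        paths = sim.write(outdir / "fixtures")

    manifest = mio.read_manifest(paths["manifest"])
    genes = mio.read_gene_models(paths["gtf"], paths["genome"], paths.get("expression"))
    records = mio.read_mutation_table(paths["mutations"], manifest)
    gene_sets = mio.read_gene_sets(paths["sets"])
    known_classes = set(manifest.classes)
    for cls_name in config.get("classes", []):
        if cls_name not in known_classes:
            raise ValueError(f"config names unknown exposure class {cls_name!r}")
    classes = config.get("classes") or manifest.classes
    genome = pyfaidx.Fasta(str(paths["genome"]))

    assignment = mio.assign_mutations(records, genes)
    mio.gene_table(genes).to_csv(outdir / "gene_models.tsv", sep="\t", index=False)
    assignment.counts.to_csv(outdir / "assignment_counts.tsv", sep="\t", index=False)

    # --- enrichment ----------------------------------------------------
    e_cfg = config.get("enrichment", {})
    n_sets = int(e_cfg.get("n_sets", 1000))
    set_size = min(int(e_cfg.get("set_size", 300)), len(genes))
    universe = [g.gene_id for g in genes]
    null_models = {}
    for cls_name in classes:
        totals = assignment.class_gene_totals(manifest, cls_name, genes, level="gene")
        null_sets = enr.sample_null_sets(
            universe, n_sets, set_size, stage_seeds["null_sets"]
        )
        null_models[cls_name] = enr.null_rate(
            totals, null_sets, cls_name, manifest.n_subclones(cls_name),
            seed=stage_seeds["null_sets"],
        )
    mc_class = e_cfg.get("montecarlo_class", classes[0])
    tables = {}
    for level in ("gene", "cds"):
        nm = null_models
        if level == "cds":
            nm = {}
            for cls_name in classes:
                totals = assignment.class_gene_totals(manifest, cls_name, genes, level="cds")
                null_sets = enr.sample_null_sets(
                    universe, n_sets, set_size, stage_seeds["null_sets"]
                )
                nm[cls_name] = enr.null_rate(
                    totals, null_sets, cls_name, manifest.n_subclones(cls_name)
                )
        tables[level] = enr.enrichment_table(
            gene_sets, classes, assignment, nm, manifest, genes,
            level=level,
            montecarlo_for=mc_class if level == "gene" else None,
            mc_n_sets=n_sets,
            seed=stage_seeds["montecarlo"],
        )
        tables[level].to_frame().to_csv(
            outdir / f"enrichment_{level}.tsv", sep="\t", index=False
        )

    sweep = None
    if e_cfg.get("sweep", True):
        cls_name = classes[0]
        totals = assignment.class_gene_totals(manifest, cls_name, genes, level="gene")
        sizes = [s for s in range(10, 301, 10) if s <= len(genes)]
        sweep = enr.setsize_sweep(
            totals,
            manifest.n_subclones(cls_name),
            sizes=sizes,
            n_sets=int(e_cfg.get("sweep_n_sets", 200)),
            seed=stage_seeds["sweep"],
        )
        sweep.to_csv(outdir / "setsize_sweep.tsv", sep="\t", index=False)

    # --- quasi-Poisson models -------------------------------------------
    gt = mio.gene_table(genes)
    totals_all = (
        assignment.counts.groupby("gene_id")[["n_gene", "n_cds"]].sum()
        .reindex(gt["gene_id"], fill_value=0)
    )
    fits = {}
    glm_results = {}
    gene_cov = pd.DataFrame(
        {
            "length": gt["gene_length"].to_numpy(dtype=float),
            "expression": gt["expression"].to_numpy(dtype=float),
            "gc_percent": gt["gene_gc"].to_numpy(dtype=float) * 100.0,
        }
    )
    fits["gene"] = glm.fit_quasipoisson(
        gene_cov, totals_all["n_gene"].to_numpy(), response_level="gene"
    )
    cds_mask = gt["cds_length"] > 0
    cds_cov = pd.DataFrame(
        {
            "length": gt.loc[cds_mask, "cds_length"].to_numpy(dtype=float),
            "expression": gt.loc[cds_mask, "expression"].to_numpy(dtype=float),
            "gc_percent": gt.loc[cds_mask, "cds_gc"].to_numpy(dtype=float) * 100.0,
        }
    ).reset_index(drop=True)
    fits["cds"] = glm.fit_quasipoisson(
        cds_cov,
        totals_all.loc[cds_mask.to_numpy(), "n_cds"].to_numpy(),
        response_level="cds",
    )
    curves = []
    for level, fit in fits.items():
        rr = fit.rate_ratios()
        glm_results[level] = {
            "coefficients": fit.coefficients.to_dict(),
            "standard_errors": fit.standard_errors.to_dict(),
            "dispersion": fit.dispersion,
            "n_observations": fit.n_observations,
            "rate_ratios_per_iqr": rr.to_dict(orient="index"),
        }
        for cov in rr.index:
            lo = float(fit.covariate_means[cov] - 2 * fit.iqr[cov])
            hi = float(fit.covariate_means[cov] + 2 * fit.iqr[cov])
            grid = np.linspace(max(lo, 0.0), hi, 50)
            curve = glm.centered_rr_curve(fit, cov, grid)
            curve.insert(0, "level", level)
            curve.insert(1, "covariate", cov)
            curves.append(curve)
    pd.concat(curves).to_csv(outdir / "glm_rr_curves.tsv", sep="\t", index=False)
    with open(outdir / "glm_fits.json", "w") as fh:
        json.dump(glm_results, fh, indent=2)

    # --- local sequence context -----------------------------------------
    c_cfg = config.get("context", {})
    k = int(c_cfg.get("k", 7))
    comp = ctx.extract_kmers(records, genome, k=k)
    comp_by_class = ctx.extract_kmers(records, genome, k=k, stratify_by_class=True)
    rand = ctx.sample_random_kmers(
        genome, n=int(c_cfg.get("random_n", 50000)), k=k, seed=stage_seeds["context"]
    )
    spectrum = ctx.trinucleotide_spectrum(records, genome)
    comp.to_frame().to_csv(outdir / "kmer_composition_mutations.tsv", sep="\t", index=False)
    rand.to_frame().to_csv(outdir / "kmer_composition_random.tsv", sep="\t", index=False)
    strat = pd.concat(
        [m.to_frame().assign(exposure_class=c) for c, m in comp_by_class.items()]
    )
    strat.to_csv(outdir / "kmer_composition_by_class.tsv", sep="\t", index=False)
    spectrum.to_series().to_csv(outdir / "sbs96_spectrum.tsv", sep="\t")

    lengths = [g.gene_length for g in genes]
    hit_lengths = ctx.random_mutation_length_model(
        lengths, n=int(c_cfg.get("length_model_n", 100000)), seed=stage_seeds["context"]
    )
    random_mean_length = float(hit_lengths.mean())

    # --- damage enrichment ------------------------------------------------
    damage_results = {}
    damage_df = None
    if "damage" in paths:
        track = mio.read_bedgraph(paths["damage"])
        frames = []
        for level in ("gene", "cds"):
            d = dmg.gene_damage_table(track, genes, gene_sets, level=level)
            frames.append(d)
            if d["gene_set"].nunique() >= 2:
                cmpres = dmg.compare_damage(d, level=level)
                damage_results[level] = {
                    "stat": cmpres.stat_name,
                    "statistic": cmpres.statistic,
                    "p_value": cmpres.p_value,
                    "group_means": cmpres.group_means.to_dict(),
                    "pairwise": cmpres.pairwise.to_dict(orient="records"),
                }
        damage_df = pd.concat(frames)
        damage_df.to_csv(outdir / "damage_enrichment.tsv", sep="\t", index=False)
        with open(outdir / "damage_tests.json", "w") as fh:
            json.dump(damage_results, fh, indent=2)

    # --- manifest ---------------------------------------------------------
    run_manifest = {
        "tool_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": seed,
        "stage_seeds": stage_seeds,
        "input_digests": {k: _digest(p) for k, p in paths.items() if p.is_file()},
        "decisions": DECISION_FLAGS,
        "n_records": len(records),
        "n_genes": len(genes),
        "random_mutation_mean_hit_length": random_mean_length,
    }
    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2)

    if config.get("report", True):
        from . import report

        report.render_reports(outdir)

    return {
        "paths": paths,
        "manifest": manifest,
        "genes": genes,
        "gene_sets": gene_sets,
        "records": records,
        "assignment": assignment,
        "null_models": null_models,
        "enrichment": tables,
        "sweep": sweep,
        "glm_fits": fits,
        "spectrum": spectrum,
        "composition": comp,
        "random_composition": rand,
        "damage": damage_df,
        "damage_tests": damage_results,
        "run_manifest": run_manifest,
    }
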