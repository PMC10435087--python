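"""Figure rendering from the pipeline's machine-readable outputs.

Every figure is a pure function of a TSV/JSON twin already written by the
pipeline, so plots can be regenerated without recomputation.  Marker
convention for enrichment heatmaps: '*' nominal p < 0.05 (higher rate),
'**' Bonferroni-adjusted p < 0.05, and a dagger for nominally significant
*lower* rates.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

DAGGER = "†"


def cell_marker(p_binomial, significant_bonferroni, direction) -> str:
    if p_binomial >= 0.05:
        return ""
    if direction == "less":
        return DAGGER
    return "**" if significant_bonferroni else "*"


def enrichment_heatmap(table: pd.DataFrame, ax=None):
    """Observed-minus-expected heatmap with significance markers."""
    pivot = table.pivot(index="gene_set", columns="exposure_class", values="obs_minus_exp")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(pivot.columns) + 3, 0.6 * len(pivot) + 2))
    vmax = np.nanmax(np.abs(pivot.to_numpy())) or 1.0
    im = ax.imshow(pivot.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    lookup = table.set_index(["gene_set", "exposure_class"])
    for i, gs in enumerate(pivot.index):
        for j, cls in enumerate(pivot.columns):
            row = lookup.loc[(gs, cls)]
            mark = cell_marker(
                row["p_binomial"], bool(row["significant_bonferroni"]), row["direction"]
            )
            txt = f"{row['obs_minus_exp']:.1f}{mark}"
            ax.text(j, i, txt, ha="center", va="center", fontsize=8)
    plt.colorbar(im, ax=ax, label="observed − expected mutations")
    return ax


def sweep_curves(sweep: pd.DataFrame, axes=None):
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(sweep["set_size"], sweep["mean_mutations_per_subclone"], "o-")
    axes[0].set_xlabel("random set size")
    axes[0].set_ylabel("mean mutations / subclone")
    axes[1].plot(sweep["set_size"], sweep["mean_mutations_per_gene_per_subclone"], "o-")
    axes[1].set_xlabel("random set size")
    axes[1].set_ylabel("mean mutations / gene / subclone")
    return axes


def rr_curves(curves: pd.DataFrame, level: str, axes=None):
    covs = curves.loc[curves["level"] == level, "covariate"].unique()
    if axes is None:
        _, axes = plt.subplots(1, len(covs), figsize=(4 * len(covs), 3.2))
        axes = np.atleast_1d(axes)
    for ax, cov in zip(axes, covs):
        sub = curves[(curves["level"] == level) & (curves["covariate"] == cov)]
        ax.plot(sub["x"], sub["rr"], color="C0")
        ax.fill_between(sub["x"], sub["ci_low"], sub["ci_high"], alpha=0.3, color="C0")
        ax.axhline(1.0, ls="--", color="grey", lw=0.8)
        ax.set_xlabel(cov)
        ax.set_ylabel("centred rate ratio")
    return axes


def composition_bars(comp: pd.DataFrame, ax=None, title=""):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(len(comp))
    bottom = np.zeros(len(comp))
    for base, color in zip("ACGT", ("#4daf4a", "#377eb8", "#ff7f00", "#e41a1c")):
        ax.bar(x, comp[base], bottom=bottom, label=base, color=color)
        bottom += comp[base].to_numpy()
    ax.set_xticks(x, comp["position"])
    ax.set_xlabel("position relative to mutation")
    ax.set_ylabel("frequency")
    ax.set_title(title)
    ax.legend(ncol=4, fontsize=8)
    return ax


def spectrum_bars(spectrum: pd.Series, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(14, 3))
    colors = np.repeat(
        ["#03bcee", "#010101", "#e32926", "#cac9c9", "#a1ce63", "#ebc6c4"], 16
    )
    ax.bar(range(96), spectrum.to_numpy(), color=colors)
    ax.set_xticks(range(96), spectrum.index, rotation=90, fontsize=4)
    ax.set_ylabel("mutations")
    return ax


def damage_boxplots(damage: pd.DataFrame, level: str, ax=None):
    """Boxplots ordered left-to-right from highest to lowest mean enrichment."""
    sub = damage[damage["level"] == level]
    order = (
        sub.groupby("gene_set")["enrichment"].mean().sort_values(ascending=False).index
    )
    data = [sub.loc[sub["gene_set"] == g, "enrichment"].to_numpy() for g in order]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 * len(order) + 2, 3.5))
    ax.boxplot(data, tick_labels=list(order))
    for i, d in enumerate(data, start=1):
        ax.plot(i, d.mean(), "D", color="red", ms=5)
    ax.set_ylabel("damage enrichment")
    ax.tick_params(axis="x", rotation=45)
    return ax


def render_reports(results_dir) -> list[Path]:
    """Render every figure whose TSV twin exists under `results_dir`."""
    results_dir = Path(results_dir)
    figdir = results_dir / "figures"
    figdir.mkdir(exist_ok=True)
    written = []

    def _save(name):
        p = figdir / name
        plt.tight_layout()
        plt.savefig(p, dpi=120)
        plt.close("all")
        written.append(p)

    for level in ("gene", "cds"):
        f = results_dir / f"enrichment_{level}.tsv"
        if f.exists():
            enrichment_heatmap(pd.read_csv(f, sep="\t"))
            _save(f"enrichment_heatmap_{level}.png")
    f = results_dir / "setsize_sweep.tsv"
    if f.exists():
        sweep_curves(pd.read_csv(f, sep="\t"))
        _save("setsize_sweep.png")
    f = results_dir / "glm_rr_curves.tsv"
    if f.exists():
        curves = pd.read_csv(f, sep="\t")
        for level in curves["level"].unique():
            rr_curves(curves, level)
            _save(f"glm_rr_curves_{level}.png")
    f = results_dir / "kmer_composition_mutations.tsv"
    if f.exists():
        composition_bars(pd.read_csv(f, sep="\t"), title="7-mers at mutations")
        _save("kmer_composition_mutations.png")
    f = results_dir / "kmer_composition_random.tsv"
    if f.exists():
        composition_bars(pd.read_csv(f, sep="\t"), title="random 7-mers")
        _save("kmer_composition_random.png")
    f = results_dir / "sbs96_spectrum.tsv"
    if f.exists():
        spec = pd.read_csv(f, sep="\t", index_col=0)["count"]
        spectrum_bars(spec)
        _save("sbs96_spectrum.png")
    f = results_dir / "damage_enrichment.tsv"
    if f.exists():
        damage = pd.read_csv(f, sep="\t")
        for level in damage["level"].unique():
            damage_boxplots(damage, level)
            _save(f"damage_boxplot_{level}.png")
    return written
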