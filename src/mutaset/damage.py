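"""DNA-damage signal enrichment over genes/CDS and group comparisons.

Per-region enrichment is the base-pair-weighted mean of a depth-normalised
signal track over the region (uncovered bases contribute 0), which for a
piecewise-constant track equals the scaled-region mean.  Gene-level
enrichments across disease sets are compared with one-way ANOVA followed
by pooled-variance pairwise contrasts under Benjamini-Hochberg FDR; the
(non-normal) CDS-level enrichments use Kruskal-Wallis with Dunn's post-hoc
test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import SignalTrack


def region_enrichment(track: SignalTrack, intervals_by_chrom) -> float:
    """bp-weighted mean signal over the union of regions.

    `intervals_by_chrom`: iterable of (chrom, start, end) half-open pieces
    (e.g. a gene span, or a gene's merged CDS intervals).  Enrichment =
    sum(value x overlap width) / total width; a zero-width region errors.
    """
    total_width = 0
    weighted = 0.0
    for chrom, start, end in intervals_by_chrom:
        if end <= start:
            raise ValueError(f"zero-width region {chrom}:{start}-{end}")
        total_width += end - start
        if chrom not in track.intervals:
            continue
        starts, ends, values = track.intervals[chrom]
        # track intervals are sorted and disjoint: find candidates by binary search
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for i in range(lo, hi):
            ov = min(end, ends[i]) - max(start, starts[i])
            if ov > 0:
                weighted += values[i] * ov
    if total_width == 0:
        raise ValueError("empty region list")
    return weighted / total_width


def gene_damage_table(track, genes, gene_sets, level: str = "gene") -> pd.DataFrame:
    """Per-gene enrichment for every gene of every set (symbol-matched).

    At CDS level the enrichment is averaged over the gene's merged CDS
    union; genes without CDS are dropped at that level.
    """
    by_symbol = {g.symbol: g for g in genes}
    rows = []
    for gs in gene_sets:
        for sym in sorted(gs.members):
            g = by_symbol.get(sym)
            if g is None:
                continue
            if level == "gene":
                regions = [(g.chrom, g.start, g.end)]
            else:
                regions = [(g.chrom, s, e) for s, e in g.cds_intervals]
                if not regions:
                    continue
            rows.append(
                {
                    "gene_set": gs.name,
                    "gene_id": g.gene_id,
                    "symbol": sym,
                    "level": level,
                    "enrichment": region_enrichment(track, regions),
                }
            )
    return pd.DataFrame(rows)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over >= 2 groups of reals."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def pairwise_contrasts_fdr(groups, labels=None) -> pd.DataFrame:
    """All pairwise contrasts using the pooled one-way-ANOVA error variance
    (t with N-k df), Benjamini-Hochberg adjusted."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    n = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    N = int(n.sum())
    df_err = N - k
    if df_err <= 0:
        raise ValueError("no residual degrees of freedom")
    sse = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    mse = sse / df_err
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        if mse == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(mse * (1 / n[i] + 1 / n[j]))
            t = diff / se
            p = 2 * stats.t.sf(abs(t), df_err)
        rows.append({"a": labels[i], "b": labels[j], "diff": diff, "t": t, "p": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        raise ValueError("all values tied: H undefined")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunns_test(groups, labels=None, adjust: str = "fdr_bh") -> pd.DataFrame:
    """Dunn's post-hoc z tests on mean ranks with tie-corrected variance.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with
    tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values
    adjusted by Benjamini-Hochberg (default), Bonferroni or left raw.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    flat = np.concatenate(groups)
    N = flat.size
    ranks = stats.rankdata(flat)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        denom = np.sqrt(var_base * (1 / len(groups[i]) + 1 / len(groups[j])))
        if denom == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / denom
            p = 2 * stats.norm.sf(abs(z))
        rows.append({"a": labels[i], "b": labels[j], "z": z, "p": p})
    df = pd.DataFrame(rows)
    if adjust == "none":
        df["p_adjusted"] = df["p"]
    elif adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(df["p"] * len(df), 1.0)
    elif adjust == "fdr_bh":
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


@dataclass
class DamageComparison:
    """Group-comparison summary for one level (gene or cds)."""

    level: str
    stat_name: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame
    group_means: pd.Series


def compare_damage(damage: pd.DataFrame, level: str = "gene") -> DamageComparison:
    """ANOVA + FDR contrasts at gene level; Kruskal-Wallis + Dunn at CDS."""
    sub = damage[damage["level"] == level]
    labels = sorted(sub["gene_set"].unique())
    groups = [sub.loc[sub["gene_set"] == l, "enrichment"].to_numpy() for l in labels]
    means = pd.Series([g.mean() for g in groups], index=labels).sort_values(ascending=False)
    if level == "gene":
        f, p = one_way_anova(groups)
        pw = pairwise_contrasts_fdr(groups, labels)
        return DamageComparison(level, "anova_F", f, p, pw, means)
    h, p = kruskal_wallis(groups)
    pw = dunns_test(groups, labels)
    return DamageComparison(level, "kruskal_H", h, p, pw, means)
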