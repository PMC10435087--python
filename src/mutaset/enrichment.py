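"""Random-gene-set nulls and gene-set mutation-burden tests.

The burden question: do disease gene sets accumulate more substitutions
under a mutagen class than randomly sampled gene sets do?  The null rate
p0 is the mean mutations-per-gene-per-treated-subclone over many random
sets; enrichment is tested with a two-sided exact binomial test (trials
n = n_genes x n_subclones, successes = total mutations in the set) and,
as a sensitivity analysis, against a size-matched Monte-Carlo empirical
null.  Multiplicity is controlled table-wide with Bonferroni.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import GeneSet

# Relative tolerance when comparing point probabilities in the
# minimum-likelihood two-sided tail (guards against floating-point ties).
_MINLIKE_RTOL = 1e-7


@dataclass
class NullModel:
    """Expected per-gene-per-subclone mutation rate for one exposure class,
    estimated from random gene sets."""

    exposure_class: str
    per_set_rates: np.ndarray
    n_sets: int
    set_size: int
    rng_seed: int | None = None

    @property
    def p0(self) -> float:
        return float(np.mean(self.per_set_rates))


@dataclass
class EnrichmentResult:
    gene_set: str
    exposure_class: str
    n_genes: int
    n_subclones: int
    observed: int
    expected: float
    p_binomial: float
    p_montecarlo: float | None = None
    mc_below_resolution: bool = False
    significant_nominal: bool = False
    significant_bonferroni: bool = False

    @property
    def obs_minus_exp(self) -> float:
        return self.observed - self.expected

    @property
    def direction(self) -> str:
        return "more" if self.observed > self.expected else "less"


def sample_null_sets(universe, n_sets: int, set_size: int, seed) -> list[np.ndarray]:
    """Draw `n_sets` gene sets of exactly `set_size` distinct genes,
    uniformly without replacement within each set and independently across
    sets.  Reproducible under `seed` (an int or a Generator)."""
    universe = np.asarray(universe)
    if len(universe) < set_size:
        raise ValueError(
            f"universe of {len(universe)} genes is smaller than set_size {set_size}"
        )
    rng = np.random.default_rng(seed)
    return [rng.choice(universe, size=set_size, replace=False) for _ in range(n_sets)]


def null_rate(
    gene_totals: pd.Series,
    null_sets,
    exposure_class: str,
    n_subclones: int,
    seed=None,
) -> NullModel:
    """Per-set rate = (mutations in the set's genes among the class's
    subclones) / (set_size x n_subclones); p0 is the mean over sets.

    `gene_totals` is a Series of class-total mutation counts indexed by
    gene id over the whole universe (see AssignmentResult.class_gene_totals).
    """
    if n_subclones < 1:
        raise ValueError("exposure class must have at least one subclone")
    sizes = {len(s) for s in null_sets}
    if len(sizes) != 1:
        raise ValueError("null sets must share a single set size")
    set_size = sizes.pop()
    totals = gene_totals.to_numpy()
    pos = {g: i for i, g in enumerate(gene_totals.index)}
    rates = np.empty(len(null_sets))
    for i, s in enumerate(null_sets):
        idx = [pos[g] for g in s]
        rates[i] = totals[idx].sum() / (set_size * n_subclones)
    return NullModel(
        exposure_class=exposure_class,
        per_set_rates=rates,
        n_sets=len(null_sets),
        set_size=set_size,
        rng_seed=seed,
    )


def _minlike_two_sided(pmf: np.ndarray, observed: int) -> float:
    p_obs = pmf[observed]
    return float(pmf[pmf <= p_obs * (1.0 + _MINLIKE_RTOL)].sum())


def binomial_enrichment(observed: int, n_trials: int, p0: float) -> float:
    """Exact two-sided binomial p-value by the minimum-likelihood method.

    The p-value is the total probability of all outcomes whose point
    probability does not exceed that of the observed outcome (with a small
    relative tolerance for floating-point ties).  If ``observed`` exceeds
    the number of trials — possible because single genes may contribute
    multiple mutations — the test falls back to an exact Poisson test with
    mean p0*n, with a warning.
    """
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"p0 must be in [0, 1] (got {p0})")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if observed > n_trials:
        warnings.warn(
            f"observed count {observed} exceeds binomial trials {n_trials}; "
            "falling back to an exact Poisson test",
            stacklevel=2,
        )
        return poisson_enrichment(observed, p0 * n_trials)
    pmf = stats.binom.pmf(np.arange(n_trials + 1), n_trials, p0)
    return min(_minlike_two_sided(pmf, observed), 1.0)


def poisson_enrichment(observed: int, mean: float) -> float:
    """Exact two-sided Poisson test (minimum-likelihood tail)."""
    if mean <= 0:
        return 1.0 if observed == 0 else 0.0
    # Enumerate outcomes out to where the upper tail is negligible.
    upper = int(max(observed, mean) + 20 * np.sqrt(mean) + 20)
    k = np.arange(upper + 1)
    pmf = stats.poisson.pmf(k, mean)
    p = _minlike_two_sided(pmf, observed) + float(stats.poisson.sf(upper, mean))
    return min(p, 1.0)


@dataclass
class MonteCarloP:
    p: float
    resolution: float
    below_resolution: bool


def montecarlo_enrichment(observed: int, null_totals) -> MonteCarloP:
    """Two-tailed empirical p against size-matched random-set totals.

    p = 2 x min(#{null >= observed}, #{null <= observed}) / N, truncated at
    1; ties count in both tails.  No pseudo-count is added, so p may be 0
    when the observed total lies outside the null range; such values are
    flagged as below the 2/N resolution of the null.
    """
    null_totals = np.asarray(null_totals)
    if null_totals.size == 0:
        raise ValueError("empty Monte-Carlo null")
    n = null_totals.size
    upper = np.count_nonzero(null_totals >= observed) / n
    lower = np.count_nonzero(null_totals <= observed) / n
    p = min(2.0 * min(upper, lower), 1.0)
    resolution = 2.0 / n
    return MonteCarloP(p=p, resolution=resolution, below_resolution=p < resolution)


def montecarlo_null_totals(
    gene_totals: pd.Series, n_sets: int, set_size: int, seed
) -> np.ndarray:
    """Total mutation counts of `n_sets` random sets matched to `set_size`."""
    sets = sample_null_sets(gene_totals.index.to_numpy(), n_sets, set_size, seed)
    totals = gene_totals.to_numpy()
    pos = {g: i for i, g in enumerate(gene_totals.index)}
    return np.array([totals[[pos[g] for g in s]].sum() for s in sets])


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Table-wide Bonferroni flags: significant iff p < 0.05 / m.

    m defaults to the number of p-values (all cells of one heatmap)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return p < 0.05 / m


def setsize_sweep(
    gene_totals: pd.Series,
    n_subclones: int,
    sizes=None,
    n_sets: int = 1000,
    seed=0,
) -> pd.DataFrame:
    """Mean mutations per subclone and per gene per subclone as a function
    of random-set size (diagnostic showing the per-gene rate is size-free).
    """
    if sizes is None:
        sizes = range(10, 301, 10)
    rng = np.random.default_rng(seed)
    universe = gene_totals.index.to_numpy()
    totals = gene_totals.to_numpy()
    rows = []
    for size in sizes:
        # vectorised: one permutation-free draw per set
        set_totals = np.empty(n_sets)
        for i in range(n_sets):
            idx = rng.choice(len(universe), size=size, replace=False)
            set_totals[i] = totals[idx].sum()
        per_sub = set_totals / n_subclones
        per_gene = set_totals / (size * n_subclones)
        rows.append(
            {
                "set_size": int(size),
                "mean_mutations_per_subclone": per_sub.mean(),
                "sem_mutations_per_subclone": per_sub.std(ddof=1) / np.sqrt(n_sets),
                "mean_mutations_per_gene_per_subclone": per_gene.mean(),
                "sem_mutations_per_gene_per_subclone": per_gene.std(ddof=1)
                / np.sqrt(n_sets),
            }
        )
    return pd.DataFrame(rows)


def quartile_stratify(gene_set: GeneSet, gene_lengths: dict[str, int]) -> list[GeneSet]:
    """Split a set into four length-quartile sub-lists, longest first.

    Genes are ranked by length (ties broken by symbol order) and split into
    four near-equal groups; when the size is not divisible by 4 the extra
    genes go to the longest-gene groups, so group sizes differ by at most 1.
    """
    members = sorted(gene_set.members)
    ranked = sorted(members, key=lambda s: (-gene_lengths[s], s))
    chunks = np.array_split(np.array(ranked, dtype=object), 4)
    labels = ["Q1_longest", "Q2", "Q3", "Q4_shortest"]
    out = []
    for label, chunk in zip(labels, chunks):
        if len(chunk):
            out.append(GeneSet.from_iterable(f"{gene_set.name}_{label}", chunk))
    return out


@dataclass
class EnrichmentTable:
    """All set x class cells of one heatmap, with table-wide correction."""

    results: list[EnrichmentResult] = field(default_factory=list)
    level: str = "gene"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_set": r.gene_set,
                    "exposure_class": r.exposure_class,
                    "level": self.level,
                    "n_genes": r.n_genes,
                    "n_subclones": r.n_subclones,
                    "observed": r.observed,
                    "expected": r.expected,
                    "obs_minus_exp": r.obs_minus_exp,
                    "direction": r.direction,
                    "p_binomial": r.p_binomial,
                    "p_montecarlo": r.p_montecarlo,
                    "significant_nominal": r.significant_nominal,
                    "significant_bonferroni": r.significant_bonferroni,
                }
                for r in self.results
            ]
        )


def enrichment_table(
    gene_sets,
    classes,
    assignment,
    null_models: dict[str, NullModel],
    manifest,
    genes,
    level: str = "gene",
    montecarlo_for: str | None = None,
    mc_n_sets: int = 1000,
    seed=0,
) -> EnrichmentTable:
    """One EnrichmentResult per gene set x exposure class.

    Gene-set membership is matched by symbol against the annotation.  When
    `montecarlo_for` names a class, size-matched Monte-Carlo p-values are
    added for that class's cells (the sensitivity analysis).
    """
    symbol_to_id = {g.symbol: g.gene_id for g in genes}
    results = []
    rng = np.random.default_rng(seed)
    for cls in classes:
        nm = null_models[cls]
        n_sub = manifest.n_subclones(cls)
        gene_totals = assignment.class_gene_totals(manifest, cls, genes, level=level)
        for gs in gene_sets:
            ids = [symbol_to_id[s] for s in gs.members if s in symbol_to_id]
            observed = int(gene_totals.loc[ids].sum())
            n_genes = len(ids)
            expected = nm.p0 * n_genes * n_sub
            p = binomial_enrichment(observed, n_genes * n_sub, min(nm.p0, 1.0))
            res = EnrichmentResult(
                gene_set=gs.name,
                exposure_class=cls,
                n_genes=n_genes,
                n_subclones=n_sub,
                observed=observed,
                expected=expected,
                p_binomial=p,
            )
            if montecarlo_for is not None and cls == montecarlo_for:
                nulls = montecarlo_null_totals(
                    gene_totals, mc_n_sets, n_genes, rng
                )
                mc = montecarlo_enrichment(observed, nulls)
                res.p_montecarlo = mc.p
                res.mc_below_resolution = mc.below_resolution
            results.append(res)
    pvals = np.array([r.p_binomial for r in results])
    bonf = bonferroni_adjust(pvals, m=len(results))
    for r, b in zip(results, bonf):
        r.significant_nominal = r.p_binomial < 0.05
        r.significant_bonferroni = bool(b)
    return EnrichmentTable(results=results, level=level)
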