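"""Random-set nulls, exact binomial / Monte-Carlo burden tests, sweeps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutaset import enrichment as enr
from mutaset.models import GeneSet


class TestSampleNullSets:
    def test_full_universe_set(self):
        sets = enr.sample_null_sets(list("ABCD" * 75), 5, 300, seed=0)
        assert all(len(s) == 300 for s in sets)

    def test_universe_equal_to_set_size(self):
        universe = [f"g{i}" for i in range(300)]
        sets = enr.sample_null_sets(universe, 3, 300, seed=1)
        for s in sets:
            assert set(s) == set(universe)

    def test_inclusion_frequency_uniform(self):
        # set_size 2 from 4 genes: each gene included with prob 1/2 per set
        universe = ["a", "b", "c", "d"]
        sets = enr.sample_null_sets(universe, 1000, 2, seed=2)
        freq = {g: np.mean([g in set(s) for s in sets]) for g in universe}
        se = np.sqrt(0.5 * 0.5 / 1000)
        for f in freq.values():
            assert abs(f - 0.5) < 3 * se

    def test_same_seed_identical(self):
        u = [f"g{i}" for i in range(50)]
        a = enr.sample_null_sets(u, 10, 5, seed=9)
        b = enr.sample_null_sets(u, 10, 5, seed=9)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_universe_too_small_errors(self):
        with pytest.raises(ValueError, match="smaller than set_size"):
            enr.sample_null_sets(["a"], 1, 2, seed=0)


class TestNullRate:
    def test_hand_arithmetic(self):
        # 2 sets of 2 genes, 3 subclones; set totals 4 and 8
        totals = pd.Series([1, 3, 5, 3], index=["a", "b", "c", "d"])
        nm = enr.null_rate(totals, [np.array(["a", "b"]), np.array(["c", "d"])],
                           "PAH", n_subclones=3)
        assert nm.per_set_rates == pytest.approx([4 / 6, 8 / 6])
        assert nm.p0 == pytest.approx(1.0)

    def test_no_mutations_gives_zero(self):
        totals = pd.Series([0, 0], index=["a", "b"])
        nm = enr.null_rate(totals, [np.array(["a", "b"])], "PAH", 4)
        assert nm.p0 == 0.0

    def test_homogeneous_counts_give_rate_c(self):
        # every gene mutated c times per subclone -> p0 = c for any sampling
        c, n_sub = 3, 5
        totals = pd.Series(c * n_sub, index=[f"g{i}" for i in range(20)])
        sets = enr.sample_null_sets(totals.index.to_numpy(), 50, 7, seed=0)
        nm = enr.null_rate(totals, sets, "PAH", n_sub)
        assert nm.p0 == pytest.approx(c)

    def test_zero_subclones_is_hard_error(self):
        totals = pd.Series([1], index=["a"])
        with pytest.raises(ValueError, match="subclone"):
            enr.null_rate(totals, [np.array(["a"])], "PAH", 0)


class TestBinomialEnrichment:
    @pytest.mark.parametrize(
        "observed, n, p0, expected",
        [
            (0, 5, 0.0, 1.0),
            (7, 10, 0.5, 0.34375),
            (10, 10, 0.5, 0.001953125),
        ],
    )
    def test_worked_values(self, observed, n, p0, expected):
        assert enr.binomial_enrichment(observed, n, p0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_scipy_exact_binomtest(self):
        # independent implementation of the minimum-likelihood two-sided test
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            ours = enr.binomial_enrichment(k, n, p0)
            ref = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_observed_above_trials_poisson_fallback(self):
        with pytest.warns(UserWarning, match="Poisson"):
            p = enr.binomial_enrichment(12, 10, 0.5)
        # independent check: exact Poisson with mean 5
        assert p == pytest.approx(enr.poisson_enrichment(12, 5.0))
        assert 0 < p < 0.05

    def test_upper_tail_monotone_in_observed(self):
        # for observed above the mean, increasing observed never raises p
        ps = [enr.binomial_enrichment(k, 30, 0.2) for k in range(7, 31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bad_p0_is_hard_error(self):
        with pytest.raises(ValueError, match="p0"):
            enr.binomial_enrichment(1, 10, 1.5)


class TestPoissonEnrichment:
    def test_matches_enumeration(self):
        mean = 3.0
        k = np.arange(200)
        pmf = stats.poisson.pmf(k, mean)
        for obs in [0, 1, 3, 7, 12]:
            expected = pmf[pmf <= pmf[obs] * (1 + 1e-7)].sum()
            assert enr.poisson_enrichment(obs, mean) == pytest.approx(expected, abs=1e-12)


class TestMonteCarlo:
    def test_direct_count(self):
        res = enr.montecarlo_enrichment(10, list(range(1, 11)))
        assert res.p == pytest.approx(0.2)

    def test_below_every_null_flagged(self):
        nulls = np.arange(100, 1100)  # 1000 values, all above observed
        res = enr.montecarlo_enrichment(5, nulls)
        assert res.p == 0.0
        assert res.below_resolution
        assert res.resolution == pytest.approx(2 / 1000)

    def test_all_ties_truncates_to_one(self):
        res = enr.montecarlo_enrichment(4, [4] * 50)
        assert res.p == 1.0

    def test_empty_null_errors(self):
        with pytest.raises(ValueError, match="empty"):
            enr.montecarlo_enrichment(1, [])


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, m, expected",
        [(0.001, 120, False), (1e-6, 120, True), (0.01, 1, True)],
    )
    def test_flags(self, p, m, expected):
        assert enr.bonferroni_adjust([p], m=m)[0] == expected


class TestQuartileStratify:
    def test_balanced_split(self):
        lengths = {f"g{i:03d}": 1000 + i for i in range(220)}
        gs = GeneSet.from_iterable("set", lengths)
        quarts = enr.quartile_stratify(gs, lengths)
        assert [len(q) for q in quarts] == [55, 55, 55, 55]

    def test_remainder_goes_to_longest_groups(self):
        lengths = {f"g{i}": 100 * (i + 1) for i in range(10)}
        gs = GeneSet.from_iterable("set", lengths)
        quarts = enr.quartile_stratify(gs, lengths)
        assert [len(q) for q in quarts] == [3, 3, 2, 2]
        # first group holds the longest genes
        assert quarts[0].members == frozenset({"g9", "g8", "g7"})

    def test_equal_lengths_split_by_symbol_order(self):
        lengths = {s: 500 for s in "abcdefgh"}
        gs = GeneSet.from_iterable("set", lengths)
        quarts = enr.quartile_stratify(gs, lengths)
        assert quarts[0].members == frozenset({"a", "b"})
        assert [len(q) for q in quarts] == [2, 2, 2, 2]


class TestSetsizeSweep:
    def test_zero_mutations_flat_zero(self):
        totals = pd.Series(0, index=[f"g{i}" for i in range(50)])
        sweep = enr.setsize_sweep(totals, 5, sizes=[10, 20], n_sets=20, seed=0)
        assert (sweep["mean_mutations_per_subclone"] == 0).all()
        assert (sweep["mean_mutations_per_gene_per_subclone"] == 0).all()

    def test_homogeneous_rates_linear_per_subclone_flat_per_gene(self):
        rng = np.random.default_rng(3)
        n_sub, rate = 10, 0.4
        totals = pd.Series(
            rng.poisson(rate * n_sub, size=500), index=[f"g{i}" for i in range(500)]
        )
        sizes = [10, 50, 100, 200, 300]
        sweep = enr.setsize_sweep(totals, n_sub, sizes=sizes, n_sets=300, seed=1)
        per_gene = sweep["mean_mutations_per_gene_per_subclone"]
        # flat per-gene curve: relative spread under 10%
        assert per_gene.max() - per_gene.min() < 0.1 * per_gene.mean()
        # per-subclone curve ~ linear with slope = empirical per-gene rate
        slope = np.polyfit(sweep["set_size"], sweep["mean_mutations_per_subclone"], 1)[0]
        assert slope == pytest.approx(totals.mean() / n_sub, rel=0.05)

    def test_size_ratio_30x(self):
        rng = np.random.default_rng(4)
        totals = pd.Series(
            rng.poisson(2.0, size=400), index=[f"g{i}" for i in range(400)]
        )
        sweep = enr.setsize_sweep(totals, 4, sizes=[10, 300], n_sets=400, seed=2)
        per_sub = sweep.set_index("set_size")["mean_mutations_per_subclone"]
        assert per_sub[300] / per_sub[10] == pytest.approx(30, rel=0.1)


class TestEnrichmentTable:
    def test_obs_minus_exp_cell_value(self):
        from mutaset.enrichment import EnrichmentResult

        r = EnrichmentResult(
            gene_set="s", exposure_class="c", n_genes=5, n_subclones=2,
            observed=10, expected=7.5, p_binomial=0.5,
        )
        assert r.obs_minus_exp == pytest.approx(2.5)
        assert r.direction == "more"

    def test_full_table_on_simulation(self, desk_sim):
        from mutaset import io as mio

        assignment = mio.assign_mutations(desk_sim.records, desk_sim.genes)
        universe = [g.gene_id for g in desk_sim.genes]
        null_models = {}
        for cls in desk_sim.manifest.classes:
            totals = assignment.class_gene_totals(
                desk_sim.manifest, cls, desk_sim.genes, level="gene"
            )
            sets = enr.sample_null_sets(universe, 100, 100, seed=0)
            null_models[cls] = enr.null_rate(
                totals, sets, cls, desk_sim.manifest.n_subclones(cls)
            )
        table = enr.enrichment_table(
            desk_sim.gene_sets, desk_sim.manifest.classes, assignment,
            null_models, desk_sim.manifest, desk_sim.genes,
            montecarlo_for="radiation", mc_n_sets=200,
        )
        df = table.to_frame()
        assert len(df) == len(desk_sim.gene_sets) * len(desk_sim.manifest.classes)
        assert ((df["p_binomial"] > 0) & (df["p_binomial"] <= 1)).all()
        # the delta=2 set should be flagged "more" for every class
        ndd = df[df["gene_set"] == "NDD_like"]
        assert (ndd["direction"] == "more").all()
        # Monte-Carlo p present exactly for the requested class
        assert df["p_montecarlo"].notna().sum() == len(
            df[df["exposure_class"] == "radiation"]
        )
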