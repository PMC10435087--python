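"""The synthetic study generator and its ground truth."""

import numpy as np
import pytest

from mutaset import io as mio
from mutaset.simulate import (
    ExposureClassConfig,
    SetConfig,
    Simulation,
    SimulationConfig,
    draw_counts,
    expected_rates,
    generate_genome,
)


def small_config(**kw):
    base = dict(
        seed=0,
        n_chromosomes=2,
        chrom_length=200_000,
        n_genes=80,
        classes=[ExposureClassConfig("PAH", 5, 1.0)],
        sets=[SetConfig("hot", size=10, enrichment=1.0)],
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenome:
    def test_gc_concentration(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length=1_000_000)
        genome = generate_genome(cfg)
        seq = genome["chr1"]
        gc = np.isin(seq, ["G", "C"]).mean()
        assert 0.497 < gc < 0.503  # binomial concentration at 1 Mb

    def test_gc_one_all_strong(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length=5000,
                               background_gc=1.0)
        seq = generate_genome(cfg)["chr1"]
        assert np.isin(seq, ["G", "C"]).all()

    def test_same_seed_identical_fasta(self, tmp_path):
        a = Simulation(small_config())
        b = Simulation(small_config())
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        from mutaset.simulate import write_fasta

        write_fasta(a.genome, pa)
        write_fasta(b.genome, pb)
        assert pa.read_bytes() == pb.read_bytes()


class TestAnnotation:
    def test_gene_count_and_containment(self):
        sim = Simulation(small_config())
        assert len(sim.genes) == 80
        for g in sim.genes:
            assert 0 <= g.start < g.end <= 200_000
            for s, e in g.cds_intervals:
                assert g.start <= s < e <= g.end

    def test_genes_do_not_overlap(self):
        sim = Simulation(small_config())
        by_chrom = {}
        for g in sim.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(ivs, ivs[1:]))

    def test_length_biased_set_has_longer_genes(self):
        hits = 0
        for seed in range(10):
            cfg = small_config(
                seed=seed,
                sets=[SetConfig("long_biased", size=15, length_biased=True)],
            )
            sim = Simulation(cfg)
            lengths = {g.symbol: g.gene_length for g in sim.genes}
            members = sim.gene_sets[0].members
            set_mean = np.mean([lengths[s] for s in members])
            hits += set_mean > np.mean(list(lengths.values()))
        assert hits >= 9  # length-weighted sampling favours long genes

    def test_roundtrip_through_readers_without_warnings(self, tmp_path, recwarn):
        sim = Simulation(small_config())
        paths = sim.write(tmp_path)
        manifest = mio.read_manifest(paths["manifest"])
        genes = mio.read_gene_models(paths["gtf"], paths["genome"], paths["expression"])
        records = mio.read_mutation_table(paths["mutations"], manifest)
        sets = mio.read_gene_sets(paths["sets"])
        track = mio.read_bedgraph(paths["damage"])
        assert len(genes) == len(sim.genes)
        assert len(records) == len(sim.records)
        assert {gs.name for gs in sets} == {gs.name for gs in sim.gene_sets}
        assert len(track) == len(sim.genes)
        assert not [w for w in recwarn if issubclass(w.category, UserWarning)]
        # covariates computed from files match the generator's values
        by_id = {g.gene_id: g for g in genes}
        for g in sim.genes:
            assert by_id[g.gene_id].gene_length == g.gene_length
            assert by_id[g.gene_id].gene_gc == pytest.approx(g.gene_gc, abs=1e-12)


class TestMutationModel:
    def test_total_count_matches_rate(self):
        # flat rates: total ~ Poisson(r * G * S)
        cfg = small_config(
            beta0=np.log(0.1), beta_length=0.0, beta_gc=0.0, beta_expression=0.0,
        )
        sim = Simulation(cfg)
        expected = 0.1 * 80 * 5
        assert abs(len(sim.records) - expected) < 3 * np.sqrt(expected)

    def test_enriched_set_rate_doubles(self):
        cfg = small_config(
            seed=3,
            n_genes=200,
            chrom_length=500_000,
            beta0=np.log(0.3), beta_length=0.0, beta_gc=0.0, beta_expression=0.0,
            classes=[ExposureClassConfig("PAH", 20, 1.0)],
            sets=[SetConfig("hot", size=50, enrichment=2.0)],
        )
        sim = Simulation(cfg)
        assignment = mio.assign_mutations(sim.records, sim.genes)
        totals = assignment.class_gene_totals(sim.manifest, "PAH", sim.genes)
        members = {g.gene_id for g in sim.genes if g.symbol in sim.gene_sets[0].members}
        in_rate = totals[totals.index.isin(members)].mean() / 20
        out_rate = totals[~totals.index.isin(members)].mean() / 20
        se = np.sqrt(2 * 0.3 / (50 * 20)) + np.sqrt(0.3 / (150 * 20))
        assert abs(in_rate / out_rate - 2.0) < 3 * se / out_rate * 2

    def test_zero_rate_empty_catalog(self):
        sim = Simulation(small_config(beta0=-np.inf))
        assert sim.records == []

    def test_truth_rates_formula(self):
        cfg = small_config(seed=4, sets=[SetConfig("hot", size=10, enrichment=3.0)])
        sim = Simulation(cfg)
        rates = expected_rates(cfg, sim.genes, sim.gene_sets)
        members = sim.gene_sets[0].members
        for g in sim.genes:
            lam = np.exp(
                cfg.beta0
                + cfg.beta_length * g.gene_length
                + cfg.beta_gc * g.gene_gc
                + cfg.beta_expression * g.expression
            )
            if g.symbol in members:
                lam *= 3.0
            assert rates.loc[g.gene_id, "PAH"] == pytest.approx(lam)

    def test_ref_alleles_match_genome(self):
        sim = Simulation(small_config(seed=5))
        genome = sim.genome_str()
        for r in sim.records[:200]:
            assert genome[r.chrom][r.pos - 1] == r.ref_allele
            assert r.alt_allele != r.ref_allele


class TestDrawCounts:
    def test_nb_overdispersion_inflates_variance(self):
        rng = np.random.default_rng(0)
        lam = np.full(20000, 2.0)
        poisson = draw_counts(rng, lam)
        nb = draw_counts(rng, lam, overdispersion=1.0)
        assert np.isclose(nb.mean(), 2.0, atol=0.1)
        # NB variance = mu (1 + mu/r) = 6 vs Poisson 2
        assert nb.var() > 1.8 * poisson.var()


class TestDamageTrack:
    def test_noiseless_track_recovers_set_means(self):
        cfg = small_config(
            sets=[SetConfig("hot", size=10, damage_mean=2.5)],
            damage_background_mean=1.0,
            damage_noise_sd=0.0,
        )
        sim = Simulation(cfg)
        from mutaset import damage as dmg
        from mutaset.models import SignalTrack

        intervals = {}
        for chrom, grp in sim.damage_track.groupby("chrom"):
            intervals[chrom] = (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
                grp["value"].to_numpy(float),
            )
        track = SignalTrack(intervals)
        members = sim.gene_sets[0].members
        for g in sim.genes:
            e = dmg.region_enrichment(track, [(g.chrom, g.start, g.end)])
            assert e == pytest.approx(2.5 if g.symbol in members else 1.0)

    def test_same_seed_identical_track(self):
        a = Simulation(small_config(seed=9)).damage_track
        b = Simulation(small_config(seed=9)).damage_track
        assert a.equals(b)
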