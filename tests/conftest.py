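import numpy as np
import pytest

from mutaset.models import GeneModel, SubcloneManifest


@pytest.fixture
def manifest():
    return SubcloneManifest.from_records(
        [
            ("s1", "PAH", "benzopyrene"),
            ("s2", "PAH", "benzopyrene"),
            ("s3", "radiation", "gamma"),
        ]
    )


@pytest.fixture
def toy_gene():
    # 1-based GTF span [101, 200] -> internal [100, 200)
    return GeneModel(
        gene_id="GENE1",
        symbol="G1",
        chrom="chr1",
        strand="+",
        start=100,
        end=200,
        cds_intervals=[(120, 170)],
    )


@pytest.fixture
def toy_genome():
    # deterministic 9-nt chromosome used in the k-mer examples
    return {"chr1": "AAACGTTTT"}


@pytest.fixture(scope="session")
def desk_sim():
    """One shared desk-scale simulation (expensive enough to cache)."""
    from mutaset.simulate import Simulation, SimulationConfig

    return Simulation(SimulationConfig(seed=7, n_genes=120, n_chromosomes=2,
                                       chrom_length=400_000))


def make_records(rows, manifest):
    """rows: iterable of (subclone, chrom, pos, ref, alt)."""
    from mutaset.models import MutationRecord

    return [
        MutationRecord(
            subclone_id=s,
            exposure_class=manifest.exposure_class(s),
            chemical=manifest.chemical(s),
            chrom=c,
            pos=p,
            ref_allele=r,
            alt_allele=a,
        )
        for s, c, p, r, a in rows
    ]
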