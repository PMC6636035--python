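import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from exomescape.catalog import GeneRecord, SpeciesTable
from exomescape.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_record(symbol="TP53", chrom="chr1", start=100, end=500, tx="NM_000001",
                length=400, species="human", clade="mammal", protein=None):
    return GeneRecord(
        gene_symbol=symbol, chromosome=chrom, start=start, end=end, strand="+",
        transcript_accession=tx, transcript_length=length,
        protein_accession=protein, species=species, clade=clade,
    )


@pytest.fixture
def small_table():
    recs = [
        make_record("ALPHA", "chr1", 100, 500, "NM_000001", 400),
        make_record("BETA", "chr1", 1000, 1600, "NM_000002", 600),
        make_record("GAMMA", "chr2", 50, 250, "NM_000003", 200),
    ]
    return SpeciesTable(species="human", clade="mammal", records=recs)


@pytest.fixture(scope="session")
def two_species_sim():
    """A small two-leaf simulation shared across tests (read-only)."""
    cfg = SimulationConfig(
        n_genes=200, n_chromosomes=2, n_codons=60, gc_baseline=50.0,
        peaks=[(100, 30, 12)], coupling=1.0,
        tree="(A:0.05,B:0.05)root;", seed=4242,
    )
    species, truth = simulate_dataset(cfg)
    return cfg, species, truth
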