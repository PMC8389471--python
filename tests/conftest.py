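"""Shared fixtures: tiny hand-built genomes and small simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from sbds import GenomeConfig, CohortConfig, DriverSpec
from sbds import genome_model_from_arrays, simulate_genome_model, simulate_cohort
from sbds.insertion_io import INSERTION_COLUMNS


@pytest.fixture(scope="session")
def tiny_model():
    """Two short chromosomes with hand-verifiable TA sites and two genes.

    chrA = 'GGTACCTAGGTATA' -> TA at 1-based positions 3, 7, 11, 13
    chrB = 'TTTTAAAA'       -> TA at position 4
    """
    sequences = {"chrA": "GGTACCTAGGTATA", "chrB": "TTTTAAAA"}
    genes = pd.DataFrame(
        {
            "gene_id": ["plusG", "minusG"],
            "chrom": ["chrA", "chrA"],
            "start": [2, 10],
            "end": [8, 14],
            "gene_strand": ["+", "-"],
        }
    )
    return genome_model_from_arrays(sequences, genes)


@pytest.fixture(scope="session")
def sim_model():
    """Small simulated genome: 2 x 200 kb, 40 x 2 kb genes, AT-rich."""
    cfg = GenomeConfig(
        n_chroms=2, chrom_length=200_000, gc_fraction=0.42,
        n_genes=40, gene_length=2_000,
    )
    sequences, genes, model = simulate_genome_model(cfg, seed=11)
    return model


@pytest.fixture(scope="session")
def sim_cohort(sim_model):
    """Cohort with two strong planted drivers and a donor hopping window."""
    cfg = CohortConfig(
        n_tumors=12, n_normals=8, burden_mean=200, burden_dispersion=3.5,
        drivers=[
            DriverSpec("g0003", "activating", carrier_fraction=0.6),
            DriverSpec("g0025", "inactivating", carrier_fraction=0.5),
        ],
        donor_chrom="chr1", donor_window=(50_000, 100_000), donor_fold=8.0,
    )
    tumors, normals, truth = simulate_cohort(cfg, sim_model, seed=23)
    return tumors, normals, truth


def random_insertion_table(rng, n, specimens=("s1", "s2"), chroms=("chrA", "chrB"),
                           max_pos=1000, max_depth=50):
    """Helper for property tests: arbitrary (possibly duplicated) records."""
    return pd.DataFrame(
        {
            "specimen_id": rng.choice(specimens, n),
            "chrom": rng.choice(chroms, n),
            "pos": rng.integers(1, max_pos + 1, n),
            "strand": rng.choice(["+", "-"], n),
            "read_count": rng.integers(0, max_depth + 1, n),
        }
    )[INSERTION_COLUMNS]
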