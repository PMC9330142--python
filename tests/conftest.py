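from importlib import resources

import pytest

from mtoop import (CohortSimConfig, load_gene_map, load_tree, read_profiles,
                   simulate_study)
from mtoop.annotate import GeneRecord


@pytest.fixture(scope="session")
def toy_tree():
    return load_tree(resources.files("mtoop.data") / "toy_phylotree.tsv")


@pytest.fixture(scope="session")
def table1_profiles():
    return read_profiles(resources.files("mtoop.data") / "table1_profiles.tsv")


@pytest.fixture(scope="session")
def rcrs_gene_map():
    return load_gene_map()


@pytest.fixture(scope="session")
def toy_genome():
    """Synthetic 200-bp genome with a hand-designed 3-gene map.

    geneA: heavy-strand protein, 10-69 (20 codons), complex I.
    geneB: light-strand protein, 100-161 (20 codons + 2-base incomplete
      stop tail at positions 100-101, the low-coordinate end).
    geneC: heavy-strand protein, 60-119, complex V — overlaps geneA
      (60-69) and geneB (100-119).
    trnX: tRNA at 170-180; everything else noncoding.
    """
    import numpy as np

    rng = np.random.default_rng(2024)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    gene_map = [
        GeneRecord("geneA", 10, 69, "heavy", "protein", "I"),
        GeneRecord("geneC", 60, 119, "heavy", "protein", "V"),
        GeneRecord("geneB", 100, 161, "light", "protein", "IV"),
        GeneRecord("trnX", 170, 180, "heavy", "tRNA", None),
    ]
    return seq, gene_map


@pytest.fixture(scope="session")
def default_sim():
    """One fitted default simulated study shared across tests."""
    return simulate_study(CohortSimConfig(seed=7))
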