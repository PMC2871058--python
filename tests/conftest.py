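import numpy as np
import pytest

from geneorder import (
    GeneRecord,
    PlantedPair,
    SyntheticConfig,
    generate_dataset,
    read_newick_string,
)


def make_gene(species="spA", chromosome="chr1", gene_id="g1", start=100,
              end=200, strand="+", protein_length=100, cluster_id=None):
    return GeneRecord(species=species, chromosome=chromosome, gene_id=gene_id,
                      start=start, end=end, strand=strand,
                      protein_length=protein_length, cluster_id=cluster_id)


@pytest.fixture
def gene_factory():
    return make_gene


@pytest.fixture
def tree_abc():
    """Three-leaf tree with known pairwise path lengths."""
    return read_newick_string("((A:0.1,B:0.2):0.05,C:0.3);")


@pytest.fixture(scope="session")
def planted_dataset():
    """Eight species, mixed planted pairs; shared by several test modules."""
    species = tuple(f"sp{i:02d}" for i in range(1, 9))
    config = SyntheticConfig(
        seed=11,
        n_species=8,
        genes_per_species=150,
        planted_pairs=(
            PlantedPair("divergent", species, (100, 900), 0.8),
            PlantedPair("divergent", species[:4], (100, 900), 0.8),
            PlantedPair("convergent", species[2:6], (100, 900), 0.1),
            PlantedPair("codirectional", species[:3], (50, 500), 0.5),
            PlantedPair("divergent", species[:2], (100, 400), 0.1),
        ),
    )
    return generate_dataset(config)


def random_records(rng: np.random.Generator, n_genes=30, species="spX",
                   chromosome="chr1", cluster_prob=0.8):
    """A random single-chromosome gene list for property tests."""
    records = []
    pos = 1
    for i in range(n_genes):
        length = int(rng.integers(150, 3000))
        gap = int(rng.integers(1, 5000))
        records.append(GeneRecord(
            species=species,
            chromosome=chromosome,
            gene_id=f"{species}_g{i:04d}",
            start=pos,
            end=pos + length - 1,
            strand="+" if rng.random() < 0.5 else "-",
            protein_length=length // 3,
            cluster_id=f"C{int(rng.integers(0, n_genes)):04d}"
            if rng.random() < cluster_prob else None,
        ))
        pos += length + gap
    return records
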