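from collections import Counter

import numpy as np
import pytest

from repeatscape import (
    ClusteringConfig,
    GenomeSpec,
    ReadSimSpec,
    RepeatFamilySpec,
    build_similarity_graph,
    partition_graph,
    simulate_genome,
    simulate_reads,
)
from repeatscape._dna import random_dna


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_genome():
    """Three dispersed families plus one satellite, with ground truth."""
    fams = [
        RepeatFamilySpec("FAM0", "LTR_copia", 800, 0.06, divergence=0.01),
        RepeatFamilySpec("FAM1", "LTR_gypsy", 800, 0.05, divergence=0.01),
        RepeatFamilySpec("FAM2", "DNA_transposon", 600, 0.04, divergence=0.01),
        RepeatFamilySpec(
            "SAT1", "satellite", 153, 0.05, monomer_length=153, divergence=0.01
        ),
    ]
    return simulate_genome(GenomeSpec("A", 150_000, fams, seed=42))


@pytest.fixture(scope="session")
def small_read_run(small_genome):
    """Reads from the small genome, clustered; shared by several test files."""
    pairs, labels = simulate_reads(
        small_genome, ReadSimSpec(n_pairs=1200, error_rate=0.003, seed=7)
    )
    reads = [r for p in pairs for r in p]
    config = ClusteringConfig(detail_threshold=0.005)
    edges = build_similarity_graph(reads, config)
    clusters = partition_graph(edges, reads, config)
    return {
        "genome": small_genome,
        "reads": reads,
        "reads_by_id": {r.read_id: r for r in reads},
        "labels": labels,
        "edges": edges,
        "clusters": clusters,
        "config": config,
    }


def cluster_majority_label(cluster, labels):
    return Counter(labels[r] for r in cluster.read_ids).most_common(1)[0][0]


@pytest.fixture(scope="session")
def random_template():
    return random_dna(np.random.default_rng(11), 1000)
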