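import numpy as np
import pytest

from panarch import GenePresenceMatrix


@pytest.fixture
def toy_matrix():
    """Three genomes A={g1,g2,g3}, B={g1,g2,g4}, C={g1,g5}."""
    presence = np.array(
        [
            [1, 1, 1, 0, 0],
            [1, 1, 0, 1, 0],
            [1, 0, 0, 0, 1],
        ],
        dtype=bool,
    )
    return GenePresenceMatrix(
        species_id="toy",
        genome_ids=["A", "B", "C"],
        cluster_ids=["g1", "g2", "g3", "g4", "g5"],
        presence=presence,
    )


def random_matrix(rng, n_genomes=None, n_clusters=None, species_id="rand"):
    """Random presence matrix with every genome and cluster nonempty."""
    n_genomes = n_genomes or int(rng.integers(3, 6))
    n_clusters = n_clusters or int(rng.integers(4, 12))
    while True:
        P = rng.random((n_genomes, n_clusters)) < rng.uniform(0.2, 0.8)
        if P.any(axis=0).all() and P.any(axis=1).all():
            return GenePresenceMatrix(
                species_id=species_id,
                genome_ids=[f"G{i}" for i in range(n_genomes)],
                cluster_ids=[f"c{j}" for j in range(n_clusters)],
                presence=P,
            )
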