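import numpy as np
import pytest
from hypothesis import settings

from structnet.proximity_graph import ProximityGraph
from structnet import synthetic as syn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def clique_contacts(nodes, weight=10):
    return {(a, b): weight for i, a in enumerate(nodes) for b in nodes[i + 1 :]}


@pytest.fixture(scope="session")
def triangle_graph():
    # P(A->B) = 3/4, P(A->C) = 1/4 by construction
    return ProximityGraph.from_contacts({("A", "B"): 3, ("A", "C"): 1, ("B", "C"): 2})


@pytest.fixture(scope="session")
def barbell_graph():
    """Two 5-cliques with heavy internal contacts joined by one weak edge."""
    left = ["L1", "L2", "L3", "L4", "L5"]
    right = ["R1", "R2", "R3", "R4", "R5"]
    contacts = {**clique_contacts(left, 20), **clique_contacts(right, 20), ("L1", "R1"): 1}
    return ProximityGraph.from_contacts(contacts)


@pytest.fixture(scope="session")
def two_cliques_graph():
    """Two disconnected 6-cliques."""
    a = [f"A{i}" for i in range(6)]
    b = [f"B{i}" for i in range(6)]
    return ProximityGraph.from_contacts({**clique_contacts(a), **clique_contacts(b)})


@pytest.fixture(scope="session")
def ring_fixture():
    """A 6-protein ring point-cloud complex with its true adjacency at 12 Å."""
    spec = syn.BlobSpec(
        6, residues_per_protein=20, blob_radius=1.5, layout="ring",
        inter_center_distance=10.0, seed=3,
    )
    structure, adjacency = syn.make_blob_complex(spec, d_t=12.0)
    return structure, adjacency


@pytest.fixture(scope="session")
def clustered_fixture():
    """9 clusters of 8 proteins each; clusters internally dense, mutually
    disconnected at 12 Å.  Used for planted-enrichment and calibration."""
    centers = syn.clustered_centers(9, 8, intra_spacing=6.0, inter_spacing=60.0)
    spec = syn.BlobSpec(
        72, residues_per_protein=12, blob_radius=1.0, layout="custom",
        inter_center_distance=6.0, seed=11, centers=centers,
    )
    structure, _ = syn.make_blob_complex(spec)
    return structure
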