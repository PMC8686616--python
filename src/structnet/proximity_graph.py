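"""Contact-weighted protein proximity graphs.

Each chain is coarse-grained to one point per residue (the unweighted
centroid of its non-hydrogen atoms).  Two proteins are connected when at
least one pair of residue centers lies within the distance threshold d_t
(inclusive).  The number of such residue pairs is the symmetric contact
count; normalising a node's contacts by its total outgoing contacts gives
asymmetric edge weights and, equivalently, the transit probabilities
P[x, y] = w[x, y] / w[x] that drive the random-walk sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from structnet.structure_io import ComplexStructure, ProteinChain

__all__ = [
    "GraphConfig",
    "ResidueCenter",
    "ProximityGraph",
    "residue_centers",
    "count_contacts",
    "build_graph",
    "export_graph",
    "load_graph",
    "pair_distance_matrix",
]

_HYDROGENS = {"H", "D"}


@dataclass(frozen=True)
class GraphConfig:
    """Distance threshold d_t in Å for residue-residue contacts.

    12 Å is the default for large RNA-scaffolded complexes such as the
    ribosome, where many protein-protein proximities are RNA-mediated;
    8 Å is the consensus residue-contact distance within a single protein.
    """

    d_t: float = 12.0

    def __post_init__(self) -> None:
        if not self.d_t > 0:
            raise ValueError(f"d_t must be positive, got {self.d_t}")


@dataclass(frozen=True)
class ResidueCenter:
    protein_name: str
    seq_index: int
    center: tuple[float, float, float]


def residue_centers(chain: ProteinChain) -> list[ResidueCenter]:
    """Coarse-grain a chain to one geometric center per residue.

    Hydrogens are excluded from the mean (rarely modeled, would skew
    centroids across structures of differing completeness).
    """
    out = []
    for res in chain.residues:
        coords = np.array(
            [a.coord for a in res.atoms if a.element.upper() not in _HYDROGENS], dtype=float
        )
        if coords.size == 0:
            raise ValueError(
                f"residue {res.residue_name} {res.seq_index} of {chain.protein_name} "
                "has no non-hydrogen atoms"
            )
        center = coords.mean(axis=0)
        out.append(ResidueCenter(chain.protein_name, res.seq_index, tuple(center)))
    return out


def _coords(centers: Sequence[ResidueCenter]) -> np.ndarray:
    return np.array([c.center for c in centers], dtype=float)


def count_contacts(
    centers_a: Sequence[ResidueCenter],
    centers_b: Sequence[ResidueCenter],
    config: GraphConfig,
) -> int:
    """Number of residue pairs (one from each chain) within d_t, inclusive."""
    if not centers_a or not centers_b:
        return 0
    tree = cKDTree(_coords(centers_b))
    hits = tree.query_ball_point(_coords(centers_a), r=config.d_t)
    return int(sum(len(h) for h in hits))


def pair_distance_matrix(
    centers_a: Sequence[ResidueCenter], centers_b: Sequence[ResidueCenter]
) -> np.ndarray:
    """Full Euclidean distance matrix between two chains' residue centers."""
    a, b = _coords(centers_a), _coords(centers_b)
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)


@dataclass
class ProximityGraph:
    """Protein proximity graph with contact counts and transit probabilities.

    ``contacts`` is a symmetric mapping over unordered protein pairs; an
    edge exists iff the contact count is >= 1.  Isolated proteins remain
    as degree-0 nodes.  Transit probabilities are row-normalised contact
    counts: P[x, y] = contacts(x, y) / sum_z contacts(x, z).
    """

    nodes: tuple[str, ...]
    _contacts: dict[frozenset, int]
    d_t: float
    _adj: dict | None = field(default=None, repr=False, compare=False)

    def _adjacency(self) -> dict[str, dict[str, int]]:
        # cached node -> {neighbor: contacts}; contacts map is never mutated
        if self._adj is None:
            adj: dict[str, dict[str, int]] = {n: {} for n in self.nodes}
            for key, c in self._contacts.items():
                x, y = tuple(key)
                adj.setdefault(x, {})[y] = c
                adj.setdefault(y, {})[x] = c
            self._adj = {n: dict(sorted(d.items())) for n, d in adj.items()}
        return self._adj

    @classmethod
    def from_contacts(
        cls,
        contacts: Mapping[tuple[str, str], int] | Mapping[frozenset, int],
        nodes: Iterable[str] | None = None,
        d_t: float = 12.0,
    ) -> "ProximityGraph":
        cmap: dict[frozenset, int] = {}
        for pair, count in contacts.items():
            key = frozenset(pair)
            if len(key) != 2:
                raise ValueError(f"self-contact not allowed: {pair}")
            count = int(count)
            if count < 0:
                raise ValueError(f"negative contact count for {pair}")
            if key in cmap and cmap[key] != count:
                raise ValueError(f"inconsistent contact counts for {pair}")
            if count >= 1:
                cmap[key] = count
        node_set = {n for key in cmap for n in key}
        if nodes is not None:
            node_set |= set(nodes)
        return cls(tuple(sorted(node_set)), cmap, float(d_t))

    def contacts(self, x: str, y: str) -> int:
        return self._contacts.get(frozenset((x, y)), 0)

    def neighbors(self, x: str) -> list[str]:
        return list(self._adjacency().get(x, {}))

    def total_contacts(self, x: str) -> int:
        return sum(self._adjacency().get(x, {}).values())

    def weight(self, x: str, y: str) -> float:
        """Source-normalised weight w[x, y] (asymmetric)."""
        total = self.total_contacts(x)
        if total == 0:
            return 0.0
        return self.contacts(x, y) / total

    def out_weight(self, x: str) -> float:
        """w[x]: sum of outgoing weights (1 for non-isolated nodes)."""
        return sum(self.weight(x, y) for y in self.neighbors(x))

    def transit(self, x: str, y: str) -> float:
        """Transit probability P[x, y] = w[x, y] / w[x]."""
        wx = self.out_weight(x)
        if wx == 0.0:
            return 0.0
        return self.weight(x, y) / wx

    def transit_row(self, x: str) -> dict[str, float]:
        row = self._adjacency().get(x, {})
        total = sum(row.values())
        if total == 0:
            return {}
        return {y: c / total for y, c in row.items()}

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return sorted((min(k), max(k), c) for k, c in self._contacts.items())

    @property
    def n_edges(self) -> int:
        return len(self._contacts)

    def isolated_nodes(self) -> list[str]:
        connected = {n for key in self._contacts for n in key}
        return sorted(set(self.nodes) - connected)

    def drop_isolated(self) -> "ProximityGraph":
        iso = set(self.isolated_nodes())
        return ProximityGraph(
            tuple(n for n in self.nodes if n not in iso), dict(self._contacts), self.d_t
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(d_t=self.d_t)
        g.add_nodes_from(self.nodes)
        for x, y, c in self.edges:
            g.add_edge(x, y, contacts=c)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProximityGraph):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and self._contacts == other._contacts
            and self.d_t == other.d_t
        )


def build_graph(structure: ComplexStructure, config: GraphConfig | float = GraphConfig()) -> ProximityGraph:
    """Build the proximity graph of a complex at threshold d_t.

    All chains appear as nodes (possibly isolated); contacts are counted
    between residue centers of distinct chains only.
    """
    if isinstance(config, (int, float)):
        config = GraphConfig(d_t=float(config))
    if len(structure.chains) < 2:
        raise ValueError("need at least 2 chains to build a proximity graph")
    centers = {c.protein_name: residue_centers(c) for c in structure.chains}
    names = list(structure.protein_names)
    contacts: dict[tuple[str, str], int] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            n = count_contacts(centers[a], centers[b], config)
            if n >= 1:
                contacts[(a, b)] = n
    return ProximityGraph.from_contacts(contacts, nodes=names, d_t=config.d_t)


_TSV_HEADER = "source\ttarget\tcontacts\tweight"


def export_graph(graph: ProximityGraph, path: str | Path, format: str = "tsv") -> Path:
    """Serialise the graph as a directed edge-list TSV or as GraphML.

    The TSV carries one row per directed edge (source, target, contact
    count, source-normalised weight) so that the asymmetric weights are
    explicit; nodes and d_t are kept in header comments for round-tripping.
    """
    path = Path(path)
    if format == "tsv":
        lines = [
            f"# structnet proximity graph, d_t={graph.d_t}",
            "# nodes: " + ",".join(graph.nodes),
            _TSV_HEADER,
        ]
        for x, y, c in graph.edges:
            lines.append(f"{x}\t{y}\t{c}\t{graph.weight(x, y):.12g}")
            lines.append(f"{y}\t{x}\t{c}\t{graph.weight(y, x):.12g}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        nx.write_graphml(graph.to_networkx(), str(path))
    else:
        raise ValueError(f"unknown export format: {format!r} (use 'tsv' or 'graphml')")
    return path


def load_graph(path: str | Path) -> ProximityGraph:
    """Load a graph previously written by export_graph (TSV or GraphML)."""
    path = Path(path)
    if path.suffix == ".graphml":
        g = nx.read_graphml(str(path))
        contacts = {(x, y): int(d["contacts"]) for x, y, d in g.edges(data=True)}
        return ProximityGraph.from_contacts(
            contacts, nodes=g.nodes, d_t=float(g.graph.get("d_t", 12.0))
        )
    d_t = 12.0
    nodes: list[str] = []
    contacts: dict[tuple[str, str], int] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line == _TSV_HEADER:
            continue
        if line.startswith("#"):
            if "d_t=" in line:
                d_t = float(line.split("d_t=")[1])
            elif line.startswith("# nodes:"):
                nodes = [n for n in line.split(":", 1)[1].strip().split(",") if n]
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed edge row in {path}: {line!r}")
        x, y, c = parts[0], parts[1], int(parts[2])
        key = (min(x, y), max(x, y))
        if key in contacts and contacts[key] != c:
            raise ValueError(f"inconsistent contact count for {key} in {path}")
        contacts[key] = c
        nodes.extend(k for k in key if k not in nodes)
    return ProximityGraph.from_contacts(contacts, nodes=nodes, d_t=d_t)
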