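"""Structurally coherent regions via consensus random walks and set cover.

From every node of the proximity graph, I random walks of L steps are
restarted; each step follows the transit probabilities P[x, y].  Every
visit to a node is tallied, including repeat visits within one walk.  The
pre-region of a start node is the set of nodes visited in at least half
of the iterations (tally * 2 >= I), plus the start node itself.  A minimum
set cover over the pre-regions yields the final, possibly overlapping
region set spanning the whole node universe.

The walk default forbids only immediate edge reversal (one step of
memory, remaining probabilities renormalised); a pure memoryless mode is
available.  Dead ends and isolated nodes terminate walks early.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from structnet.proximity_graph import ProximityGraph

__all__ = [
    "SamplingParams",
    "Region",
    "RegionSet",
    "random_walk",
    "consensus_preregion",
    "members_from_tallies",
    "minimum_set_cover",
    "sample_regions",
    "region_overlap",
    "OverlapResult",
    "recommend_region_size",
    "partition_communities",
    "save_regions",
    "load_regions",
]

BACKTRACK_MODES = ("no-immediate-reverse", "memoryless")


@dataclass(frozen=True)
class SamplingParams:
    """Parameters of the consensus random-walk sampling.

    walk_length: steps per walk; an integer >= 1, or a fraction in (0, 1)
        of the node count, resolved as max(1, round(fraction * |V|)).
        Default 0.25 (walks about a quarter of the network); smaller
        fractions yield smaller regions.
    iterations: number of restarted walks per start node (default 50;
        higher values give more reproducible consensus regions).
    seed: master RNG seed; per-start-node streams are derived from it so
        results do not depend on node iteration order.
    backtrack_mode: 'no-immediate-reverse' (default) or 'memoryless'.
    """

    walk_length: float | int = 0.25
    iterations: int = 50
    seed: int = 0
    backtrack_mode: str = "no-immediate-reverse"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        wl = self.walk_length
        if not (0 < wl < 1 or (float(wl).is_integer() and wl >= 1)):
            raise ValueError(
                f"walk_length must be an integer >= 1 or a fraction in (0, 1), got {wl}"
            )
        if self.backtrack_mode not in BACKTRACK_MODES:
            raise ValueError(f"backtrack_mode must be one of {BACKTRACK_MODES}")

    def resolve_walk_length(self, n_nodes: int) -> int:
        wl = self.walk_length
        if 0 < wl < 1:
            return max(1, round(wl * n_nodes))
        return int(wl)


@dataclass(frozen=True)
class Region:
    """A start node with the consensus set of nodes reachable from it."""

    start_node: str
    members: frozenset
    visit_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start_node not in self.members:
            raise ValueError(f"start node {self.start_node} not in its own members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RegionSet:
    """The selected cover: regions whose union spans the node universe."""

    regions: tuple[Region, ...]
    universe: frozenset
    params: SamplingParams | None = None

    def __post_init__(self) -> None:
        covered = frozenset().union(*(r.members for r in self.regions)) if self.regions else frozenset()
        if not self.universe <= covered:
            missing = sorted(self.universe - covered)
            raise ValueError(f"regions do not cover the universe; missing {missing}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def _rng_for_node(seed: int, node: str) -> np.random.Generator:
    # stream keyed by (seed, crc32(node)): independent of iteration order
    return np.random.default_rng([seed, zlib.crc32(node.encode())])


def random_walk(
    graph: ProximityGraph,
    start: str,
    length: int,
    rng: np.random.Generator,
    backtrack_mode: str = "no-immediate-reverse",
) -> list[str]:
    """One weighted random walk of at most ``length`` steps from ``start``.

    Steps are drawn from the transit probabilities of the current node.
    In no-immediate-reverse mode the node just left is excluded and the
    remaining probabilities renormalised; a dead end ends the walk.
    """
    if start not in graph.nodes:
        raise KeyError(f"start node {start!r} not in graph")
    if backtrack_mode not in BACKTRACK_MODES:
        raise ValueError(f"unknown backtrack_mode {backtrack_mode!r}")
    path = [start]
    prev: str | None = None
    current = start
    for _ in range(length):
        row = graph.transit_row(current)
        if backtrack_mode == "no-immediate-reverse" and prev is not None:
            row = {y: p for y, p in row.items() if y != prev}
        if not row:
            break
        nodes = list(row)
        probs = np.array([row[y] for y in nodes], dtype=float)
        probs /= probs.sum()
        nxt = nodes[rng.choice(len(nodes), p=probs)]
        path.append(nxt)
        prev, current = current, nxt
    return path


def members_from_tallies(tallies: Mapping[str, int], iterations: int, start: str) -> frozenset:
    """Consensus rule: nodes tallied at least I/2 times, plus the start.

    The threshold is tally * 2 >= I (no rounding of I/2); the start node
    is tallied once per iteration and is therefore always a member.
    """
    members = {node for node, t in tallies.items() if t * 2 >= iterations}
    members.add(start)
    return frozenset(members)


def consensus_preregion(
    graph: ProximityGraph,
    start: str,
    params: SamplingParams,
    rng: np.random.Generator | None = None,
) -> Region:
    """Pre-region of one start node from I restarted walks.

    Every visit is tallied, including repeat visits within a single walk;
    the start counts once per iteration as the walk's first element.
    """
    if rng is None:
        rng = _rng_for_node(params.seed, start)
    length = params.resolve_walk_length(len(graph.nodes))
    tallies: dict[str, int] = {}
    for _ in range(params.iterations):
        for node in random_walk(graph, start, length, rng, params.backtrack_mode):
            tallies[node] = tallies.get(node, 0) + 1
    members = members_from_tallies(tallies, params.iterations, start)
    return Region(start, members, dict(sorted(tallies.items())))


def _greedy_cover(preregions: Sequence[Region], universe: frozenset) -> list[Region]:
    uncovered = set(universe)
    remaining = list(preregions)
    selected: list[Region] = []
    while uncovered:
        best = max(
            remaining,
            key=lambda r: (len(r.members & uncovered), len(r.members), _neg_lex(r.start_node)),
        )
        if not best.members & uncovered:  # defensive; union was checked upstream
            raise ValueError("pre-regions do not cover the universe")
        selected.append(best)
        remaining.remove(best)
        uncovered -= best.members
    return selected


class _NegLex:
    """Inverts lexicographic order so it can be used inside max()."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegLex") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegLex) and self.s == other.s


def _neg_lex(s: str) -> _NegLex:
    return _NegLex(s)


def _exact_cover_size(sets: Sequence[frozenset], universe: frozenset) -> tuple[int, tuple[int, ...]]:
    """Branch-and-bound minimum set cover; returns (size, chosen indices).

    Intended for small instances (<= ~20 distinct candidate sets).  Among
    optimal covers the lexicographically smallest index tuple is returned.
    """
    order = sorted(range(len(sets)), key=lambda i: (-len(sets[i]), i))
    best_size = len(sets) + 1
    best_choice: tuple[int, ...] = ()
    max_set = max((len(s) for s in sets), default=1)

    def recurse(uncovered: frozenset, chosen: tuple[int, ...], start_pos: int) -> None:
        nonlocal best_size, best_choice
        if not uncovered:
            if len(chosen) < best_size or (len(chosen) == best_size and chosen < best_choice):
                best_size, best_choice = len(chosen), chosen
            return
        lower = len(chosen) + math.ceil(len(uncovered) / max_set)
        if lower > best_size:
            return
        for pos in range(start_pos, len(order)):
            i = order[pos]
            if sets[i] & uncovered:
                recurse(uncovered - sets[i], chosen + (i,), pos + 1)

    recurse(universe, (), 0)
    if best_size > len(sets):
        raise ValueError("sets do not cover the universe")
    return best_size, best_choice


def minimum_set_cover(
    preregions: Sequence[Region],
    universe: Iterable[str],
    method: str = "auto",
    params: SamplingParams | None = None,
) -> RegionSet:
    """Select a small set of pre-regions covering every node.

    Greedy selection repeatedly takes the pre-region covering the most
    still-uncovered nodes (ties: larger total size, then lexicographically
    smallest start node), which prefers few large regions over many small
    ones.  With ``method='auto'`` an exact branch-and-bound optimum is
    computed when there are at most 20 distinct candidate member sets; the
    greedy solution is returned whenever it attains the optimal size (it
    usually does), otherwise the exact cover.
    """
    universe = frozenset(universe)
    if method not in ("auto", "greedy", "exact"):
        raise ValueError(f"unknown method {method!r}")
    if not preregions:
        raise ValueError("no pre-regions given")
    union = frozenset().union(*(r.members for r in preregions))
    if not universe <= union:
        raise ValueError(f"pre-regions do not cover the universe; missing {sorted(universe - union)}")

    greedy = _greedy_cover(preregions, universe)

    # one representative per distinct member set (smallest start node);
    # subsets of another candidate cannot improve a minimum cover
    representative: dict[frozenset, Region] = {}
    for region in preregions:
        prev = representative.get(region.members)
        if prev is None or region.start_node < prev.start_node:
            representative[region.members] = region
    distinct = [
        s for s in representative
        if not any(s < t for t in representative)
    ]
    use_exact = method == "exact" or (method == "auto" and len(distinct) <= 20)
    if use_exact:
        member_sets = sorted(distinct, key=lambda s: representative[s].start_node)
        opt_size, choice = _exact_cover_size(member_sets, universe)
        if len(greedy) > opt_size:
            exact = [representative[member_sets[i]] for i in choice]
            # order the exact selection greedily, for a deterministic output
            selected = _greedy_cover(exact, universe)
            return RegionSet(tuple(selected), universe, params)
    return RegionSet(tuple(greedy), universe, params)


def sample_regions(
    graph: ProximityGraph,
    params: SamplingParams,
    cover_method: str = "auto",
) -> RegionSet:
    """Full sampling pipeline: one pre-region per node, then the set cover.

    Deterministic for a given (graph, params) pair.  Isolated nodes yield
    singleton pre-regions and hence singleton final regions.
    """
    if not graph.nodes:
        raise ValueError("empty graph")
    preregions = [
        consensus_preregion(graph, node, params) for node in sorted(graph.nodes)
    ]
    return minimum_set_cover(preregions, graph.nodes, method=cover_method, params=params)


@dataclass(frozen=True)
class OverlapResult:
    """Set arithmetic between signature-selected regions of two runs."""

    union_a: frozenset
    union_b: frozenset
    intersection: frozenset
    only_a: frozenset
    only_b: frozenset
    empty_a: bool
    empty_b: bool

    @property
    def jaccard(self) -> float:
        denom = len(self.union_a | self.union_b)
        return len(self.intersection) / denom if denom else 0.0


def _signature_union(regions: RegionSet, signature: frozenset, mode: str) -> tuple[frozenset, bool]:
    if mode == "all":
        picked = [r for r in regions if signature <= r.members]
    elif mode == "any":
        picked = [r for r in regions if signature & r.members]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not picked:
        return frozenset(), True
    return frozenset().union(*(r.members for r in picked)), False


def region_overlap(
    run_a: RegionSet,
    run_b: RegionSet,
    signature: Iterable[str],
    mode: str = "all",
) -> OverlapResult:
    """Overlap between the signature-containing regions of two runs.

    Regions containing the signature node set (mode='all'; mode='any'
    requires only a non-empty intersection with the signature) are pooled
    per run; the pooled member sets are then intersected and differenced.
    A run in which no region matches the signature is flagged empty.
    """
    signature = frozenset(signature)
    if not signature:
        raise ValueError("empty signature")
    ua, empty_a = _signature_union(run_a, signature, mode)
    ub, empty_b = _signature_union(run_b, signature, mode)
    if empty_a or empty_b:
        warnings.warn("signature absent from all regions of at least one run", stacklevel=2)
    return OverlapResult(ua, ub, ua & ub, ua - ub, ub - ua, empty_a, empty_b)


def recommend_region_size(background_fraction: float) -> int:
    """Minimum region size so one changed node matches the background rate.

    If a fraction f of all entities is changed, a region must hold at
    least ceil(1/f) nodes for a single changed node not to exceed the
    background proportion; e.g. f=0.20 -> 5 nodes, f=0.08 -> 13 nodes.
    """
    if not 0 < background_fraction <= 1:
        raise ValueError(f"background fraction must be in (0, 1], got {background_fraction}")
    return int(math.ceil(round(1.0 / background_fraction, 9)))


def partition_communities(graph: ProximityGraph, method: str = "walktrap") -> list[frozenset]:
    """Non-overlapping community partition via igraph, for comparison.

    Supported methods: 'walktrap', 'infomap', 'eigenvector' (leading
    eigenvector).  These yield a covering, overlap-free partition whose
    node kernels can be compared with the overlapping sampled regions.
    Raises RuntimeError with a clear message if igraph is unavailable.
    """
    try:
        import igraph as ig
    except ImportError as exc:  # pragma: no cover - igraph present in CI env
        raise RuntimeError(
            f"community method {method!r} needs python-igraph, which is not installed; "
            "skipping community comparison"
        ) from exc
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[x], index[y]) for x, y, _ in graph.edges]
    weights = [float(c) for _, _, c in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    if method == "walktrap":
        clustering = g.community_walktrap(weights=weights).as_clustering()
    elif method == "infomap":
        clustering = g.community_infomap(edge_weights=weights)
    elif method == "eigenvector":
        clustering = g.community_leading_eigenvector(weights=weights)
    else:
        raise ValueError(f"unknown community method {method!r}")
    return [frozenset(nodes[i] for i in comm) for comm in clustering]


def _params_dict(params: SamplingParams | None) -> dict:
    if params is None:
        return {}
    return {
        "walk_length": params.walk_length,
        "iterations": params.iterations,
        "seed": params.seed,
        "backtrack_mode": params.backtrack_mode,
    }


def save_regions(regions: RegionSet, path: str | Path | None = None) -> str:
    """Serialise a RegionSet as JSON (string; optionally written to path)."""
    doc = {
        "params": _params_dict(regions.params),
        "universe": sorted(regions.universe),
        "regions": [
            {
                "start_node": r.start_node,
                "members": sorted(r.members),
                "visit_counts": dict(r.visit_counts),
            }
            for r in regions.regions
        ],
    }
    text = json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def load_regions(path: str | Path) -> RegionSet:
    doc = json.loads(Path(path).read_text())
    params = SamplingParams(**doc["params"]) if doc.get("params") else None
    regions = tuple(
        Region(r["start_node"], frozenset(r["members"]), r.get("visit_counts", {}))
        for r in doc["regions"]
    )
    return RegionSet(regions, frozenset(doc["universe"]), params)
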