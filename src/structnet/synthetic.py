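"""Synthetic complexes, planted CRA tables and brute-force oracles.

The generators make the whole pipeline testable without any structure
download: point-cloud "proteins" with controlled spatial adjacency stand
in for real chains, and CRA tables with a planted, spatially confined
enrichment provide ground truth for power and calibration checks.  The
brute-force oracles (pairwise-distance adjacency, exhaustive set cover,
hypergeometric enumeration) are deliberately independent of the
implementations they check.

Every generated residue is a single-atom residue, so its geometric
center equals its coordinate and all geometry checks are exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

from structnet.enrichment import ContingencyTable, CRATable
from structnet.proximity_graph import residue_centers
from structnet.region_sampling import Region
from structnet.structure_io import (
    AtomRecord,
    ComplexStructure,
    ProteinChain,
    ResidueRecord,
)

__all__ = [
    "BlobSpec",
    "PlantSpec",
    "make_blob_complex",
    "layout_centers",
    "clustered_centers",
    "brute_force_adjacency",
    "name_map",
    "plant_cra",
    "brute_force_cover",
    "hypergeom_oracle",
]

LAYOUTS = ("ring", "lattice", "two-clusters", "custom")


@dataclass(frozen=True)
class BlobSpec:
    """A toy complex: n point-cloud proteins on a geometric layout.

    Each protein is a Gaussian cloud of single-atom residues (sd =
    blob_radius) around its layout center; inter_center_distance is the
    nearest-neighbor center spacing of the layout.
    """

    n_proteins: int
    residues_per_protein: int = 30
    blob_radius: float = 2.0
    layout: str = "ring"
    inter_center_distance: float = 20.0
    seed: int = 0
    centers: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        if self.blob_radius <= 0 or self.inter_center_distance <= 0:
            raise ValueError("blob_radius and inter_center_distance must be positive")
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}")
        if self.layout == "custom" and self.centers is None:
            raise ValueError("custom layout needs explicit centers")


def layout_centers(spec: BlobSpec) -> np.ndarray:
    """Protein layout centers for a spec, shape (n, 3)."""
    n, d = spec.n_proteins, spec.inter_center_distance
    if spec.layout == "custom":
        centers = np.asarray(spec.centers, dtype=float)
        if centers.shape != (n, 3):
            raise ValueError(f"custom centers must have shape ({n}, 3)")
    elif spec.layout == "ring":
        # radius such that neighboring chord length equals d
        radius = d / (2.0 * math.sin(math.pi / n))
        angles = 2.0 * math.pi * np.arange(n) / n
        centers = np.stack(
            [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)], axis=1
        )
    elif spec.layout == "lattice":
        side = math.ceil(math.sqrt(n))
        pts = [(i % side, i // side) for i in range(n)]
        centers = np.array([(x * d, y * d, 0.0) for x, y in pts])
    elif spec.layout == "two-clusters":
        half = n // 2
        sub_a = layout_centers(
            BlobSpec(max(half, 2), layout="ring", inter_center_distance=d, blob_radius=spec.blob_radius)
        )[:half]
        sub_b = layout_centers(
            BlobSpec(max(n - half, 2), layout="ring", inter_center_distance=d, blob_radius=spec.blob_radius)
        )[: n - half]
        offset = np.array([10.0 * d, 0.0, 0.0])
        centers = np.vstack([sub_a, sub_b + offset])
    else:  # pragma: no cover
        raise AssertionError(spec.layout)
    diffs = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    np.fill_diagonal(diffs, np.inf)
    if diffs.min() < 1e-9:
        raise ValueError("degenerate layout: coincident protein centers")
    return centers


def clustered_centers(
    n_clusters: int,
    per_cluster: int,
    intra_spacing: float = 6.0,
    inter_spacing: float = 40.0,
) -> tuple[tuple[float, float, float], ...]:
    """Centers for a two-level layout: small rings of proteins arranged on
    a large ring of cluster positions (densely connected clusters, sparse
    or absent links between clusters)."""
    big = layout_centers(
        BlobSpec(max(n_clusters, 2), layout="ring", inter_center_distance=inter_spacing)
    )[:n_clusters]
    small = layout_centers(
        BlobSpec(max(per_cluster, 2), layout="ring", inter_center_distance=intra_spacing)
    )[:per_cluster]
    centers = []
    for c in big:
        for s in small:
            centers.append(tuple(c + s))
    return tuple(centers)


def _protein_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"B{str(i + 1).zfill(width)}" for i in range(n)]


def make_blob_complex(
    spec: BlobSpec, d_t: float | None = None
) -> tuple[ComplexStructure, set[frozenset] | None]:
    """Generate a point-cloud complex; optionally its true adjacency at d_t.

    Residue positions are drawn once from isotropic Gaussians around the
    layout centers (seeded); the returned adjacency is computed from those
    realised positions by brute force over all inter-protein residue
    pairs, so it is the exact ground truth for the stated threshold.
    """
    centers = layout_centers(spec)
    rng = np.random.default_rng(spec.seed)
    names = _protein_names(spec.n_proteins)
    chains = []
    for i, (name, center) in enumerate(zip(names, centers)):
        points = center + rng.normal(0.0, spec.blob_radius, size=(spec.residues_per_protein, 3))
        residues = tuple(
            ResidueRecord(
                j + 1,
                "GLY",
                (AtomRecord("CA", "C", tuple(points[j]), occupancy=1.0),),
            )
            for j in range(spec.residues_per_protein)
        )
        chains.append(ProteinChain(chain_id=_chain_id(i), protein_name=name, residues=residues))
    structure = ComplexStructure(tuple(chains), source_id=f"blob-{spec.layout}-{spec.seed}")
    adjacency = brute_force_adjacency(structure, d_t) if d_t is not None else None
    return structure, adjacency


def name_map(structure: ComplexStructure) -> dict[str, str]:
    """Chain-id -> protein-name map for re-parsing written fixtures."""
    return {c.chain_id: c.protein_name for c in structure.chains}


def _chain_id(i: int) -> str:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if i < 26:
        return alphabet[i]
    return alphabet[i // 26 - 1] + alphabet[i % 26]


def brute_force_adjacency(structure: ComplexStructure, d_t: float) -> set[frozenset]:
    """Ground-truth adjacency: plain double loop over all residue pairs.

    Independent of the KD-tree contact counting it is used to check.
    """
    centers = {
        chain.protein_name: np.array([c.center for c in residue_centers(chain)])
        for chain in structure.chains
    }
    adjacency: set[frozenset] = set()
    names = list(centers)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            touching = False
            for pa in centers[a]:
                for pb in centers[b]:
                    if math.dist(pa, pb) <= d_t:
                        touching = True
                        break
                if touching:
                    break
            if touching:
                adjacency.add(frozenset((a, b)))
    return adjacency


@dataclass(frozen=True)
class PlantSpec:
    """A planted, spatially confined enrichment in a CRA table.

    Paralogs of families inside ``target_region`` are flagged changed
    with probability q_in, all others with q_out; q_in = q_out gives the
    null generator.
    """

    target_region: frozenset
    q_in: float = 0.9
    q_out: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_region:
            raise ValueError("empty target region")
        if not (0.0 <= self.q_out <= self.q_in <= 1.0):
            raise ValueError("need 0 <= q_out <= q_in <= 1")


def plant_cra(
    families: Mapping[str, int], spec: PlantSpec
) -> tuple[CRATable, dict[str, bool]]:
    """Draw a CRA table with planted regional enrichment.

    ``families`` maps family name -> paralog count.  Returns the table
    and the ground-truth in-target label per paralog.
    """
    unknown = spec.target_region - set(families)
    if unknown:
        raise ValueError(f"target families not in universe: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    records = []
    truth: dict[str, bool] = {}
    for family in sorted(families):
        count = families[family]
        in_target = family in spec.target_region
        q = spec.q_in if in_target else spec.q_out
        for k in range(count):
            paralog = f"{family}{chr(ord('a') + k)}" if count > 1 else family
            flag = int(rng.random() < q)
            records.append((paralog, family, flag))
            truth[paralog] = in_target
    return CRATable.from_records(records), truth


def brute_force_cover(
    sets: Sequence[frozenset] | Sequence[Region], universe: Iterable[str]
) -> list[int]:
    """Exhaustive minimum set cover (indices); oracle for small instances.

    Tries all combinations by increasing size, so the first feasible
    combination found is optimal; ties resolve to the lexicographically
    smallest index tuple.  Limited to <= 20 sets.
    """
    member_sets = [s.members if isinstance(s, Region) else frozenset(s) for s in sets]
    universe = frozenset(universe)
    if len(member_sets) > 20:
        raise ValueError("brute-force cover limited to 20 sets")
    if not universe <= frozenset().union(*member_sets, frozenset()):
        raise ValueError("sets do not cover the universe")
    for k in range(1, len(member_sets) + 1):
        for combo in itertools.combinations(range(len(member_sets)), k):
            if universe <= frozenset().union(*(member_sets[i] for i in combo)):
                return list(combo)
    raise AssertionError("unreachable")  # pragma: no cover


def hypergeom_oracle(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Exact-test p-value by direct enumeration with rational arithmetic.

    Enumerates every feasible 2x2 table with the observed margins; the
    two-sided p sums probabilities <= the observed one, 'greater' sums
    the upper tail.  Independent of scipy.
    """
    n_total = table.total
    n_changed = table.a + table.c
    n_region = table.a + table.b
    k_min = max(0, n_region - (n_total - n_changed))
    k_max = min(n_region, n_changed)
    denom = math.comb(n_total, n_region)
    pmf = {
        k: Fraction(math.comb(n_changed, k) * math.comb(n_total - n_changed, n_region - k), denom)
        for k in range(k_min, k_max + 1)
    }
    observed = pmf[table.a]
    if alternative == "greater":
        p = sum(p_k for k, p_k in pmf.items() if k >= table.a)
    elif alternative == "two-sided":
        p = sum(p_k for p_k in pmf.values() if p_k <= observed)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(Fraction(1), p))
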