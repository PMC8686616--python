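"""Spatial enrichment testing of binary abundance-change flags.

Each protein family in the structure may be encoded by several paralogs;
abundance measurements live at the paralog level.  A region's paralogs
are all paralogs of the families whose node belongs to the region.  For
each region a 2x2 contingency table (changed/unchanged x in/out of
region) over the full paralog universe is tested with the exact
hypergeometric (Fisher) test; the null hypothesis is that changed
paralogs are scattered randomly across the complex.  Raw p-values are
Bonferroni-adjusted by the number of regions tested.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from structnet.region_sampling import Region, RegionSet

__all__ = [
    "CRATable",
    "ContingencyTable",
    "EnrichmentResult",
    "EnrichmentReport",
    "load_cra",
    "region_contingency",
    "exact_test",
    "bonferroni",
    "test_regions",
    "test_assigned",
]

ALTERNATIVES = ("two-sided", "greater")


@dataclass(frozen=True)
class CRATable:
    """Binary change-in-relative-abundance table over paralogs.

    entries: paralog name -> (family name, changed flag in {0, 1}).
    Family names must match the node names of the proximity graph.
    """

    entries: Mapping[str, tuple[str, int]]

    def __post_init__(self) -> None:
        for paralog, (family, flag) in self.entries.items():
            if flag not in (0, 1):
                raise ValueError(f"flag for paralog {paralog!r} must be 0 or 1, got {flag!r}")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]]) -> "CRATable":
        return cls({p: (f, int(c)) for p, f, c in records})

    @property
    def families(self) -> frozenset:
        return frozenset(f for f, _ in self.entries.values())

    @property
    def n_paralogs(self) -> int:
        return len(self.entries)

    @property
    def n_changed(self) -> int:
        return sum(flag for _, flag in self.entries.values())

    @property
    def baseline_fraction(self) -> float:
        """Fraction of all paralogs flagged changed (baseline enrichment)."""
        return self.n_changed / self.n_paralogs if self.entries else 0.0

    def paralogs_of(self, families: Iterable[str]) -> list[str]:
        fams = set(families)
        return sorted(p for p, (f, _) in self.entries.items() if f in fams)

    def restrict_to_families(self, families: Iterable[str]) -> "CRATable":
        """Drop paralogs whose family is absent from ``families`` (e.g. not
        resolved in the structure), with a warning."""
        fams = set(families)
        missing = sorted(self.families - fams)
        if missing:
            warnings.warn(
                f"{len(missing)} families in the table are absent from the structure "
                f"and were dropped: {missing[:8]}{'...' if len(missing) > 8 else ''}",
                stacklevel=2,
            )
        kept = {p: e for p, e in self.entries.items() if e[0] in fams}
        return CRATable(kept)

    def with_flags(self, changed_paralogs: Iterable[str]) -> "CRATable":
        """Same universe, flags rebuilt from an explicit changed-name set."""
        changed = set(changed_paralogs)
        return CRATable({p: (f, int(p in changed)) for p, (f, _) in self.entries.items()})


def load_cra(path: str | Path) -> CRATable:
    """Read a delimited table with columns paralog, family, changed.

    Tab- or comma-separated; the delimiter is sniffed.  Flags must be
    exactly 0 or 1; anything else is rejected naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"paralog", "family", "changed"}
    if not required <= set(df.columns):
        raise ValueError(
            f"CRA table {path} must have columns {sorted(required)}, found {list(df.columns)}"
        )
    records = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        raw = str(getattr(row, "changed")).strip()
        if raw not in ("0", "1"):
            raise ValueError(f"non-binary changed flag {raw!r} in {path} row {row_number}")
        records.append((str(row.paralog).strip(), str(row.family).strip(), int(raw)))
    paralogs = [p for p, _, _ in records]
    if len(set(paralogs)) != len(paralogs):
        dups = sorted({p for p in paralogs if paralogs.count(p) > 1})
        raise ValueError(f"duplicate paralog names in {path}: {dups}")
    return CRATable.from_records(records)


def save_cra(table: CRATable, path: str | Path) -> Path:
    path = Path(path)
    rows = [(p, f, c) for p, (f, c) in sorted(table.entries.items())]
    pd.DataFrame(rows, columns=["paralog", "family", "changed"]).to_csv(path, sep="\t", index=False)
    return path


@dataclass(frozen=True)
class ContingencyTable:
    """Counts: a changed-in-region, b unchanged-in-region, c changed-out,
    d unchanged-out; all at the paralog level."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative contingency count: {self}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def region_contingency(region: Region, cra: CRATable) -> ContingencyTable:
    """2x2 counts of changed/unchanged paralogs inside/outside a region.

    Families in the region that are missing from the table are warned
    about and skipped; the universe is every paralog in the table.
    """
    if len(region.members) == 0:
        raise ValueError("empty region")
    missing = sorted(set(region.members) - set(cra.families))
    if missing:
        warnings.warn(
            f"region {region.start_node}: families missing from CRA table, skipped: {missing}",
            stacklevel=2,
        )
    in_paralogs = set(cra.paralogs_of(region.members))
    a = b = c = d = 0
    for paralog, (_, flag) in cra.entries.items():
        inside = paralog in in_paralogs
        if inside and flag:
            a += 1
        elif inside:
            b += 1
        elif flag:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def exact_test(table: ContingencyTable, alternative: str = "two-sided") -> float:
    """Exact hypergeometric (Fisher) p-value for a 2x2 table.

    'two-sided' sums the probabilities of all tables with fixed margins
    that are as or less probable than the observed one; 'greater' tests
    pure enrichment of changed paralogs inside the region.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    _, p = stats.fisher_exact(table.as_array(), alternative=alternative)
    return float(p)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p), m = number of tests."""
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("m must be >= 1")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {p}")
    return [min(1.0, m * p) for p in p_values]


@dataclass(frozen=True)
class EnrichmentResult:
    region: Region
    table: ContingencyTable
    p: float
    p_adj: float
    m: int

    @property
    def region_fraction(self) -> float:
        in_region = self.table.a + self.table.b
        return self.table.a / in_region if in_region else 0.0


@dataclass(frozen=True)
class EnrichmentReport:
    """All per-region results plus the shared baseline, sorted by p_adj."""

    results: tuple[EnrichmentResult, ...]
    baseline_fraction: float
    alternative: str
    alpha: float = 0.05

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    @property
    def significant(self) -> tuple[EnrichmentResult, ...]:
        return tuple(r for r in self.results if r.p_adj < self.alpha)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "region": r.region.start_node,
                    "members": " ".join(sorted(r.region.members)),
                    "a": r.table.a,
                    "b": r.table.b,
                    "c": r.table.c,
                    "d": r.table.d,
                    "p": r.p,
                    "p_adj": r.p_adj,
                }
            )
        return pd.DataFrame(rows)


def test_regions(
    regions: RegionSet,
    cra: CRATable,
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> EnrichmentReport:
    """Test every region of a cover for enrichment of changed paralogs.

    One exact test per region; Bonferroni m equals the number of regions.
    Results are sorted by adjusted p-value (ties: raw p, then start node).
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    tables = [region_contingency(r, cra) for r in regions]
    ps = [exact_test(t, alternative) for t in tables]
    p_adjs = bonferroni(ps, m=len(regions))
    results = [
        EnrichmentResult(r, t, p, p_adj, len(regions))
        for r, t, p, p_adj in zip(regions, tables, ps, p_adjs)
    ]
    results.sort(key=lambda r: (r.p_adj, r.p, r.region.start_node))
    return EnrichmentReport(tuple(results), cra.baseline_fraction, alternative, alpha)


def _resolve_to_paralogs(names: Iterable[str], cra: CRATable) -> set[str]:
    """Accept paralog or family names; expand families to their paralogs."""
    by_family: dict[str, list[str]] = {}
    for p, (f, _) in cra.entries.items():
        by_family.setdefault(f, []).append(p)
    resolved: set[str] = set()
    unknown = []
    for name in names:
        if name in cra.entries:
            resolved.add(name)
        elif name in by_family:
            resolved.update(by_family[name])
        else:
            unknown.append(name)
    if unknown:
        raise ValueError(f"names not resolvable to paralogs or families: {sorted(unknown)}")
    return resolved


def test_assigned(
    regions: RegionSet,
    significant_names: Iterable[str],
    cra_universe: CRATable,
    region_ids: Sequence[str] | None = None,
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> EnrichmentReport:
    """Test user-selected regions against a manual list of changed proteins.

    Builds the binary vector from ``significant_names`` (paralog or family
    names) over the universe of ``cra_universe`` and tests the regions
    whose start node is in ``region_ids`` (all regions when None).
    """
    significant = _resolve_to_paralogs(significant_names, cra_universe)
    cra = cra_universe.with_flags(significant)
    if region_ids is None:
        selected = regions
    else:
        wanted = set(region_ids)
        picked = tuple(r for r in regions if r.start_node in wanted)
        unknown = wanted - {r.start_node for r in picked}
        if unknown:
            raise ValueError(f"unknown region ids: {sorted(unknown)}")
        selected = RegionSet(picked, frozenset().union(*(r.members for r in picked)), regions.params)
    return test_regions(selected, cra, alternative=alternative, alpha=alpha)


def format_significance(report: EnrichmentReport) -> str:
    """Human-readable verdict lines, one per tested region."""
    lines = [
        f"baseline changed fraction: {report.baseline_fraction:.4f} "
        f"({report.alternative} test, alpha={report.alpha})"
    ]
    for r in report:
        verdict = "SIGNIFICANT" if r.p_adj < report.alpha else "not significant"
        lines.append(
            f"region {r.region.start_node} ({len(r.region.members)} nodes): "
            f"a={r.table.a} b={r.table.b} c={r.table.c} d={r.table.d} "
            f"p={r.p:.3g} p_adj={r.p_adj:.3g} -> {verdict}"
        )
    return "\n".join(lines)
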