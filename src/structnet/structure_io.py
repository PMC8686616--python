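"""Reading, cleaning and splitting multi-protein complex structures.

Structures arrive as PDBx/mmCIF or legacy PDB files.  Only polymer protein
chains are retained: nucleic acids (rRNA/tRNA/mRNA), ions, waters and other
ligands are ignored, because the proximity analysis downstream treats the
complex as an interconnected array of proteins.  Chains can be renamed to
protein-family names (e.g. the universal rProtein scheme uL4, eS1) through
a user-supplied chain-to-name map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ProteinChain",
    "ComplexStructure",
    "parse_structure",
    "strip_nonstandard",
    "check_completeness",
    "reindex_residues",
    "write_entity_pdbs",
    "write_mmcif",
    "completeness_report",
    "load_name_map",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: name, element symbol, coordinates in Å, occupancy, flags."""

    name: str
    element: str
    coord: tuple[float, float, float]
    occupancy: float | None = None
    is_hetero: bool = False
    alt_loc: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate in atom {self.name}: {self.coord}")
        if self.occupancy is not None and not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy out of [0, 1] in atom {self.name}: {self.occupancy}")


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: sequence position, 3-letter code and its atoms."""

    seq_index: int
    residue_name: str
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError(f"residue {self.residue_name} {self.seq_index} has no atoms")

    @property
    def one_letter(self) -> str:
        info = gemmi.find_tabulated_residue(self.residue_name)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            return code if code.isalpha() else "X"
        return "X"


@dataclass(frozen=True)
class ProteinChain:
    """An ordered protein chain with per-residue atom coordinates."""

    chain_id: str
    protein_name: str
    residues: tuple[ResidueRecord, ...]

    @property
    def modeled_sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ComplexStructure:
    """A multi-protein complex: protein chains plus provenance."""

    chains: tuple[ProteinChain, ...]
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.chains) == 0:
            raise ValueError("structure has no protein chains")
        names = [c.protein_name for c in self.chains]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate protein names in structure: {dups}")

    @property
    def protein_names(self) -> tuple[str, ...]:
        return tuple(c.protein_name for c in self.chains)

    def chain(self, protein_name: str) -> ProteinChain:
        for c in self.chains:
            if c.protein_name == protein_name:
                return c
        raise KeyError(protein_name)


def load_name_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (chain_id, protein_name) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"name map {path} needs 2 columns (chain_id, protein_name)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _normalise_altloc(altloc: str) -> str:
    return "" if altloc in ("", "\x00", ".", "?") else altloc


def _is_amino_acid(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_amino_acid()


def parse_structure(
    path: str | Path,
    name_map: Mapping[str, str] | str | Path | None = None,
) -> ComplexStructure:
    """Parse an mmCIF/PDB file into a ComplexStructure of protein chains.

    One ProteinChain is produced per chain instance (auth asym id) that
    contains amino-acid residues; nucleic-acid chains, ions and waters are
    dropped.  ``name_map`` maps chain ids to protein family names; unmapped
    chains keep their chain id as name.  Duplicate copies of the same
    protein get numeric suffixes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(name_map, (str, Path)):
        name_map = load_name_map(name_map)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]

    chains: list[ProteinChain] = []
    seen_names: dict[str, int] = {}
    for chain in model:
        residues: list[ResidueRecord] = []
        for res in chain:
            if not _is_amino_acid(res.name):
                continue
            atoms = tuple(
                AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    is_hetero=(res.het_flag == "H"),
                    alt_loc=_normalise_altloc(atom.altloc),
                )
                for atom in res
            )
            if atoms:
                residues.append(ResidueRecord(res.seqid.num, res.name, atoms))
        if not residues:
            continue
        base = name_map.get(chain.name, chain.name) if name_map else chain.name
        n_prev = seen_names.get(base, 0)
        seen_names[base] = n_prev + 1
        name = base if n_prev == 0 else f"{base}_{n_prev + 1}"
        chains.append(ProteinChain(chain.name, name, tuple(residues)))

    if not chains:
        raise ValueError(f"no protein chains found in {path}")
    return ComplexStructure(tuple(chains), source_id=path.stem)


def strip_nonstandard(structure: ComplexStructure, keep_modified: bool = False) -> ComplexStructure:
    """Remove HETATM atoms and alternate-location duplicates.

    For alt-loc duplicates, exactly one atom per (residue, atom name) is
    kept: the highest-occupancy conformer, ties resolved by listing order.
    Residues left without atoms are dropped; chains left without residues
    are dropped.  With ``keep_modified`` the HETATM filter is disabled
    (retains modified residues recorded as hetero atoms).  Idempotent.
    """
    new_chains = []
    for chain in structure.chains:
        new_residues = []
        for res in chain.residues:
            atoms = res.atoms if keep_modified else tuple(a for a in res.atoms if not a.is_hetero)
            deduped: dict[str, AtomRecord] = {}
            for atom in atoms:
                prev = deduped.get(atom.name)
                if prev is None:
                    deduped[atom.name] = atom
                else:
                    occ_new = atom.occupancy if atom.occupancy is not None else 0.0
                    occ_old = prev.occupancy if prev.occupancy is not None else 0.0
                    if occ_new > occ_old:
                        deduped[atom.name] = atom
            if deduped:
                new_residues.append(replace(res, atoms=tuple(deduped.values())))
        if new_residues:
            new_chains.append(replace(chain, residues=tuple(new_residues)))
    if not new_chains:
        raise ValueError("no residues left after removing hetero atoms")
    return replace(structure, chains=tuple(new_chains))


def reindex_residues(chain: ProteinChain) -> ProteinChain:
    """Renumber residues consecutively 1..n, preserving order.

    Deposited models often have gaps in author numbering where density was
    missing; downstream geometry only needs a dense index.
    """
    new = tuple(replace(res, seq_index=i) for i, res in enumerate(chain.residues, start=1))
    return replace(chain, residues=new)


def _local_alignment_coverage(modeled: str, reference: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(reference, modeled)[0]
    ref_aligned = sum(end - start for start, end in alignment.aligned[0])
    return 100.0 * ref_aligned / len(reference)


def check_completeness(chain: ProteinChain | str, reference: str) -> float:
    """Percent of the reference sequence covered by the modeled sequence.

    Strategy: exact substring match first; otherwise best local alignment,
    counting aligned reference positions, with a warning (modeled chains
    with internal breaks or sequence conflicts land here).
    Returns a value in [0, 100].
    """
    modeled = chain if isinstance(chain, str) else chain.modeled_sequence
    reference = reference.strip().upper()
    if not reference:
        raise ValueError("empty reference sequence")
    modeled = modeled.strip().upper()
    if not modeled:
        return 0.0
    if modeled in reference:
        return 100.0 * len(modeled) / len(reference)
    coverage = _local_alignment_coverage(modeled, reference)
    warnings.warn(
        "modeled sequence is not a contiguous block of the reference; "
        f"reporting best local alignment coverage ({coverage:.1f}%)",
        stacklevel=2,
    )
    return coverage


def completeness_report(
    structure: ComplexStructure,
    references: Mapping[str, str],
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Coverage of each chain against its reference sequence, as a table.

    ``references`` maps protein names to reference sequences (e.g. read
    from FASTA via Bio.SeqIO).  Chains without a reference are reported
    with NaN coverage.  If ``out`` is given the table is written as TSV.
    """
    rows = []
    for chain in structure.chains:
        ref = references.get(chain.protein_name)
        rows.append(
            {
                "protein_name": chain.protein_name,
                "modeled_len": len(chain),
                "reference_len": len(ref) if ref else pd.NA,
                "percent": check_completeness(chain, ref) if ref else pd.NA,
            }
        )
    df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(out, sep="\t", index=False)
    return df


def to_gemmi(structure: ComplexStructure) -> gemmi.Structure:
    """Convert to a gemmi Structure (for writing mmCIF / PDB)."""
    st = gemmi.Structure()
    st.name = structure.source_id or "structnet"
    model = gemmi.Model(1)
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.residue_name
            gres.seqid = gemmi.SeqId(res.seq_index, " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coord)
                gatom.occ = atom.occupancy if atom.occupancy is not None else 1.0
                if atom.alt_loc:
                    gatom.altloc = atom.alt_loc
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_mmcif(structure: ComplexStructure, path: str | Path) -> Path:
    """Write the structure as a minimal PDBx/mmCIF file."""
    path = Path(path)
    to_gemmi(structure).make_mmcif_document().write_file(str(path))
    return path


def write_entity_pdbs(structure: ComplexStructure, outdir: str | Path) -> list[Path]:
    """Write one PDB file per protein chain, named by protein name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for chain in structure.chains:
        single = ComplexStructure((chain,), source_id=structure.source_id)
        path = outdir / f"{chain.protein_name}.pdb"
        to_gemmi(single).write_pdb(str(path))
        paths.append(path)
    return paths
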