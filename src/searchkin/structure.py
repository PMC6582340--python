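"""Residue-level model of a protein-DNA complex, read from PDB/mmCIF.

Only what the similarity-index calculation needs is kept: heavy-atom
coordinates grouped by residue, a protein/DNA classification, a
base-vs-backbone split for DNA atoms, and an integer point charge per
protein residue (-1, 0 or +1, set by :func:`assign_charges`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import gemmi
import numpy as np

from .errors import (
    ChargeSchemeError,
    NoDNAError,
    NoProteinError,
    StructureParseError,
)

__all__ = [
    "AtomRecord", "Residue", "ResidueId", "StructureModel",
    "CHARGE_SCHEMES", "read_structure", "assign_charges",
    "write_similarity_table",
]

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: common modified residues mapped to their standard parent
MODIFIED_PARENT = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "HYP": "PRO", "KCX": "LYS", "CME": "CYS", "PCA": "GLU",
}

DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DU", "DI",
                "A", "C", "G", "U", "I"}  # incl. ribo variants

#: sugar-phosphate atoms of a nucleotide; every other heavy atom is base
DNA_BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "OP3", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'",
    "C2'", "O2'", "C1'",
}

#: residue charge schemes: name -> {residue: charge}; unlisted residues are 0
CHARGE_SCHEMES = {
    "default": {"LYS": 1, "ARG": 1, "ASP": -1, "GLU": -1},
    "his+1": {"LYS": 1, "ARG": 1, "HIS": 1, "ASP": -1, "GLU": -1},
}


class ResidueId(NamedTuple):
    """Unique residue key: (chain, sequence number, insertion code)."""

    chain: str
    seq_number: int
    insertion_code: str


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class Residue:
    """One residue with its heavy atoms and (for protein) a point charge."""

    chain: str
    seq_number: int
    insertion_code: str
    name: str
    atoms: tuple[AtomRecord, ...]
    is_dna: bool
    charge: int = 0

    @property
    def rid(self) -> ResidueId:
        return ResidueId(self.chain, self.seq_number, self.insertion_code)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) heavy-atom coordinates in Angstrom."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def base_atoms(self) -> tuple[AtomRecord, ...]:
        """Base-moiety atoms of a DNA residue (everything not backbone)."""
        if not self.is_dna:
            return ()
        return tuple(a for a in self.atoms
                     if a.name not in DNA_BACKBONE_ATOMS)

    def label(self) -> str:
        icode = self.insertion_code.strip()
        return f"{self.chain}:{self.name}{self.seq_number}{icode}"


@dataclass(frozen=True)
class StructureModel:
    """Protein and DNA residues of one model of one complex."""

    protein_residues: tuple[Residue, ...]
    dna_residues: tuple[Residue, ...]
    source_id: str
    model_number: int = 1
    charge_scheme: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_residues:
            raise NoProteinError(
                f"{self.source_id}: no protein residues in the selection")
        if not self.dna_residues:
            raise NoDNAError(
                f"{self.source_id}: no DNA residues in the selection")
        ids = [r.rid for r in self.protein_residues + self.dna_residues]
        if len(ids) != len(set(ids)):
            raise StructureParseError(
                f"{self.source_id}: duplicate residue identifiers")

    def protein(self, rid: ResidueId) -> Residue:
        for r in self.protein_residues:
            if r.rid == rid:
                return r
        raise KeyError(rid)

    def replace_protein_residue(self, rid: ResidueId,
                                new: Residue) -> "StructureModel":
        out = tuple(new if r.rid == rid else r for r in self.protein_residues)
        return replace(self, protein_residues=out)


def _dedupe_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties to the first listed."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    # preserve file order of first appearance
    seen, ordered = set(), []
    for atom in res:
        if atom.name not in seen:
            seen.add(atom.name)
            ordered.append(best[atom.name])
    return ordered


def _convert_residue(chain_name: str, res: gemmi.Residue,
                     is_dna: bool) -> Residue:
    atoms = tuple(
        AtomRecord(a.name, a.element.name.upper(),
                   a.pos.x, a.pos.y, a.pos.z)
        for a in _dedupe_altloc(res) if not a.is_hydrogen())
    icode = res.seqid.icode.strip()
    return Residue(chain=chain_name, seq_number=res.seqid.num,
                   insertion_code=icode, name=res.name.upper(),
                   atoms=atoms, is_dna=is_dna)


def read_structure(path: str, *, protein_chains: Iterable[str] | None = None,
                   dna_chains: Iterable[str] | None = None,
                   model: int = 1) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Residues are classified by name: the 20 standard amino acids (plus a
    small table of modified residues mapped to their parent) are protein;
    DA/DC/DG/DT/DU and ribo variants are DNA.  Waters and other hetero
    residues are dropped; alternate locations resolve to the highest
    occupancy (ties to the first listed); only the requested model (first
    by default) is read.

    ``protein_chains`` / ``dna_chains`` restrict which chains are
    considered for each class; ``None`` auto-detects by residue content.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    index = min(model, len(st)) - 1
    gmodel = st[index]
    pchains = set(protein_chains) if protein_chains is not None else None
    dchains = set(dna_chains) if dna_chains is not None else None

    protein: list[Residue] = []
    dna: list[Residue] = []
    for chain in gmodel:
        for res in chain:
            name = res.name.upper()
            if name in ("HOH", "DOD", "WAT"):
                continue
            parent = MODIFIED_PARENT.get(name, name)
            if parent in STANDARD_AMINO_ACIDS:
                if pchains is not None and chain.name not in pchains:
                    continue
                converted = _convert_residue(chain.name, res, is_dna=False)
                if parent != name:
                    converted = replace(converted, name=parent)
                protein.append(converted)
            elif parent in DNA_RESIDUES:
                if dchains is not None and chain.name not in dchains:
                    continue
                dna.append(_convert_residue(chain.name, res, is_dna=True))
            elif len(res) > 3:  # non-trivial hetero residue worth flagging
                warnings.warn(
                    f"{path}: dropping unrecognized residue {name} "
                    f"({chain.name}{res.seqid.num})", stacklevel=2)
    return StructureModel(protein_residues=tuple(protein),
                          dna_residues=tuple(dna),
                          source_id=str(path), model_number=index + 1)


def assign_charges(s: StructureModel,
                   scheme: str = "default") -> StructureModel:
    """Return a copy of ``s`` with integer charges set on protein residues.

    The default scheme puts +1 on LYS/ARG, -1 on ASP/GLU and 0 elsewhere
    (histidine neutral); ``"his+1"`` additionally protonates HIS.
    Coordinates and residue counts are untouched.
    """
    if scheme not in CHARGE_SCHEMES:
        raise ChargeSchemeError(
            f"unknown charge scheme {scheme!r}; "
            f"known: {sorted(CHARGE_SCHEMES)}")
    table = CHARGE_SCHEMES[scheme]
    protein = tuple(replace(r, charge=table.get(r.name, 0))
                    for r in s.protein_residues)
    return replace(s, protein_residues=protein, charge_scheme=scheme)


def write_similarity_table(result, path) -> None:
    """Write a per-residue chi table as TSV.

    Columns: chain, seq_number, residue_name, chi_i, n_neighbors; rows
    ordered by (chain, seq_number, insertion code); a final ``PROTEIN_CHI``
    row carries the protein-level average.  Output is byte-stable for
    identical inputs.
    """
    rows = sorted(result.per_residue.items())
    with open(path, "w", newline="\n") as fh:
        fh.write("chain\tseq_number\tresidue_name\tchi_i\tn_neighbors\n")
        for rid, entry in rows:
            fh.write(f"{rid.chain}\t{rid.seq_number}\t{entry.residue_name}\t"
                     f"{entry.chi_i:.17g}\t{entry.n_neighbors}\n")
        fh.write(f"PROTEIN_CHI\t\t\t{result.chi:.17g}\t{len(rows)}\n")
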