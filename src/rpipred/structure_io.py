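"""Reading protein-RNA complex structures and extracting per-chain records.

Complexes arrive as PDB-format text. Each polymer chain is reduced to a
:class:`ChainRecord` holding its one-letter sequence, its per-residue atom
coordinates (used later for the inter-chain contact test) and, optionally, a
per-residue structure string (protein-block letters for proteins, secondary
structure element classes for RNA).

DNA and hybrid chains are recognised but flagged ``dna``/``unknown`` so the
pairing stage can reject them; the predictor concerns RNA-protein pairs only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1_extended

__all__ = [
    "Atom",
    "Residue",
    "ChainRecord",
    "ComplexRecord",
    "EmptyComplexError",
    "read_complex",
    "write_fasta",
]

PROTEIN = "protein"
RNA = "rna"

# Ribonucleotide residue names, including common modified parents.
_RNA_RES = {"A": "A", "U": "U", "C": "C", "G": "G", "I": "N", "N": "N"}
_DNA_RES = {"DA", "DT", "DC", "DG", "DU", "DI", "DN"}

_MOD_RNA = {
    "PSU": "U", "5MU": "U", "4SU": "U", "H2U": "U", "OMU": "U", "UR3": "U",
    "1MA": "A", "2MA": "A", "MA6": "A", "6MA": "A", "OMA": "A", "A2M": "A",
    "5MC": "C", "OMC": "C", "4OC": "C", "CCC": "C",
    "1MG": "G", "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "YG": "G",
    "G7M": "G", "QUO": "G",
}


class EmptyComplexError(ValueError):
    """Raised when a structure file contains no polymer chains."""


@dataclass(frozen=True)
class Atom:
    """A single atom: label, element and Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("coords must be 3 finite components")
        object.__setattr__(self, "coords", c)


@dataclass
class Residue:
    name: str
    one_letter: str
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class ChainRecord:
    """One macromolecular chain of a complex.

    ``structure_string``, when set, is a per-residue code string the same
    length as ``sequence``: protein-block letters (a-p, Z unassigned) for
    proteins, secondary-structure element classes (S/H/L/B/I) for RNA.
    """

    complex_id: str
    chain_id: str
    kind: str
    sequence: str
    residues: list[Residue] = field(default_factory=list)
    structure_string: str | None = None

    def __post_init__(self) -> None:
        if self.residues and len(self.sequence) != len(self.residues):
            raise ValueError(
                f"chain {self.chain_id}: sequence length {len(self.sequence)} "
                f"!= residue count {len(self.residues)}"
            )
        if self.structure_string is not None and len(self.structure_string) != len(self.sequence):
            raise ValueError(
                f"chain {self.chain_id}: structure string length mismatch"
            )
        if self.kind == RNA and not set(self.sequence) <= set("AUCGN"):
            raise ValueError(f"chain {self.chain_id}: invalid RNA alphabet")

    @property
    def fasta_id(self) -> str:
        return f"{self.complex_id}_{self.chain_id}"

    def atom_coords(self) -> np.ndarray:
        """All atom coordinates of the chain as an (n, 3) array."""
        pts = [a.coords for r in self.residues for a in r.atoms]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ComplexRecord:
    complex_id: str
    chains: list[ChainRecord]

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in complex {self.complex_id}")

    def chain(self, chain_id: str) -> ChainRecord:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    def by_kind(self, kind: str) -> list[ChainRecord]:
        return [c for c in self.chains if c.kind == kind]


def _residue_identity(resname: str) -> tuple[str, str]:
    """Map a residue name to (kind, one-letter code).

    Unmappable residues become X (protein) / N (RNA); the feature encoder
    skips those letters, so unknown chemistry is kept in the sequence but
    never counted.
    """
    resname = resname.strip()
    if resname in _RNA_RES:
        return RNA, _RNA_RES[resname]
    if resname in _MOD_RNA:
        return RNA, _MOD_RNA[resname]
    if resname in _DNA_RES:
        return "dna", "N"
    if resname in protein_letters_3to1_extended:
        one = protein_letters_3to1_extended[resname]
        return PROTEIN, one if len(one) == 1 and one.isalpha() else "X"
    if len(resname) == 3:  # unknown three-letter code: assume modified aa
        return PROTEIN, "X"
    return "unknown", "X"


def read_complex(path: str | Path) -> ComplexRecord:
    """Parse a PDB file into a :class:`ComplexRecord`.

    Polymer chains are classified protein/RNA by majority residue vocabulary;
    waters and free ligands are dropped. Only the first alternate location of
    each atom is kept (Biopython default), so the contact test sees a single
    conformer.
    """
    path = Path(path)
    complex_id = path.stem.lower()
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(complex_id, str(path))
    model = next(structure.get_models())

    chains: list[ChainRecord] = []
    for chain in model:
        kinds: list[str] = []
        letters: list[str] = []
        residues: list[Residue] = []
        for res in chain:
            hetflag = res.id[0]
            if hetflag == "W":
                continue
            kind, one = _residue_identity(res.get_resname())
            # HETATM residues that are not recognised polymers are ligands
            if hetflag != " " and res.get_resname() not in _MOD_RNA and kind == "unknown":
                continue
            if hetflag != " " and kind == PROTEIN and res.get_resname() not in protein_letters_3to1_extended:
                continue
            kinds.append(kind)
            letters.append(one)
            atoms = [
                Atom(a.get_name(), (a.element or "").strip() or a.get_name()[0], a.get_coord())
                for a in res.get_atoms()
            ]
            residues.append(Residue(res.get_resname(), one, atoms))
        if not residues:
            continue
        counts = {k: kinds.count(k) for k in set(kinds)}
        kind = max(counts, key=counts.get)
        if kind not in (PROTEIN, RNA):
            warnings.warn(
                f"{complex_id} chain {chain.id}: {kind} chain excluded from pairing"
            )
        seq = "".join(letters)
        if kind == RNA:
            seq = "".join(c if c in "AUCG" else "N" for c in seq)
        chains.append(
            ChainRecord(
                complex_id=complex_id,
                chain_id=chain.id,
                kind=kind,
                sequence=seq,
                residues=residues,
            )
        )

    polymer = [c for c in chains if c.kind in (PROTEIN, RNA)]
    if not polymer:
        raise EmptyComplexError(f"{path}: no protein or RNA polymer chains found")
    return ComplexRecord(complex_id=complex_id, chains=polymer)


def write_fasta(chains: list[ChainRecord], path: str | Path) -> None:
    """Write chains as FASTA with ``complex-id_chain-id`` headers."""
    if not chains:
        raise ValueError("no chains to write")
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f">{c.fasta_id}\n{c.sequence}\n")
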