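"""Reading and writing protein structures (PDB format).

The internal model is deliberately small: an ordered chain of residues,
each carrying its alpha-carbon position and the list of heavy atoms.
Author numbering, insertion codes and alternate conformations are
resolved at parse time; everywhere else in the package residues are
addressed by a dense 0-based sequence index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: one-letter -> three-letter residue names used when writing PDB output
_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


class PDBParseError(ValueError):
    """Raised when a file yields no usable residues or the chain is absent."""


@dataclass
class Atom:
    """A single heavy atom: label, element symbol and position in Angstroms."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element")


@dataclass
class Residue:
    """One amino acid: dense sequence index, one-letter type, CA and heavy atoms."""

    seq_index: int
    aa_type: str
    ca: np.ndarray
    heavy_atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)


@dataclass
class ProteinStructure:
    """An ordered amino-acid chain with optional hierarchical labels.

    ``label`` is a (family, superfamily, fold) triple in the style of the
    SCOP hierarchy; it is only consulted by classification / retrieval
    evaluation and by labeled pivot selection.
    """

    id: str
    residues: list[Residue]
    label: Optional[tuple[str, str, str]] = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("a structure needs at least one residue")
        for k, r in enumerate(self.residues):
            if r.seq_index != k:
                raise ValueError("residues must be densely renumbered 0..n-1")
        self._ca = None
        self._heavy = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of alpha-carbon positions (cached)."""
        if self._ca is None:
            self._ca = np.array([r.ca for r in self.residues], dtype=float)
        return self._ca

    def heavy_atom_table(self) -> tuple[np.ndarray, np.ndarray]:
        """All heavy-atom coordinates with their owning residue index (cached)."""
        if self._heavy is None:
            coords, owner = [], []
            for r in self.residues:
                for a in r.heavy_atoms:
                    coords.append(a.coords)
                    owner.append(r.seq_index)
            self._heavy = (np.array(coords, dtype=float), np.array(owner, dtype=int))
        return self._heavy

    @property
    def sequence(self) -> str:
        return "".join(r.aa_type for r in self.residues)


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> list[gemmi.Atom]:
    """Collapse alternate conformations: per atom name keep the highest
    occupancy, ties resolved by file order."""
    chosen: dict[str, gemmi.Atom] = {}
    for a in atoms:
        prev = chosen.get(a.name)
        if prev is None or a.occ > prev.occ:
            chosen[a.name] = a
    # preserve file order of the winners
    winners = set(id(a) for a in chosen.values())
    return [a for a in atoms if id(a) in winners]


def read_pdb_structure(path: str | Path, chain_id: Optional[str] = None) -> ProteinStructure:
    """Parse one chain of a PDB file into a :class:`ProteinStructure`.

    Only the first model is read.  Amino acids (including HETATM parents
    such as MSE, mapped to their one-letter code) are kept; hydrogens and
    non-amino-acid heteroatoms are discarded.  Residues without an
    alpha-carbon are dropped with a warning.  Remaining residues are
    renumbered densely in file order, which is the sequence order used by
    every downstream computation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models")
    model = st[0]
    chain = None
    if chain_id is None:
        if len(model) == 0:
            raise PDBParseError(f"{path}: no chains")
        chain = model[0]
    else:
        for ch in model:
            if ch.name == chain_id:
                chain = ch
                break
        if chain is None:
            raise PDBParseError(f"{path}: chain {chain_id!r} not found")

    residues: list[Residue] = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        one = info.one_letter_code.upper()
        if not one.isalpha():
            one = "X"
        atoms = _pick_altloc(list(res))
        heavy = [
            Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
            for a in atoms
            if a.element.name not in ("H", "D")
        ]
        ca = next((a for a in heavy if a.name == "CA"), None)
        if ca is None:
            logger.warning("%s: residue %s %s has no alpha-carbon; dropped", path.name, res.seqid, res.name)
            continue
        residues.append(Residue(len(residues), one, ca.coords.copy(), heavy))

    if not residues:
        raise PDBParseError(f"{path}: no parseable amino-acid residues")
    return ProteinStructure(path.stem if chain_id is None else f"{path.stem}_{chain_id}", residues)


def write_pdb_structure(structure: ProteinStructure, path: str | Path, transform: Optional[tuple[np.ndarray, np.ndarray]] = None) -> None:
    """Write a structure as a single-chain PDB file.

    ``transform`` optionally applies a rigid motion ``x -> R x + t``
    to every atom before writing.
    """
    R, t = (np.eye(3), np.zeros(3)) if transform is None else transform
    st = gemmi.Structure()
    st.name = structure.id
    mdl = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for r in structure.residues:
        res = gemmi.Residue()
        res.name = _AA3.get(r.aa_type, "UNK")
        res.seqid = gemmi.SeqId(r.seq_index + 1, " ")
        res.het_flag = "A"
        for a in r.heavy_atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.occ = 1.0
            x, y, z = R @ a.coords + t
            ga.pos = gemmi.Position(x, y, z)
            res.add_atom(ga)
        ch.add_residue(res)
    mdl.add_chain(ch)
    st.add_model(mdl)
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True)))


def write_alignment(alignment, structures, path_prefix: str | Path) -> dict[str, Path]:
    """Write a structure alignment to disk.

    Produces three files under ``path_prefix``:

    * ``<prefix>.pairs.tsv`` -- aligned residue index pairs with their
      post-superposition CA distances,
    * ``<prefix>.query_superposed.pdb`` -- the query rotated/translated
      into the target frame,
    * ``<prefix>.summary.json`` -- TM-score, cover (%) and aligned RMSD.

    ``structures`` is the (query, target) pair the alignment refers to.
    """
    query, target = structures
    if len(alignment.pairs) == 0:
        raise ValueError("empty alignment")
    for i, j in alignment.pairs:
        if not (0 <= i < len(query) and 0 <= j < len(target)):
            raise ValueError(f"alignment pair ({i}, {j}) out of range")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sup = alignment.superposition
    tsv = prefix.with_name(prefix.name + ".pairs.tsv")
    with open(tsv, "w") as fh:
        fh.write("query_index\ttarget_index\tdistance_A\n")
        for (i, j), d in zip(alignment.pairs, alignment.distances):
            fh.write(f"{i}\t{j}\t{d:.4f}\n")
    pdb = prefix.with_name(prefix.name + ".query_superposed.pdb")
    write_pdb_structure(query, pdb, transform=(sup.rotation, sup.translation))
    summary = prefix.with_name(prefix.name + ".summary.json")
    with open(summary, "w") as fh:
        json.dump(
            {
                "query": query.id,
                "target": target.id,
                "tm_score": alignment.tm_score,
                "cover_pct": alignment.cover,
                "rmsd_aligned_A": alignment.rmsd_aligned,
                "n_pairs": len(alignment.pairs),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return {"pairs": tsv, "pdb": pdb, "summary": summary}
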