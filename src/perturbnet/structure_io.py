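"""Read and write protein 3D coordinates with an explicit atom-filtering policy.

The rest of the package works on a minimal in-memory :class:`Structure`:
an ordered list of residues, each identified by (chain, number, insertion
code) and holding the 3D coordinates of its atoms.  Which atoms enter the
model is controlled by ``atom_policy`` because downstream contact counts
depend on it: structures emitted by mutagenesis engines may carry hydrogens
that the deposited wild type lacks, and mixing the two conventions would
change edge weights.  The default policy is ``heavy`` (drop hydrogens).

Only standard amino-acid residues are kept; waters, ligands and other
hetero records never enter a Structure.  For alternate locations the
first-listed conformer is used, and only the first model of a multi-model
file is read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = [
    "ResidueID",
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "EmptyStructureError",
    "ATOM_POLICIES",
    "read_structure",
    "write_structure",
    "list_chains",
    "STANDARD_AA3",
    "AA3_TO_1",
    "AA1_TO_3",
]

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

ATOM_POLICIES = ("heavy", "all", "calpha")


class StructureError(ValueError):
    """A coordinate file could not be parsed or violates model assumptions."""


class EmptyStructureError(StructureError):
    """No residues survived parsing and filtering."""


@dataclass(frozen=True, order=True)
class ResidueID:
    """Identifies a residue by chain, sequence number and insertion code.

    Ordering is lexicographic by (chain, number, icode).  The amino-acid
    type is deliberately not part of the identity, so a mutated residue
    keeps its ID and wild-type/mutant structures can be matched node by
    node.
    """

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:42" or "A:42B"
        return f"{self.chain}:{self.number}{self.icode}"


@dataclass(frozen=True)
class Atom:
    name: str
    coord: tuple[float, float, float]
    element: str = ""


@dataclass
class Residue:
    rid: ResidueID
    resname: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Structure:
    """Ordered residues with atom coordinates (Ångstroms)."""

    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def residue_ids(self) -> list[ResidueID]:
        return [r.rid for r in self.residues]

    def get(self, rid: ResidueID) -> Residue:
        for r in self.residues:
            if r.rid == rid:
                return r
        raise KeyError(rid)

    def validate(self) -> None:
        seen: set[ResidueID] = set()
        for r in self.residues:
            if r.rid in seen:
                raise StructureError(f"duplicate residue {r.rid}")
            seen.add(r.rid)
            if not r.atoms:
                raise StructureError(f"residue {r.rid} has no atoms")
            if not np.isfinite(r.coords).all():
                raise StructureError(f"non-finite coordinates in {r.rid}")


def _is_hydrogen(atom) -> bool:
    elem = (atom.element or "").strip().upper()
    if elem:
        return elem in ("H", "D")
    return atom.get_name().lstrip("0123456789").upper().startswith(("H", "D"))


def _keep_atom(atom, policy: str) -> bool:
    if policy == "all":
        return True
    if policy == "heavy":
        return not _is_hydrogen(atom)
    if policy == "calpha":
        return atom.get_name().strip() == "CA"
    raise ValueError(f"unknown atom_policy {policy!r}; choose from {ATOM_POLICIES}")


def read_structure(
    path: str | Path,
    atom_policy: str = "heavy",
    chains: Iterable[str] | None = None,
) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Parameters
    ----------
    path:
        PDB file with fixed-width ATOM records.
    atom_policy:
        ``heavy`` (default, hydrogens excluded), ``all``, or ``calpha``
        (alpha carbons only).
    chains:
        Restrict to these chain identifiers; all chains if None.

    Raises
    ------
    StructureError
        If the file cannot be parsed or a requested chain is absent.
    EmptyStructureError
        If no residue survives filtering.
    """
    if atom_policy not in ATOM_POLICIES:
        raise ValueError(f"unknown atom_policy {atom_policy!r}; choose from {ATOM_POLICIES}")
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio_structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(bio_structure)
    if not models:
        raise EmptyStructureError(f"no models in {path}")
    model = models[0]  # first model only

    wanted = set(chains) if chains is not None else None
    present = {ch.id for ch in model}
    if wanted is not None and not wanted <= present:
        missing = sorted(wanted - present)
        raise StructureError(f"chains {missing} not present in {path}")

    residues: list[Residue] = []
    for chain in model:
        if wanted is not None and chain.id not in wanted:
            continue
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():  # waters and hetero records
                continue
            if res.get_resname().strip() not in STANDARD_AA3:
                continue
            atoms = []
            for atom in res.get_unpacked_list():
                # keep the first-listed conformer only
                altloc = atom.get_altloc().strip()
                if altloc and atom is not _first_conformer(res, atom.get_name()):
                    continue
                if not _keep_atom(atom, atom_policy):
                    continue
                x, y, z = (float(v) for v in atom.get_coord())
                atoms.append(Atom(atom.get_name().strip(), (x, y, z),
                                  (atom.element or "").strip()))
            if atoms:
                rid = ResidueID(chain.id, int(resseq), icode.strip())
                residues.append(Residue(rid, res.get_resname().strip(), atoms))

    structure = Structure(residues)
    if not structure.residues:
        raise EmptyStructureError(f"no residues left after filtering {path}")
    structure.validate()
    return structure


def _first_conformer(res, name: str):
    """First-listed altloc conformer for a (possibly disordered) atom name."""
    entry = res.child_dict.get(name)
    if entry is None:
        return None
    if entry.is_disordered():
        return entry.disordered_get_list()[0]
    return entry


def list_chains(structure: Structure) -> list[str]:
    """Unique chain identifiers in file order."""
    seen: list[str] = []
    for res in structure:
        if res.rid.chain not in seen:
            seen.append(res.rid.chain)
    return seen


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-width PDB ATOM records (3-decimal coords)."""
    path = Path(path)
    lines = []
    serial = 1
    for res in structure:
        for atom in res.atoms:
            name = atom.name
            # names of <= 3 chars start in column 14 per the fixed layout
            field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
            elem = atom.element or name.lstrip("0123456789")[:1]
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {field} {res.resname:>3s} {res.rid.chain:1s}"
                f"{res.rid.number:4d}{res.rid.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {elem.upper():>2s}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
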