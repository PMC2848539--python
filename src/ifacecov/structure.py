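"""Two-chain complex structures: in-memory model plus PDB reading and writing.

Residue identity is (residue_number, insertion_code) in author numbering and
is preserved verbatim through every operation, so model and native residues
stay matchable by number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser

from .errors import StructureError

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "ComplexStructure",
    "read_pdb",
    "write_pdb",
    "three_to_one",
]

#: residue_name (upper-case 3-letter) -> 1-letter code for the 20 standard residues
_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}

_HYDROGEN_ELEMENTS = {"H", "D"}


def three_to_one(resname: str) -> str:
    """Map a 3-letter residue name to a 1-letter code; non-standard -> 'X'."""
    return _THREE_TO_ONE.get(resname.strip().upper(), "X")


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.position):
            raise StructureError(
                f"non-finite coordinate for atom {self.atom_name} "
                f"{self.chain_id}/{self.residue_number}"
            )

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class Residue:
    number: int
    insertion_code: str
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def res_id(self) -> tuple[int, str]:
        return (self.number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.res_id for r in self.residues]
        if len(ids) != len(set(ids)):
            raise StructureError(f"duplicate residue identifiers in chain {self.chain_id}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue_by_id(self, res_id: tuple[int, str]) -> Residue | None:
        for r in self.residues:
            if r.res_id == res_id:
                return r
        return None

    def atoms(self) -> Iterator[AtomRecord]:
        for r in self.residues:
            yield from r.atoms

    def coordinates(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array, residue order."""
        return np.array([a.position for a in self.atoms()], dtype=float).reshape(-1, 3)


@dataclass
class ComplexStructure:
    """A two-chain complex: exactly two ordered chains of residues."""

    id: str
    chains: tuple[Chain, Chain]

    def __post_init__(self):
        if len(self.chains) != 2:
            raise StructureError(f"complex {self.id}: expected exactly 2 chains")
        if self.chains[0].chain_id == self.chains[1].chain_id:
            raise StructureError(f"complex {self.id}: chain IDs must differ")

    @property
    def chain_ids(self) -> tuple[str, str]:
        return (self.chains[0].chain_id, self.chains[1].chain_id)

    @property
    def sequences(self) -> dict[str, str]:
        return {c.chain_id: c.sequence for c in self.chains}

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise StructureError(
            f"complex {self.id}: no chain {chain_id!r} (available: {self.chain_ids})"
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Return a copy with every atom position mapped to R @ x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        new_chains = []
        for c in self.chains:
            residues = []
            for r in c.residues:
                atoms = [
                    AtomRecord(
                        a.chain_id, a.residue_number, a.insertion_code,
                        a.residue_name, a.atom_name, a.element,
                        tuple(rotation @ a.xyz + translation),
                    )
                    for a in r.atoms
                ]
                residues.append(Residue(r.number, r.insertion_code, r.name, atoms))
            new_chains.append(Chain(c.chain_id, residues))
        return ComplexStructure(self.id, (new_chains[0], new_chains[1]))


def read_pdb(
    path,
    chain_ids: Sequence[str],
    complex_id: str | None = None,
    keep_hetatm: bool = False,
) -> ComplexStructure:
    """Read two selected chains from a PDB-format file.

    Hydrogens are dropped; for alternate locations the highest-occupancy
    conformer is kept (ties: first encountered); HETATM residues are skipped
    unless ``keep_hetatm`` is set. Non-standard residues map to 'X' in the
    derived sequence but are retained as residues.
    """
    if len(chain_ids) != 2:
        raise StructureError("exactly two chain IDs must be selected")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(complex_id or "complex", str(path))
    models = list(structure.get_models())
    if not models:
        raise StructureError(f"no ATOM records in {path}")
    model = models[0]
    available = [c.id for c in model]
    chains: list[Chain] = []
    n_atoms = 0
    for cid in chain_ids:
        if cid not in available:
            raise StructureError(
                f"chain {cid!r} not found; available chains: {sorted(available)}"
            )
        bio_chain = model[cid]
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, resnum, icode = bio_res.id
            if hetflag.strip() and not keep_hetatm:
                continue
            atoms: list[AtomRecord] = []
            for bio_atom in bio_res:
                # disordered atoms yield their highest-occupancy conformer
                if bio_atom.is_disordered():
                    bio_atom = bio_atom.selected_child
                element = (bio_atom.element or "").strip().upper()
                if element in _HYDROGEN_ELEMENTS:
                    continue
                atoms.append(
                    AtomRecord(
                        chain_id=cid,
                        residue_number=resnum,
                        insertion_code=icode.strip(),
                        residue_name=bio_res.resname.strip(),
                        atom_name=bio_atom.name.strip(),
                        element=element,
                        position=tuple(float(x) for x in bio_atom.coord),
                    )
                )
                n_atoms += 1
            if atoms:
                residues.append(Residue(resnum, icode.strip(), bio_res.resname.strip(), atoms))
        chains.append(Chain(cid, residues))
    if n_atoms == 0:
        raise StructureError(f"no ATOM records found for chains {tuple(chain_ids)}")
    return ComplexStructure(complex_id or "complex", (chains[0], chains[1]))


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: names shorter than 4 chars start in column 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(complex_structure: ComplexStructure, path) -> None:
    """Write a complex as PDB ATOM records (deterministic text output)."""
    lines = []
    serial = 1
    for chain in complex_structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                x, y, z = a.position
                lines.append(
                    f"ATOM  {serial:5d} {_format_atom_name(a.atom_name)} "
                    f"{a.residue_name:>3s} {chain.chain_id:1s}{res.number:4d}"
                    f"{a.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {a.element:>2s}"
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].name:>3s} "
                     f"{chain.chain_id:1s}{chain.residues[-1].number:4d}"
                     if chain.residues else "TER")
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random proper rotation matrix (via QR of a Gaussian)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
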