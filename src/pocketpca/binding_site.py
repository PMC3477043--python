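"""Structure parsing, ligand-contact extraction, and structure→alignment mapping.

The binding site is defined structurally: every residue of the protein with at
least one heavy (non-hydrogen) atom within a cutoff distance — 5.0 Å by
default, inclusive — of any heavy atom of the bound ligand. Residues are
identified by author (PDB) numbering throughout, and contacts are searched on
the ligand's own chain unless other chains are requested, so a site on one
subunit of a hetero-oligomer is not contaminated by neighbouring chains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .dataset_io import AlignmentBlock
from .errors import ContractError, MappingError, SelectionError, StructureParseError

_WATER = {"HOH", "DOD", "WAT", "H2O"}


@dataclass(frozen=True)
class Atom:
    """One atom with author-numbered residue identifiers."""

    serial: int
    name: str
    resname: str
    chain: str
    resnum: int
    icode: str
    x: float
    y: float
    z: float
    element: str
    occupancy: float = 1.0
    altloc: str = ""
    het: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.icode)


@dataclass(frozen=True)
class StructureModel:
    """A flat, immutable atom list (first model of a structure)."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not (np.isfinite(a.x) and np.isfinite(a.y) and np.isfinite(a.z)):
                raise ContractError(f"non-finite coordinates on atom {a.serial}")
            if not a.element:
                raise ContractError(f"empty element on atom {a.serial}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def select(
        self,
        chain: str | None = None,
        resnum: int | None = None,
        resname: str | None = None,
        atom_names: Sequence[str] | None = None,
        het: bool | None = None,
        heavy_only: bool = False,
    ) -> list[Atom]:
        """Atoms matching every given criterion."""
        names = set(atom_names) if atom_names is not None else None
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if resnum is not None and a.resnum != resnum:
                continue
            if resname is not None and a.resname != resname:
                continue
            if names is not None and a.name not in names:
                continue
            if het is not None and a.het != het:
                continue
            if heavy_only and not a.is_heavy:
                continue
            out.append(a)
        return out

    def residue(self, chain: str, resnum: int, icode: str = "") -> list[Atom]:
        atoms = [a for a in self.atoms if a.residue_key == (chain, resnum, icode)]
        if not atoms:
            raise SelectionError(f"no residue {chain}:{resnum}{icode}")
        return atoms

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Atoms grouped by residue, in file order."""
        groups: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            groups.setdefault(a.residue_key, []).append(a)
        return groups

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Apply a rigid-body transform x → R·x + t to all atoms."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new = []
        for a in self.atoms:
            x, y, z = R @ a.coord + t
            new.append(replace(a, x=float(x), y=float(y), z=float(z)))
        return StructureModel(atoms=tuple(new))


def parse_structure(path: str | Path, keep_waters: bool = False) -> StructureModel:
    """Parse a PDB file into a StructureModel.

    Reads ATOM and HETATM records of the first model; waters are excluded by
    default. For alternate-location groups, the highest-occupancy location is
    kept (ties: the first encountered).
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models found")
    atoms: list[Atom] = []
    serial = 0
    model = st[0]
    for chain in model:
        for residue in chain:
            if not keep_waters and residue.name.strip() in _WATER:
                continue
            het = residue.het_flag == "H"
            # altloc resolution: per atom name, keep max occupancy (first wins ties)
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    order.append(atom.name)
                elif atom.occ > prev.occ:
                    best[atom.name] = atom
            for name in order:
                atom = best[name]
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=atom.name,
                        resname=residue.name.strip(),
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        element=atom.element.name,
                        occupancy=atom.occ,
                        altloc=(atom.altloc or "").strip(),
                        het=het,
                    )
                )
    return StructureModel(atoms=tuple(atoms))


def write_pdb(model: StructureModel, path: str | Path | None = None) -> str:
    """Serialize a StructureModel as PDB text (and optionally write it)."""
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        record = "HETATM" if a.het else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{i:5d} {name}{a.altloc or ' ':1s}{a.resname:>3s} "
            f"{a.chain[:1]:1s}{a.resnum:4d}{a.icode or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element.upper():>2s}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass(frozen=True)
class ContactResidue:
    chain: str
    resnum: int
    resname: str
    min_distance: float


@dataclass(frozen=True)
class ContactSet:
    """Ligand-contact residues sorted by residue number."""

    residues: tuple[ContactResidue, ...]
    cutoff: float
    ligand: str

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def residue_numbers(self) -> list[int]:
        return [r.resnum for r in self.residues]


def _find_ligand_atoms(model: StructureModel, ligand) -> list[Atom]:
    chain, sel = ligand
    atoms = []
    for a in model.atoms:
        if not a.het or a.chain != chain:
            continue
        if isinstance(sel, int):
            if a.resnum == sel:
                atoms.append(a)
        elif a.resname == str(sel):
            atoms.append(a)
    return atoms


def extract_contact_residues(
    model: StructureModel,
    ligand: tuple[str, str | int],
    cutoff: float = 5.0,
    chains: Sequence[str] | None = None,
) -> ContactSet:
    """Residues with ≥1 heavy atom within ``cutoff`` (inclusive) of any ligand heavy atom.

    ``ligand`` is (chain, residue name or residue number) and must select at
    least one HETATM residue. Hydrogens are ignored on both sides. Contacts
    are searched on the ligand's own chain unless ``chains`` is given.
    """
    if cutoff <= 0:
        raise ContractError(f"cutoff must be positive, got {cutoff}")
    ligand_atoms = [a for a in _find_ligand_atoms(model, ligand) if a.is_heavy]
    if not ligand_atoms:
        raise SelectionError(f"ligand selector {ligand!r} matched no HETATM atoms")
    ligand_keys = {a.residue_key for a in ligand_atoms}
    search_chains = set(chains) if chains is not None else {ligand[0]}

    candidates = [
        a
        for a in model.atoms
        if a.is_heavy and a.chain in search_chains and a.residue_key not in ligand_keys
    ]
    if not candidates:
        return ContactSet(residues=(), cutoff=cutoff, ligand=f"{ligand[0]}:{ligand[1]}")

    tree = cKDTree(np.array([a.coord for a in ligand_atoms]))
    dists, _ = tree.query(np.array([a.coord for a in candidates]), k=1)

    best: dict[tuple[str, int, str], tuple[float, str]] = {}
    for a, d in zip(candidates, dists):
        key = a.residue_key
        if key not in best or d < best[key][0]:
            best[key] = (float(d), a.resname)
    hits = [
        ContactResidue(chain=key[0], resnum=key[1], resname=resname, min_distance=d)
        for key, (d, resname) in best.items()
        if d <= cutoff
    ]
    hits.sort(key=lambda r: (r.chain, r.resnum))
    return ContactSet(residues=tuple(hits), cutoff=cutoff, ligand=f"{ligand[0]}:{ligand[1]}")


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from structure residue numbers to alignment columns via a reference row."""

    mapping: dict[int, int]
    reference_id: str

    def column(self, resnum: int) -> int:
        try:
            return self.mapping[resnum]
        except KeyError:
            raise MappingError(f"residue {resnum} not mapped") from None


def map_residues_to_columns(
    residues: ContactSet | Iterable[int],
    alignment: AlignmentBlock,
    reference_id: str,
    reference_numbering_offset: int = 1,
) -> ColumnMap:
    """Map author residue numbers to alignment columns through a reference row.

    Non-gap positions of the reference row are numbered consecutively starting
    at ``reference_numbering_offset``; each requested residue number maps to
    the column whose reference residue carries that number. Residues that fall
    on a gap or outside the reference are reported together in a MappingError.
    """
    numbers = residues.residue_numbers if isinstance(residues, ContactSet) else list(residues)
    ref_row = alignment.row(reference_id)
    number_to_col: dict[int, int] = {}
    n = reference_numbering_offset
    for col, letter in enumerate(ref_row):
        if letter != "-":
            number_to_col[n] = col
            n += 1
    missing = [r for r in numbers if r not in number_to_col]
    if missing:
        raise MappingError(
            f"residue number(s) {missing} not resolvable in reference {reference_id!r} "
            f"(numbering starts at {reference_numbering_offset})"
        )
    return ColumnMap(
        mapping={r: number_to_col[r] for r in numbers}, reference_id=reference_id
    )
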