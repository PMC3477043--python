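"""Geometric operators for structural-consequence analysis.

These operators turn the qualitative structural reasoning about binding-site
substitutions into reproducible geometric facts: in-silico point mutation with
idealized side-chain geometry, χ1 rotamer enumeration, hydrogen-bond and
salt-bridge detection from heavy-atom geometry, three-residue hydrophobic
staples, and helix i→i+4 backbone hydrogen bonding. No energies are computed
— every output is a distance, an angle, or a boolean derived from them.

Hydrogen-bond criterion: donor–acceptor (N/O) heavy-atom distance ≤ 3.5 Å and
donor-antecedent–donor–acceptor angle ≥ 120°. Hydrogen positions are never
required (crystal and electron-diffraction structures at modest resolution
lack them). Salt bridges use charged-nitrogen to carboxylate-oxygen distance
≤ 4.0 Å; hydrophobic staples use side-chain carbon–carbon distance ≤ 5.0 Å.
All cutoffs are arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .binding_site import Atom, StructureModel
from .errors import ContractError, GeometryError, SelectionError

BACKBONE = ("N", "CA", "C", "O")

# ---------------------------------------------------------------------------
# internal coordinate machinery


def vec_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, in (−180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihed: float
) -> np.ndarray:
    """Place atom D so that |D−c| = bond, angle(b,c,D) = angle, dihedral(a,b,c,D) = dihed.

    The natural-extension reference frame construction used by all internal
    side-chain and backbone builders.
    """
    ang, tor = np.radians(angle), np.radians(dihed)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise GeometryError("collinear reference atoms; frame undefined")
    n /= norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# idealized side-chain templates
#
# Each entry: atom name, element, reference atom names (a, b, c), bond length
# to c (Å), angle b-c-atom (deg), and dihedral a-b-c-atom. The dihedral is
# either an absolute number, "chi1", or ("chi1", offset). Distal dihedrals
# (χ2 and beyond) use ideal anti/planar values: only χ1 is a free variable.

_CHI1 = "chi1"
_T = dict  # brevity in the table below

SIDECHAIN_TEMPLATES: dict[str, list[dict]] = {
    "ALA": [],
    "SER": [_T(name="OG", element="O", refs=("N", "CA", "CB"), bond=1.417, angle=110.8, dihed=_CHI1)],
    "CYS": [_T(name="SG", element="S", refs=("N", "CA", "CB"), bond=1.808, angle=114.4, dihed=_CHI1)],
    "THR": [
        _T(name="OG1", element="O", refs=("N", "CA", "CB"), bond=1.433, angle=109.5, dihed=_CHI1),
        _T(name="CG2", element="C", refs=("N", "CA", "CB"), bond=1.521, angle=110.5, dihed=(_CHI1, -120.0)),
    ],
    "VAL": [
        _T(name="CG1", element="C", refs=("N", "CA", "CB"), bond=1.521, angle=110.5, dihed=_CHI1),
        _T(name="CG2", element="C", refs=("N", "CA", "CB"), bond=1.521, angle=110.5, dihed=(_CHI1, 122.0)),
    ],
    "ILE": [
        _T(name="CG1", element="C", refs=("N", "CA", "CB"), bond=1.530, angle=110.4, dihed=_CHI1),
        _T(name="CG2", element="C", refs=("N", "CA", "CB"), bond=1.521, angle=110.5, dihed=(_CHI1, -122.0)),
        _T(name="CD1", element="C", refs=("CA", "CB", "CG1"), bond=1.513, angle=113.8, dihed=180.0),
    ],
    "LEU": [
        _T(name="CG", element="C", refs=("N", "CA", "CB"), bond=1.530, angle=116.3, dihed=_CHI1),
        _T(name="CD1", element="C", refs=("CA", "CB", "CG"), bond=1.521, angle=110.7, dihed=180.0),
        _T(name="CD2", element="C", refs=("CA", "CB", "CG"), bond=1.521, angle=110.7, dihed=60.0),
    ],
    "ASP": [
        _T(name="CG", element="C", refs=("N", "CA", "CB"), bond=1.516, angle=112.6, dihed=_CHI1),
        _T(name="OD1", element="O", refs=("CA", "CB", "CG"), bond=1.249, angle=118.4, dihed=0.0),
        _T(name="OD2", element="O", refs=("CA", "CB", "CG"), bond=1.249, angle=118.4, dihed=180.0),
    ],
    "ASN": [
        _T(name="CG", element="C", refs=("N", "CA", "CB"), bond=1.516, angle=112.6, dihed=_CHI1),
        _T(name="OD1", element="O", refs=("CA", "CB", "CG"), bond=1.231, angle=120.8, dihed=0.0),
        _T(name="ND2", element="N", refs=("CA", "CB", "CG"), bond=1.328, angle=116.4, dihed=180.0),
    ],
    "GLU": [
        _T(name="CG", element="C", refs=("N", "CA", "CB"), bond=1.520, angle=114.1, dihed=_CHI1),
        _T(name="CD", element="C", refs=("CA", "CB", "CG"), bond=1.516, angle=112.6, dihed=180.0),
        _T(name="OE1", element="O", refs=("CB", "CG", "CD"), bond=1.249, angle=118.4, dihed=0.0),
        _T(name="OE2", element="O", refs=("CB", "CG", "CD"), bond=1.249, angle=118.4, dihed=180.0),
    ],
    "GLN": [
        _T(name="CG", element="C", refs=("N", "CA", "CB"), bond=1.520, angle=114.1, dihed=_CHI1),
        _T(name="CD", element="C", refs=("CA", "CB", "CG"), bond=1.516, angle=112.6, dihed=180.0),
        _T(name="OE1", element="O", refs=("CB", "CG", "CD"), bond=1.231, angle=120.8, dihed=0.0),
        _T(name="NE2", element="N", refs=("CB", "CG", "CD"), bond=1.328, angle=116.4, dihed=180.0),
    ],
    "MET": [
        _T(name="CG", element="C", refs=("N", "CA", "CB"), bond=1.520, angle=114.1, dihed=_CHI1),
        _T(name="SD", element="S", refs=("CA", "CB", "CG"), bond=1.803, angle=112.7, dihed=180.0),
        _T(name="CE", element="C", refs=("CB", "CG", "SD"), bond=1.791, angle=100.9, dihed=180.0),
    ],
    "LYS": [
        _T(name="CG", element="C", refs=("N", "CA", "CB"), bond=1.520, angle=114.1, dihed=_CHI1),
        _T(name="CD", element="C", refs=("CA", "CB", "CG"), bond=1.520, angle=111.3, dihed=180.0),
        _T(name="CE", element="C", refs=("CB", "CG", "CD"), bond=1.508, angle=111.3, dihed=180.0),
        _T(name="NZ", element="N", refs=("CG", "CD", "CE"), bond=1.489, angle=111.5, dihed=180.0),
    ],
    "ARG": [
        _T(name="CG", element="C", refs=("N", "CA", "CB"), bond=1.520, angle=114.1, dihed=_CHI1),
        _T(name="CD", element="C", refs=("CA", "CB", "CG"), bond=1.520, angle=111.3, dihed=180.0),
        _T(name="NE", element="N", refs=("CB", "CG", "CD"), bond=1.461, angle=112.0, dihed=180.0),
        _T(name="CZ", element="C", refs=("CG", "CD", "NE"), bond=1.329, angle=124.2, dihed=180.0),
        _T(name="NH1", element="N", refs=("CD", "NE", "CZ"), bond=1.326, angle=120.0, dihed=0.0),
        _T(name="NH2", element="N", refs=("CD", "NE", "CZ"), bond=1.326, angle=120.0, dihed=180.0),
    ],
}

#: Residues whose side chain can be rebuilt from templates (no aromatic rings;
#: ring closure needs more than a chi1 scan and is out of scope here).
SUPPORTED_TARGETS = ("GLY",) + tuple(SIDECHAIN_TEMPLATES)

#: First side-chain heavy atom defining χ1 (N-CA-CB-γ), per residue type.
CHI1_GAMMA = {
    "SER": "OG", "THR": "OG1", "VAL": "CG1", "ILE": "CG1", "CYS": "SG",
    "LEU": "CG", "ASP": "CG", "ASN": "CG", "GLU": "CG", "GLN": "CG",
    "MET": "CG", "LYS": "CG", "ARG": "CG", "PHE": "CG", "TYR": "CG",
    "TRP": "CG", "HIS": "CG",
}

_CB_PARAMS = dict(bond=1.530, angle=110.5, dihed=122.6)  # refs N, C, CA (improper)

DEFAULT_CHI1 = -60.0  # most common rotameric state


def _coords(atoms: Sequence[Atom], names: Iterable[str]) -> dict[str, np.ndarray]:
    table = {a.name: a.coord for a in atoms}
    missing = [n for n in names if n not in table]
    if missing:
        raise GeometryError(f"missing atom(s) {missing} in residue {atoms[0].residue_key}")
    return table


def measure_chi1(residue_atoms: Sequence[Atom]) -> float:
    """χ1 dihedral (N-CA-CB-γ) of a residue, in degrees."""
    resname = residue_atoms[0].resname
    gamma = CHI1_GAMMA.get(resname)
    if gamma is None:
        raise ContractError(f"{resname} has no χ1 dihedral")
    pos = _coords(residue_atoms, ("N", "CA", "CB", gamma))
    return dihedral(pos["N"], pos["CA"], pos["CB"], pos[gamma])


def _build_sidechain(
    resname: str,
    pos: dict[str, np.ndarray],
    chi1: float,
) -> list[tuple[str, str, np.ndarray]]:
    """Idealized side-chain atoms (name, element, coord) beyond CB for ``resname``.

    ``pos`` must contain N, CA and (for non-Ala) CB; positions of previously
    built atoms are added as the chain extends.
    """
    built = []
    for entry in SIDECHAIN_TEMPLATES[resname]:
        dihed = entry["dihed"]
        if dihed == _CHI1:
            torsion = chi1
        elif isinstance(dihed, tuple):
            torsion = chi1 + dihed[1]
        else:
            torsion = dihed
        a, b, c = (pos[r] for r in entry["refs"])
        coord = place_atom(a, b, c, entry["bond"], entry["angle"], torsion)
        pos[entry["name"]] = coord
        built.append((entry["name"], entry["element"], coord))
    return built


def _ideal_cb(pos: dict[str, np.ndarray]) -> np.ndarray:
    return place_atom(
        pos["N"], pos["C"], pos["CA"],
        _CB_PARAMS["bond"], _CB_PARAMS["angle"], _CB_PARAMS["dihed"],
    )


def _replace_residue_atoms(
    model: StructureModel,
    key: tuple[str, int, str],
    new_atoms: list[Atom],
) -> StructureModel:
    out: list[Atom] = []
    inserted = False
    for a in model.atoms:
        if a.residue_key == key:
            if not inserted:
                out.extend(new_atoms)
                inserted = True
            continue
        out.append(a)
    return StructureModel(atoms=tuple(replace(a, serial=i + 1) for i, a in enumerate(out)))


def mutate_residue(
    model: StructureModel,
    site: tuple[str, int],
    new_resname: str,
    chi1: float | None = None,
) -> StructureModel:
    """Replace a residue's side chain with the idealized side chain of ``new_resname``.

    Backbone atoms are never moved. Shortening mutations (→ Gly/Ala) truncate
    and rename, keeping the original CB for Ala when present. Otherwise the
    original CB is kept (or built ideally if absent) and the new side chain is
    grown on it at the original residue's χ1 where the new type supports it;
    ``chi1`` overrides, and −60° is used when no χ1 is measurable.
    """
    new_resname = new_resname.upper()
    if new_resname not in SUPPORTED_TARGETS:
        raise GeometryError(
            f"cannot build {new_resname}: supported targets are {SUPPORTED_TARGETS}"
        )
    chain, resnum = site
    residue = model.residue(chain, resnum)
    names = {a.name for a in residue}
    if not set(("N", "CA", "C", "O")) <= names:
        raise GeometryError(f"residue {chain}:{resnum} lacks backbone atoms")
    old_resname = residue[0].resname
    if new_resname == old_resname and old_resname in ("GLY", "ALA"):
        return model  # identity truncation

    if chi1 is None:
        try:
            chi1 = measure_chi1(residue)
        except (ContractError, GeometryError):
            chi1 = DEFAULT_CHI1

    by_name = {a.name: a for a in residue}
    keep = [by_name[n] for n in BACKBONE if n in by_name]
    pos = {n: by_name[n].coord for n in ("N", "CA", "C")}

    new_atoms = [replace(a, resname=new_resname) for a in keep]
    template_atom = by_name["CA"]

    def _mk(name: str, element: str, coord: np.ndarray) -> Atom:
        return replace(
            template_atom,
            name=name,
            element=element,
            resname=new_resname,
            x=float(coord[0]),
            y=float(coord[1]),
            z=float(coord[2]),
            altloc="",
            occupancy=1.0,
        )

    if new_resname != "GLY":
        if "CB" in by_name:
            cb_atom = replace(by_name["CB"], resname=new_resname)
        else:
            cb_atom = _mk("CB", "C", _ideal_cb(pos))
        new_atoms.append(cb_atom)
        pos["CB"] = cb_atom.coord
        for name, element, coord in _build_sidechain(new_resname, pos, chi1):
            new_atoms.append(_mk(name, element, coord))
    return _replace_residue_atoms(model, residue[0].residue_key, new_atoms)


@dataclass(frozen=True)
class RotamerState:
    """One χ1 rotamer of a residue: the angle and the regenerated model."""

    chi1: float
    model: StructureModel
    sidechain_atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not -180.0 < self.chi1 <= 180.0:
            raise ContractError(f"χ1 {self.chi1} outside (−180, 180]")


def scan_chi1(
    model: StructureModel,
    site: tuple[str, int],
    angles: Sequence[float] = (-60.0, 60.0, 180.0),
) -> list[RotamerState]:
    """Enumerate χ1 rotamers of a residue, rebuilding its side chain ideally.

    The residue's own CB is kept; atoms beyond CB are regenerated from the
    idealized templates at each requested χ1. Gly/Ala (no χ1) and residue
    types without a rebuild template (aromatics, Pro) are contract errors.
    """
    chain, resnum = site
    residue = model.residue(chain, resnum)
    resname = residue[0].resname
    if resname in ("GLY", "ALA"):
        raise ContractError(f"{resname} has no χ1 to scan")
    if resname not in SIDECHAIN_TEMPLATES:
        raise ContractError(f"no idealized template for {resname}")
    states = []
    for ang in angles:
        ang = float(ang)
        if ang <= -180.0:
            ang += 360.0
        mutated = mutate_residue(model, site, resname, chi1=ang)
        side = tuple(
            a
            for a in mutated.residue(chain, resnum)
            if a.name not in BACKBONE and a.name != "CB"
        )
        states.append(RotamerState(chi1=ang, model=mutated, sidechain_atoms=side))
    return states


# ---------------------------------------------------------------------------
# interaction detectors


@dataclass(frozen=True)
class HBond:
    """A donor→acceptor hydrogen bond inferred from heavy-atom geometry."""

    donor: Atom
    acceptor: Atom
    distance: float
    angle: float  # donor-antecedent – donor – acceptor, degrees

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ContractError("non-positive H-bond distance")
        if not 0.0 <= self.angle <= 180.0:
            raise ContractError("H-bond angle outside [0, 180]")


def _antecedent(model: StructureModel, donor: Atom) -> Atom | None:
    """Nearest heavy atom in the donor's residue: the donor's covalent anchor."""
    best, best_d = None, np.inf
    for a in model.residue(*donor.residue_key):
        if a is donor or not a.is_heavy or a.name == donor.name:
            continue
        d = float(np.linalg.norm(a.coord - donor.coord))
        if d < best_d:
            best, best_d = a, d
    if best is None or best_d > 2.0:  # no plausible covalent neighbour
        return None
    return best


def find_hbonds(
    model: StructureModel,
    donors: Sequence[Atom],
    acceptors: Sequence[Atom],
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> list[HBond]:
    """Hydrogen bonds between donor and acceptor N/O atoms.

    A pair qualifies when the heavy-atom distance is ≤ ``d_max`` and the
    antecedent–donor–acceptor angle is ≥ ``angle_min``. Pairs within one
    residue are never reported.
    """
    donors = [a for a in donors if a.element.upper() in ("N", "O")]
    acceptors = [a for a in acceptors if a.element.upper() in ("N", "O")]
    if not donors or not acceptors:
        raise SelectionError("empty donor or acceptor selection")
    out = []
    for d in donors:
        ante = _antecedent(model, d)
        if ante is None:
            continue
        for a in acceptors:
            if a.residue_key == d.residue_key:
                continue
            dist = float(np.linalg.norm(a.coord - d.coord))
            if dist > d_max or dist < 2.2:  # beyond cutoff / covalent overlap
                continue
            ang = vec_angle(ante.coord, d.coord, a.coord)
            if ang >= angle_min:
                out.append(HBond(donor=d, acceptor=a, distance=dist, angle=ang))
    out.sort(key=lambda h: h.distance)
    return out


_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}
_ACIDIC_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}


@dataclass(frozen=True)
class SaltBridge:
    present: bool
    min_distance: float
    d_max: float


def find_salt_bridge(
    model: StructureModel,
    basic_site: tuple[str, int],
    acidic_site: tuple[str, int],
    d_max: float = 4.0,
) -> SaltBridge:
    """Ion-pair check: any charged N to carboxylate O distance ≤ ``d_max``."""
    basic = model.residue(*basic_site)
    acidic = model.residue(*acidic_site)
    b_names = _BASIC_ATOMS.get(basic[0].resname)
    a_names = _ACIDIC_ATOMS.get(acidic[0].resname)
    if b_names is None:
        raise ContractError(f"{basic[0].resname} is not a basic residue (Lys/Arg/His)")
    if a_names is None:
        raise ContractError(f"{acidic[0].resname} is not an acidic residue (Glu/Asp)")
    b_atoms = [a for a in basic if a.name in b_names]
    a_atoms = [a for a in acidic if a.name in a_names]
    if not b_atoms or not a_atoms:
        raise ContractError("charged-group atoms missing from one of the sites")
    dmin = min(
        float(np.linalg.norm(x.coord - y.coord)) for x in b_atoms for y in a_atoms
    )
    return SaltBridge(present=dmin <= d_max, min_distance=dmin, d_max=d_max)


@dataclass(frozen=True)
class StapleResult:
    present: bool
    pair_distances: dict[tuple[int, int], float]  # keyed by residue-number pair
    d_max: float


def find_hydrophobic_staple(
    model: StructureModel,
    sites: Sequence[tuple[str, int]],
    d_max: float = 5.0,
) -> StapleResult:
    """Three-center hydrophobic staple: all three pairwise minimum side-chain
    carbon–carbon distances ≤ ``d_max``."""
    if len(sites) != 3 or len(set(sites)) != 3:
        raise ContractError("exactly three distinct residues required")
    carbons = []
    for site in sites:
        atoms = model.residue(*site)
        if atoms[0].resname == "GLY":
            raise ContractError(f"Gly at {site} has no side-chain carbons")
        side_c = [
            a for a in atoms if a.element.upper() == "C" and a.name not in ("N", "CA", "C", "O", "OXT")
        ]
        if not side_c:
            raise ContractError(f"no side-chain carbon atoms at {site}")
        carbons.append(side_c)
    dists: dict[tuple[int, int], float] = {}
    present = True
    for i in range(3):
        for j in range(i + 1, 3):
            dmin = min(
                float(np.linalg.norm(x.coord - y.coord))
                for x in carbons[i]
                for y in carbons[j]
            )
            dists[(sites[i][1], sites[j][1])] = dmin
            present &= dmin <= d_max
    return StapleResult(present=present, pair_distances=dists, d_max=d_max)


@dataclass(frozen=True)
class HelixHBond:
    """One i→i+4 backbone hydrogen-bond test."""

    resnum_i: int
    resnum_i4: int
    satisfied: bool | None  # None when atoms are missing
    distance: float | None
    angle: float | None


@dataclass(frozen=True)
class HelixHBondTable:
    entries: tuple[HelixHBond, ...]

    @property
    def fraction_satisfied(self) -> float:
        tested = [e for e in self.entries if e.satisfied is not None]
        if not tested:
            return float("nan")
        return sum(e.satisfied for e in tested) / len(tested)


def helix_backbone_hbonds(
    model: StructureModel,
    chain: str,
    start: int,
    end: int,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> HelixHBondTable:
    """α-helical i→i+4 backbone hydrogen bonds over residues ``start..end``.

    For each i, tests O(i)···N(i+4) distance ≤ ``d_max`` with carbonyl angle
    C(i)-O(i)-N(i+4) ≥ ``angle_min``. Residues with missing backbone atoms
    yield a missing-flagged entry rather than a failure.
    """
    if end - start + 1 < 5:
        raise ContractError("range must span at least 5 residues")
    entries = []
    for i in range(start, end - 3):
        try:
            res_i = {a.name: a for a in model.residue(chain, i)}
            res_i4 = {a.name: a for a in model.residue(chain, i + 4)}
            o, c, n = res_i["O"], res_i["C"], res_i4["N"]
        except (SelectionError, KeyError):
            entries.append(HelixHBond(i, i + 4, None, None, None))
            continue
        dist = float(np.linalg.norm(n.coord - o.coord))
        ang = vec_angle(c.coord, o.coord, n.coord)
        entries.append(
            HelixHBond(i, i + 4, bool(dist <= d_max and ang >= angle_min), dist, ang)
        )
    return HelixHBondTable(entries=tuple(entries))
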