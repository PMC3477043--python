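"""Synthetic alignments with planted substitution modes, and structure fixtures.

The alignment generator emulates the structure of the binding-site dataset:
a consensus string plus *modes* — sets of position substitutions toggled
jointly per sequence with a Bernoulli probability — plus independent
per-position background substitution noise. The default study configuration
mirrors the two orthogonal axes seen in the real binding site: a two-position
co-varying mode (the Thr-23/Gly-26 fungal axis) and a one-position mode (the
Ser→Ala-277 axis), each toggled with probability 0.5 on a 14-position
consensus, with zero background noise unless requested. Ground-truth mode
membership is returned with every alignment, so recovery of the planted
contrasts by the leading principal components is directly measurable.

Phylogenetic correlation is deliberately absent: sequences are exchangeable
draws, which matches the exchangeability assumption of the covariance PCA
itself (a documented limitation of both).

The structure factory emits minimal valid PDB models for the geometric
operators: a ligand contact shell with planted distances, an ideal α-helix
(φ = −57°, ψ = −47°) or any other (φ, ψ) chain, a donor–acceptor pair with an
exact distance and antecedent angle, and a three-residue staple triangle with
exact pairwise side-chain distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .binding_site import Atom, StructureModel, write_pdb
from .dataset_io import AA20, ALPHABET
from .errors import SyntheticSpecError
from .structure_geometry import place_atom

# ---------------------------------------------------------------------------
# alignments


@dataclass(frozen=True)
class Mode:
    """A set of position substitutions toggled jointly with probability ``prob``."""

    substitutions: tuple[tuple[int, str], ...]
    prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise SyntheticSpecError(f"mode probability {self.prob} outside [0, 1]")
        if not self.substitutions:
            raise SyntheticSpecError("a mode needs at least one substitution")
        for pos, letter in self.substitutions:
            if letter not in ALPHABET:
                raise SyntheticSpecError(f"invalid substitution letter {letter!r}")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.substitutions)


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a planted-mode alignment."""

    n_sequences: int
    consensus: str
    modes: tuple[Mode, ...]
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise SyntheticSpecError("need at least one sequence")
        if not 0.0 <= self.noise < 1.0:
            raise SyntheticSpecError(f"noise rate {self.noise} outside [0, 1)")
        bad = set(self.consensus) - set(ALPHABET)
        if bad:
            raise SyntheticSpecError(f"invalid consensus symbol(s) {sorted(bad)}")
        seen: set[int] = set()
        for mode in self.modes:
            for pos, letter in mode.substitutions:
                if not 0 <= pos < len(self.consensus):
                    raise SyntheticSpecError(
                        f"mode position {pos} outside consensus of length {len(self.consensus)}"
                    )
                if pos in seen:
                    raise SyntheticSpecError(f"mode positions overlap at {pos}")
                if letter == self.consensus[pos]:
                    raise SyntheticSpecError(
                        f"substitution at {pos} equals the consensus letter {letter!r}"
                    )
                seen.add(pos)

    @property
    def n_positions(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class SyntheticAlignment:
    """Generated rows plus ground truth."""

    rows: tuple[str, ...]
    mode_membership: np.ndarray  # (n_sequences, n_modes) bool
    labels: tuple[str, ...]  # quadrant-style label per sequence (2-mode case: A–D)
    spec: SyntheticSpec


_TWO_MODE_LABELS = {(True, True): "A", (True, False): "B", (False, True): "C", (False, False): "D"}

#: Majority string of the bundled binding-site dataset (the group-C consensus).
DEFAULT_CONSENSUS = "EVDDHASFTSRRGL"


def paclitaxel_like_spec(
    n_sequences: int = 200,
    noise: float = 0.0,
    seed: int = 0,
    probs: tuple[float, float] = (0.5, 0.5),
) -> SyntheticSpec:
    """The default two-mode study configuration.

    Mode 1 plants the co-varying fungal-type pair (T at the position-23
    column, G at the position-26 column); mode 2 plants A at the position-277
    column. Both toggle independently with probability 0.5.
    """
    return SyntheticSpec(
        n_sequences=n_sequences,
        consensus=DEFAULT_CONSENSUS,
        modes=(
            Mode(substitutions=((1, "T"), (2, "G")), prob=probs[0]),
            Mode(substitutions=((9, "A"),), prob=probs[1]),
        ),
        noise=noise,
        seed=seed,
    )


def mode_contrast(spec: SyntheticSpec, mode_index: int) -> np.ndarray:
    """Unit channel-space contrast of a planted mode.

    +1 on each substituted letter's channel, −1 on the consensus letter's
    channel at the same position, normalized; the direction a perfect PCA
    recovers for that mode.
    """
    from .seqspace_pca import N_CHANNELS

    v = np.zeros(spec.n_positions * N_CHANNELS)
    for pos, letter in spec.modes[mode_index].substitutions:
        v[pos * N_CHANNELS + ALPHABET.index(letter)] = 1.0
        v[pos * N_CHANNELS + ALPHABET.index(spec.consensus[pos])] = -1.0
    return v / np.linalg.norm(v)


def generate_alignment(spec: SyntheticSpec) -> SyntheticAlignment:
    """Draw an alignment from a planted-mode specification (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n, P = spec.n_sequences, spec.n_positions
    n_modes = len(spec.modes)
    membership = np.zeros((n, n_modes), dtype=bool)
    for m, mode in enumerate(spec.modes):
        membership[:, m] = rng.random(n) < mode.prob

    rows = []
    aa_indices = {c: i for i, c in enumerate(AA20)}
    for i in range(n):
        letters = list(spec.consensus)
        for m, mode in enumerate(spec.modes):
            if membership[i, m]:
                for pos, letter in mode.substitutions:
                    letters[pos] = letter
        if spec.noise > 0.0:
            noise_mask = rng.random(P) < spec.noise
            for pos in np.flatnonzero(noise_mask):
                current = letters[pos]
                choices = [c for c in AA20 if c != current]
                letters[pos] = choices[int(rng.integers(len(choices)))]
        rows.append("".join(letters))

    if n_modes == 2:
        labels = tuple(_TWO_MODE_LABELS[(bool(a), bool(b))] for a, b in membership)
    else:
        labels = tuple(
            "+".join(f"m{m + 1}" for m in range(n_modes) if membership[i, m]) or "none"
            for i in range(n)
        )
    return SyntheticAlignment(rows=tuple(rows), mode_membership=membership, labels=labels, spec=spec)


def write_fasta(alignment: SyntheticAlignment, path) -> None:
    """Write generated rows as a FASTA alignment (ids carry the truth labels)."""
    from pathlib import Path

    lines = []
    for i, (row, label) in enumerate(zip(alignment.rows, alignment.labels)):
        lines.append(f">seq{i:04d}|{label}")
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# structure fixtures

_BACKBONE_GEOM = dict(
    n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231,
    ang_n_ca_c=111.2, ang_ca_c_n=116.2, ang_c_n_ca=121.7, ang_ca_c_o=120.8,
)


def _atom(serial, name, resname, chain, resnum, coord, element, het=False) -> Atom:
    return Atom(
        serial=serial, name=name, resname=resname, chain=chain, resnum=resnum,
        icode="", x=float(coord[0]), y=float(coord[1]), z=float(coord[2]),
        element=element, occupancy=1.0, altloc="", het=het,
    )


def _unit_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-spiral points on the sphere)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def _contact_shell(
    distances: Sequence[float],
    hydrogen_residues: Sequence[int] = (),
    chain: str = "A",
    ligand_resname: str = "LIG",
) -> StructureModel:
    """A one-atom ligand at the origin with single-atom residues at planted distances.

    Residues listed in ``hydrogen_residues`` (0-based index into ``distances``)
    get a hydrogen instead of a heavy atom, to exercise the heavy-atom rule.
    """
    if not distances:
        raise SyntheticSpecError("at least one residue distance required")
    if any(d <= 0 for d in distances):
        raise SyntheticSpecError("distances must be positive")
    atoms = [_atom(1, "C1", ligand_resname, chain, 900, (0.0, 0.0, 0.0), "C", het=True)]
    dirs = _unit_directions(len(distances))
    hydro = set(hydrogen_residues)
    for i, d in enumerate(distances):
        coord = dirs[i] * d
        if i in hydro:
            atoms.append(_atom(len(atoms) + 1, "H1", "GLY", chain, i + 1, coord, "H"))
        else:
            atoms.append(_atom(len(atoms) + 1, "CA", "GLY", chain, i + 1, coord, "C"))
    return StructureModel(atoms=tuple(atoms))


def _polypeptide(
    n_residues: int, phi: float = -57.0, psi: float = -47.0, chain: str = "A"
) -> StructureModel:
    """Ideal poly-Ala chain at fixed (φ, ψ), ω = 180°, built atom-by-atom."""
    if n_residues < 2:
        raise SyntheticSpecError("need at least 2 residues")
    g = _BACKBONE_GEOM
    # seed the first three backbone atoms in a plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g["n_ca"], 0.0, 0.0])
    # C0 in the xy-plane at the ideal N-CA-C angle
    c0 = ca0 + g["ca_c"] * np.array(
        [np.cos(np.radians(180.0 - g["ang_n_ca_c"])), np.sin(np.radians(180.0 - g["ang_n_ca_c"])), 0.0]
    )
    backbone = [(n0, ca0, c0)]
    for _ in range(1, n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, g["c_n"], g["ang_ca_c_n"], psi)
        ca_i = place_atom(ca_prev, c_prev, n_i, g["n_ca"], g["ang_c_n_ca"], 180.0)
        c_i = place_atom(c_prev, n_i, ca_i, g["ca_c"], g["ang_n_ca_c"], phi)
        backbone.append((n_i, ca_i, c_i))

    atoms: list[Atom] = []
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        resnum = i + 1
        # carbonyl O: anti to the next N (dihedral ψ + 180 about CA-C)
        o_i = place_atom(n_i, ca_i, c_i, g["c_o"], g["ang_ca_c_o"], psi + 180.0)
        cb_i = place_atom(n_i, c_i, ca_i, 1.530, 110.5, 122.6)
        for name, coord, element in (
            ("N", n_i, "N"), ("CA", ca_i, "C"), ("C", c_i, "C"), ("O", o_i, "O"), ("CB", cb_i, "C"),
        ):
            atoms.append(_atom(len(atoms) + 1, name, "ALA", chain, resnum, coord, element))
    return StructureModel(atoms=tuple(atoms))


def _hbond_pair(distance: float, angle: float, chain: str = "A") -> StructureModel:
    """A carbonyl donor (C–O) and an acceptor N at exact distance and antecedent angle."""
    if distance <= 0:
        raise SyntheticSpecError("distance must be positive")
    if not 0.0 < angle <= 180.0:
        raise SyntheticSpecError("angle must be in (0, 180]")
    c = np.array([-1.231, 0.0, 0.0])
    o = np.array([0.0, 0.0, 0.0])
    # place N so that angle(C, O, N) equals the request exactly
    n = o + distance * np.array([-np.cos(np.radians(angle)), np.sin(np.radians(angle)), 0.0])
    atoms = (
        _atom(1, "C", "GLY", chain, 1, c, "C"),
        _atom(2, "O", "GLY", chain, 1, o, "O"),
        _atom(3, "N", "GLY", chain, 2, n, "N"),
    )
    return StructureModel(atoms=atoms)


def _staple_triangle(
    d12: float, d13: float, d23: float, chain: str = "A", resnums: Sequence[int] = (217, 219, 278)
) -> StructureModel:
    """Three residues whose single side-chain carbons sit at exact pairwise distances."""
    for d in (d12, d13, d23):
        if d <= 0:
            raise SyntheticSpecError("distances must be positive")
    if d12 + d13 <= d23 or d12 + d23 <= d13 or d13 + d23 <= d12:
        raise SyntheticSpecError(
            f"triangle inequality violated by distances ({d12}, {d13}, {d23})"
        )
    p1 = np.array([0.0, 0.0, 0.0])
    p2 = np.array([d12, 0.0, 0.0])
    x = (d12**2 + d13**2 - d23**2) / (2 * d12)
    y2 = d13**2 - x**2
    p3 = np.array([x, np.sqrt(max(y2, 0.0)), 0.0])
    atoms: list[Atom] = []
    for resnum, p in zip(resnums, (p1, p2, p3)):
        ca = p + np.array([0.0, 0.0, 1.53])
        n = ca + np.array([1.46, 0.0, 0.0])
        atoms.append(_atom(len(atoms) + 1, "N", "LEU", chain, resnum, n, "N"))
        atoms.append(_atom(len(atoms) + 1, "CA", "LEU", chain, resnum, ca, "C"))
        atoms.append(_atom(len(atoms) + 1, "CB", "LEU", chain, resnum, p, "C"))
    return StructureModel(atoms=tuple(atoms))


def generate_structure_fixture(kind: str, **params) -> tuple[StructureModel, str]:
    """Build a named structure fixture; returns the model and its PDB text.

    Kinds: ``contact-shell`` (distances=[...], hydrogen_residues=[...]),
    ``ideal-helix`` (n_residues, phi, psi), ``extended-chain`` (n_residues),
    ``hbond-pair`` (distance, angle), ``staple-triangle`` (d12, d13, d23).
    """
    builders = {
        "contact-shell": _contact_shell,
        "ideal-helix": _polypeptide,
        "extended-chain": lambda n_residues, chain="A": _polypeptide(
            n_residues, phi=180.0, psi=180.0, chain=chain
        ),
        "hbond-pair": _hbond_pair,
        "staple-triangle": _staple_triangle,
    }
    if kind not in builders:
        raise SyntheticSpecError(f"unknown fixture kind {kind!r}; choose from {sorted(builders)}")
    model = builders[kind](**params)
    return model, write_pdb(model)
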