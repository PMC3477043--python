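"""Axis orientation, sensitivity-group partitioning, and sequence-logo matrices.

The sign of an eigenvector is arbitrary, so before the PC1–PC2 plane can be
read biologically both axes are anchored to observable sequence features:
PC1 is flipped, if necessary, so carriers of the fungal-type residues
(Thr at the position-23 column / Gly at the position-26 column by default)
have positive mean projection, and PC2 so Ser-277 carriers have positive mean
projection. Under that orientation the four sensitivity groups are the
quadrants: A = (+,+), B = (+,−), C = (−,+), D = (−,−); group C holds the
paclitaxel-sensitive sequences. Out-of-sample sequences (e.g. the human
isotype panel) are assigned by nearest group centroid, which is robust when a
sequence carries letters never seen in the fitting set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .dataset_io import AA20, GAP
from .errors import ContractError, OrientationError
from .seqspace_pca import EncodedMatrix, PCAModel

GROUPS = ("A", "B", "C", "D")
_QUADRANT = {(True, True): "A", (True, False): "B", (False, True): "C", (False, False): "D"}

MAX_IC_BITS = float(np.log2(20.0))


def orient_axes(
    model: PCAModel,
    encoded: EncodedMatrix,
    features: dict[int, Sequence[tuple[int, str]]],
) -> tuple[PCAModel, np.ndarray]:
    """Orient principal components against sequence features.

    ``features`` maps a PC index (1-based) to a list of (column, letter)
    pairs; a sequence *matches* the feature if it carries any listed letter at
    the listed column. Each PC is flipped, if needed, so the mean centered
    projection of matching sequences is positive. Returns the oriented model
    and the oriented centered projections of ``encoded`` for the listed PCs
    (columns in ascending PC order).
    """
    if encoded.labels != model.labels:
        raise ContractError("encoded matrix channels do not match the fitted model")
    eigvecs = model.eigenvectors.copy()
    flips: list[int] = []
    pcs = sorted(features)
    projections = np.empty((encoded.n_sequences, len(pcs)))
    for j, k in enumerate(pcs):
        pairs = list(features[k])
        if not pairs:
            raise OrientationError(f"no orientation feature given for PC{k}")
        mask = np.zeros(encoded.n_sequences, dtype=bool)
        for col, letter in pairs:
            mask |= encoded.matrix[:, encoded.channel(col, letter)] == 1.0
        if not mask.any():
            raise OrientationError(
                f"orientation feature for PC{k} ({pairs}) matches no sequences"
            )
        coord = (encoded.matrix - model.means) @ eigvecs[:, k - 1]
        if coord[mask].mean() < 0:
            eigvecs[:, k - 1] = -eigvecs[:, k - 1]
            coord = -coord
            flips.append(k)
        projections[:, j] = coord
    oriented = replace(
        model,
        eigenvectors=eigvecs,
        orientation_flips=tuple(flips),
        oriented=True,
    )
    return oriented, projections


@dataclass(frozen=True)
class GroupAssignment:
    """PC1/PC2 coordinates and sensitivity-group label for one sequence."""

    pc1: float
    pc2: float
    group: str
    method: str  # "quadrant" | "nearest-centroid"
    on_axis: bool = False  # quadrant method: point lay numerically on an axis

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ContractError(f"invalid group label {self.group!r}")
        if not (np.isfinite(self.pc1) and np.isfinite(self.pc2)):
            raise ContractError("non-finite projection coordinates")


def assign_quadrant(points, oriented: bool, axis_tol: float = 1e-12) -> list[GroupAssignment]:
    """Label points by PC1–PC2 quadrant: (+,+)→A, (+,−)→B, (−,+)→C, (−,−)→D.

    Points within ``axis_tol`` of an axis are labeled with the non-negative
    side and flagged ``on_axis``. Requires oriented projections (pass the
    model's ``oriented`` flag).
    """
    if not oriented:
        raise ContractError("quadrant assignment requires oriented projections")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ContractError("expected an (n, 2) array of PC1/PC2 coordinates")
    out = []
    for x, y in pts:
        on_axis = abs(x) < axis_tol or abs(y) < axis_tol
        x_pos = x > 0 or abs(x) < axis_tol  # on-axis points take the non-negative side
        y_pos = y > 0 or abs(y) < axis_tol
        out.append(GroupAssignment(pc1=float(x), pc2=float(y),
                                   group=_QUADRANT[(x_pos, y_pos)],
                                   method="quadrant", on_axis=bool(on_axis)))
    return out


def carrier_mask(encoded: EncodedMatrix, pairs: Sequence[tuple[int, str]]) -> np.ndarray:
    """Boolean mask of sequences carrying any of the (column, letter) features."""
    mask = np.zeros(encoded.n_sequences, dtype=bool)
    for col, letter in pairs:
        mask |= encoded.matrix[:, encoded.channel(col, letter)] == 1.0
    return mask


def assign_feature_seeded(
    points,
    carrier1: np.ndarray,
    carrier2: np.ndarray,
    max_iter: int = 100,
) -> list[GroupAssignment]:
    """Partition points into groups A–D by feature-seeded nearest-centroid clustering.

    Initial centroids are the means of the four cells of the 2×2
    presence/absence table of the two marker features (carrier of the PC1
    feature × carrier of the PC2 feature): A = both, B = PC1 feature only,
    C = PC2 feature only, D = neither. Plain Lloyd iterations then refine the
    partition to convergence, so a sequence that carries a marker but sits
    with a different cluster (its remaining substitutions dominate) ends up
    with its geometric cluster, not its marker cell. Deterministic; no
    randomness involved.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ContractError("expected an (n, 2) array of PC1/PC2 coordinates")
    carrier1 = np.asarray(carrier1, dtype=bool)
    carrier2 = np.asarray(carrier2, dtype=bool)
    if carrier1.shape != (len(pts),) or carrier2.shape != (len(pts),):
        raise ContractError("carrier masks must have one entry per point")
    cells = {
        "A": carrier1 & carrier2,
        "B": carrier1 & ~carrier2,
        "C": ~carrier1 & carrier2,
        "D": ~carrier1 & ~carrier2,
    }
    empty = [g for g, m in cells.items() if not m.any()]
    if empty:
        raise ContractError(f"feature cell(s) {empty} contain no sequences; cannot seed groups")
    centroids = np.stack([pts[cells[g]].mean(axis=0) for g in GROUPS])
    labels = None
    for _ in range(max_iter):
        dists = np.linalg.norm(pts[:, None, :] - centroids[None, :, :], axis=2)
        new_labels = dists.argmin(axis=1)
        if labels is not None and (new_labels == labels).all():
            break
        labels = new_labels
        for gi in range(4):
            member = labels == gi
            if member.any():  # empty cluster keeps its previous centroid
                centroids[gi] = pts[member].mean(axis=0)
    return [
        GroupAssignment(pc1=float(x), pc2=float(y), group=GROUPS[g], method="feature-seeded")
        for (x, y), g in zip(pts, labels)
    ]


def assign_scaled_centroid(
    points,
    training: Sequence[GroupAssignment],
    std_floor_fraction: float = 0.05,
) -> list[GroupAssignment]:
    """Label points by the nearest group in per-group standardized distance.

    Each training group contributes a mean and a per-axis standard deviation
    (floored at ``std_floor_fraction`` of the global training spread so tiny
    or single-member groups stay usable); a point joins the group minimizing
    sqrt(Σ((x−μ)/σ)²). Appropriate when group spreads are very unequal — a
    broad composite group should claim a moderately displaced point that a
    tight consensus cluster would reject. Ties go alphabetically.
    """
    if not training:
        raise ContractError("empty training assignment")
    tr_pts = np.array([[a.pc1, a.pc2] for a in training])
    global_std = np.maximum(tr_pts.std(axis=0), 1e-12)
    stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in sorted({a.group for a in training}):
        member = np.array([a.group == g for a in training])
        mu = tr_pts[member].mean(axis=0)
        sd = np.maximum(tr_pts[member].std(axis=0), std_floor_fraction * global_std)
        stats[g] = (mu, sd)
    names = sorted(stats)
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ContractError("expected an (n, 2) array of PC1/PC2 coordinates")
    out = []
    for p in pts:
        dists = [float(np.linalg.norm((p - stats[g][0]) / stats[g][1])) for g in names]
        group = names[int(np.argmin(dists))]
        out.append(GroupAssignment(pc1=float(p[0]), pc2=float(p[1]), group=group,
                                   method="scaled-centroid"))
    return out


def group_centroids(assignments: Iterable[GroupAssignment]) -> dict[str, np.ndarray]:
    """Mean PC1/PC2 coordinate of each group present in ``assignments``."""
    buckets: dict[str, list[np.ndarray]] = {}
    for a in assignments:
        buckets.setdefault(a.group, []).append(np.array([a.pc1, a.pc2]))
    return {g: np.mean(v, axis=0) for g, v in buckets.items()}


def assign_nearest_centroid(
    points, training: Sequence[GroupAssignment]
) -> list[GroupAssignment]:
    """Label points by Euclidean-nearest group centroid; distance ties go alphabetically."""
    if not training:
        raise ContractError("empty training assignment")
    centroids = group_centroids(training)
    for g in centroids:
        if centroids[g].shape != (2,):
            raise ContractError("malformed centroid")
    names = sorted(centroids)  # alphabetical order makes ties deterministic
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ContractError("expected an (n, 2) array of PC1/PC2 coordinates")
    out = []
    for x, y in pts:
        dists = [float(np.hypot(x - centroids[g][0], y - centroids[g][1])) for g in names]
        group = names[int(np.argmin(dists))]  # argmin takes the first = alphabetical on ties
        out.append(GroupAssignment(pc1=float(x), pc2=float(y), group=group,
                                   method="nearest-centroid"))
    return out


@dataclass(frozen=True)
class LogoMatrix:
    """Per-column letter frequencies and information content of an alignment.

    Frequencies are over the 20 amino acids (gaps excluded, reported as a
    per-column gap fraction). Information content is log2(20) minus the
    column's Shannon entropy in bits; letter heights apportion it by
    frequency. Columns holding only gaps have undefined (NaN) content.
    """

    frequencies: np.ndarray  # (n_columns, 20), rows sum to 1 (or 0 for all-gap)
    gap_fraction: np.ndarray  # (n_columns,)
    information: np.ndarray  # bits, NaN for all-gap columns
    n_sequences: int
    small_sample_correction: bool = False

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]

    @property
    def heights(self) -> np.ndarray:
        """Letter heights: frequency × column information content."""
        info = np.where(np.isnan(self.information), 0.0, self.information)
        return self.frequencies * info[:, None]

    def majority_letter(self, column: int) -> tuple[str, float]:
        """Most frequent amino acid in a column (ties: alphabetically first)."""
        row = self.frequencies[column]
        j = int(row.argmax())
        return AA20[j], float(row[j])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.frequencies, columns=list(AA20))
        df.insert(0, "column", np.arange(self.n_columns))
        df["gap_fraction"] = self.gap_fraction
        df["information_bits"] = self.information
        return df


def logo_matrix(rows: Sequence[str], small_sample_correction: bool = False) -> LogoMatrix:
    """Compute the sequence-logo matrix of aligned rows.

    The optional small-sample correction subtracts e_n = 19 / (2·ln 2·n) from
    each column's information content (n = non-gap count in that column),
    clipped at zero.
    """
    rows = [r if isinstance(r, str) else r.pbs_string for r in rows]
    if not rows:
        raise ContractError("at least one row required")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ContractError(f"rows have unequal lengths {sorted(widths)}")
    n_cols = widths.pop()
    counts = np.zeros((n_cols, 20))
    gaps = np.zeros(n_cols)
    lut = {c: i for i, c in enumerate(AA20)}
    for row in rows:
        for j, letter in enumerate(row):
            if letter == GAP:
                gaps[j] += 1
            else:
                counts[j, lut[letter]] += 1

    m = len(rows)
    non_gap = counts.sum(axis=1)
    freqs = np.zeros_like(counts)
    info = np.full(n_cols, np.nan)
    for j in range(n_cols):
        if non_gap[j] == 0:
            warnings.warn(f"column {j} contains only gaps; information content undefined")
            continue
        p = counts[j] / non_gap[j]
        freqs[j] = p
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic = MAX_IC_BITS - entropy
        if small_sample_correction:
            ic -= 19.0 / (2.0 * np.log(2.0) * non_gap[j])
        info[j] = max(ic, 0.0)
    return LogoMatrix(
        frequencies=freqs,
        gap_fraction=gaps / m,
        information=info,
        n_sequences=m,
        small_sample_correction=small_sample_correction,
    )


@dataclass(frozen=True)
class Transition:
    """A column where two groups' majority amino acids differ."""

    column: int
    letter_a: str
    letter_b: str
    weight: float  # product of the two majority frequencies


def dominant_transitions(logo_a: LogoMatrix, logo_b: LogoMatrix) -> list[Transition]:
    """Columns where the two logos' majority letters differ, strongest first.

    Strength is the product of the two majority frequencies, so near-fixed
    differences (e.g. a column that is essentially T in one group and V in
    the other) rank above noisy ones.
    """
    if logo_a.n_columns != logo_b.n_columns:
        raise ContractError(
            f"logo column counts differ: {logo_a.n_columns} vs {logo_b.n_columns}"
        )
    out = []
    for j in range(logo_a.n_columns):
        la, fa = logo_a.majority_letter(j)
        lb, fb = logo_b.majority_letter(j)
        if la != lb:
            out.append(Transition(column=j, letter_a=la, letter_b=lb, weight=fa * fb))
    out.sort(key=lambda t: (-t.weight, t.column))
    return out
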