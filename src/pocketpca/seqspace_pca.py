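"""One-hot sequence-space PCA of binding-site alignments.

Each alignment position is a 21-channel indicator block (20 amino acids in
alphabetical one-letter order, gap last), so an M-sequence, P-position
alignment becomes an M × N binary matrix with N = 21·P. The unbiased
variance–covariance matrix of the channels,

    C_kl = Σ_i (a_ik − ā_k)(a_il − ā_l) / (M − 1),

is diagonalized; its eigenvectors are collective substitution modes and the
eigenvalues their mean-square variation. Sequences are placed in mode space by
dot products with the leading eigenvectors.

Because each one-hot block sums to 1 for every sequence, the covariance rows
of a position block sum to zero, so every eigenvector with a nonzero
eigenvalue has zero component-sum within each block, and the rank is at most
min(M − 1, N − P).

Centering: projecting the raw binary vector a_i and projecting the centered
vector (a_i − ā) differ only by the constant ā·V_k, identical for every
sequence, so cluster structure is unaffected. The default is the centered
projection; ``centering="raw"`` gives the literal dot product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dataset_io import ALPHABET, AlignmentBlock, PBSRecord
from .errors import AlphabetError, ContractError, InsufficientDataError

N_CHANNELS = len(ALPHABET)  # 21: 20 amino acids + gap


def _as_rows(data) -> list[str]:
    if isinstance(data, AlignmentBlock):
        return list(data.rows)
    rows = []
    for item in data:
        if isinstance(item, PBSRecord):
            rows.append(item.pbs_string)
        elif isinstance(item, str):
            rows.append(item)
        else:
            raise ContractError(f"cannot encode object of type {type(item).__name__}")
    return rows


@dataclass(frozen=True)
class EncodedMatrix:
    """M × N one-hot matrix of an alignment (N = 21 · positions)."""

    matrix: np.ndarray
    labels: tuple[tuple[int, str], ...]  # (position index, letter) per channel
    n_positions: int

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    def channel(self, position: int, letter: str) -> int:
        """Flat channel index of (position, letter)."""
        if letter not in ALPHABET:
            raise AlphabetError(f"invalid letter {letter!r}")
        if not 0 <= position < self.n_positions:
            raise ContractError(f"position {position} out of range")
        return position * N_CHANNELS + ALPHABET.index(letter)

    def decode(self) -> list[str]:
        """Recover the letter rows from the one-hot matrix."""
        idx = self.matrix.reshape(self.n_sequences, self.n_positions, N_CHANNELS).argmax(axis=2)
        return ["".join(ALPHABET[j] for j in row) for row in idx]


def onehot_encode(data) -> EncodedMatrix:
    """One-hot encode alignment rows / records / an AlignmentBlock.

    Channel order within each position block is alphabetical one-letter amino
    acids followed by the gap symbol, e.g. 'A' → (1, 0, ..., 0) and
    '-' → (0, ..., 0, 1).
    """
    rows = _as_rows(data)
    if not rows:
        raise ContractError("nothing to encode")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ContractError(f"rows have unequal lengths {sorted(widths)}")
    n_pos = widths.pop()
    lut = {c: i for i, c in enumerate(ALPHABET)}
    mat = np.zeros((len(rows), n_pos * N_CHANNELS), dtype=np.float64)
    for i, row in enumerate(rows):
        for p, letter in enumerate(row):
            try:
                mat[i, p * N_CHANNELS + lut[letter]] = 1.0
            except KeyError:
                raise AlphabetError(f"row {i}: invalid symbol {letter!r} at position {p}") from None
    labels = tuple((p, c) for p in range(n_pos) for c in ALPHABET)
    return EncodedMatrix(matrix=mat, labels=labels, n_positions=n_pos)


@dataclass(frozen=True)
class PCAModel:
    """Fitted covariance eigendecomposition of an encoded alignment.

    ``eigenvectors[:, j]`` is the j-th principal component (descending
    eigenvalue order). ``sign_flips`` records which eigenvectors were negated
    by the deterministic largest-component-positive convention;
    ``orientation_flips`` records subsequent biological orientation flips
    (empty until :func:`pocketpca.grouping_logos.orient_axes` is applied).
    """

    means: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    labels: tuple[tuple[int, str], ...]
    n_positions: int
    sign_flips: tuple[int, ...] = ()
    orientation_flips: tuple[int, ...] = ()
    oriented: bool = False

    @property
    def n_channels(self) -> int:
        return self.means.shape[0]

    def pc(self, k: int) -> np.ndarray:
        """k-th principal component vector, 1-based (PC1 = largest eigenvalue)."""
        if not 1 <= k <= self.eigenvectors.shape[1]:
            raise ContractError(f"PC index {k} out of range 1..{self.eigenvectors.shape[1]}")
        return self.eigenvectors[:, k - 1]


def fit_pca(encoded: EncodedMatrix) -> PCAModel:
    """Fit the unbiased channel covariance and diagonalize it.

    Eigenpairs are sorted by descending eigenvalue; exact ties are broken by
    the ascending channel index of each eigenvector's largest-magnitude
    component. Signs follow the largest-magnitude-component-positive rule so
    the decomposition is deterministic.
    """
    X = encoded.matrix
    M = X.shape[0]
    if M < 2:
        raise InsufficientDataError(f"need at least 2 sequences to fit a covariance, got {M}")
    means = X.mean(axis=0)
    Xc = X - means
    cov = (Xc.T @ Xc) / (M - 1)
    cov = (cov + cov.T) / 2.0  # enforce exact symmetry before eigh
    eigvals, eigvecs = np.linalg.eigh(cov)

    anchor = np.abs(eigvecs).argmax(axis=0)  # largest-magnitude component per vector
    order = sorted(range(len(eigvals)), key=lambda j: (-eigvals[j], anchor[j]))
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    anchor = anchor[order]

    flips = []
    for j in range(eigvecs.shape[1]):
        if eigvecs[anchor[j], j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
            flips.append(j + 1)

    return PCAModel(
        means=means,
        covariance=cov,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        labels=encoded.labels,
        n_positions=encoded.n_positions,
        sign_flips=tuple(flips),
    )


def project(
    model: PCAModel,
    encoded: EncodedMatrix,
    k: int,
    centering: str = "centered",
) -> np.ndarray:
    """Per-sequence coordinate on the k-th principal component (1-based).

    ``centered`` projects a_i − ā (default); ``raw`` projects the binary
    vector a_i itself. The two differ by the sequence-independent constant
    ā·V_k.
    """
    if encoded.labels != model.labels:
        raise ContractError("encoded matrix channels do not match the fitted model")
    if centering not in ("centered", "raw"):
        raise ContractError(f"unknown centering mode {centering!r}")
    v = model.pc(k)
    if centering == "raw":
        return encoded.matrix @ v
    return (encoded.matrix - model.means) @ v


@dataclass(frozen=True)
class CompositionProfile:
    """Per-(position, letter) composition deviation along one PC.

    ``deviations[t_index, position, letter_index]`` is the departure from the
    dataset-average composition at displacement ``t_values[t_index]`` along
    the component: Δ = t · v_k restricted to that channel. Within a position
    the 21 channel deviations sum to zero for any nonzero-eigenvalue mode.
    """

    pc: int
    t_values: np.ndarray
    deviations: np.ndarray  # (len(t), P, 21)
    labels: tuple[tuple[int, str], ...]

    def to_frame(self):
        """Long-format DataFrame (t, position, letter, deviation)."""
        import pandas as pd

        n_t, n_pos, n_ch = self.deviations.shape
        recs = []
        for ti, t in enumerate(self.t_values):
            for p in range(n_pos):
                for c in range(n_ch):
                    recs.append((t, p, ALPHABET[c], self.deviations[ti, p, c]))
        return pd.DataFrame(recs, columns=["t", "position", "letter", "deviation"])


def composition_profile(model: PCAModel, k: int, t_values: Iterable[float]) -> CompositionProfile:
    """Amino-acid composition deviation from the dataset mean along PC ``k``."""
    v = model.pc(k)  # raises on out-of-range k
    t = np.asarray(list(t_values), dtype=float)
    dev = t[:, None, None] * v.reshape(1, model.n_positions, N_CHANNELS)
    return CompositionProfile(pc=k, t_values=t, deviations=dev, labels=model.labels)
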