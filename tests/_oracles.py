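"""Independent oracles shared across test modules (kept free of package code paths)."""

import numpy as np

from pocketpca.dataset_io import ALPHABET

AA = ALPHABET[:-1]


def brute_force_covariance(X: np.ndarray) -> np.ndarray:
    """Double-loop evaluation of the unbiased channel covariance."""
    M, N = X.shape
    means = X.mean(axis=0)
    C = np.zeros((N, N))
    for k in range(N):
        for l in range(N):
            C[k, l] = sum((X[i, k] - means[k]) * (X[i, l] - means[l]) for i in range(M))
    return C / (M - 1)


def random_rows(rng, m, p):
    """m random ungapped rows of width p."""
    return ["".join(rng.choice(list(AA), size=p)) for _ in range(m)]
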