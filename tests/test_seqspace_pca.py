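"""One-hot encoding and covariance PCA: oracles, identities, and properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pocketpca as pp
from pocketpca.dataset_io import ALPHABET
from pocketpca.errors import AlphabetError, ContractError, InsufficientDataError
from pocketpca.seqspace_pca import N_CHANNELS

from _oracles import brute_force_covariance, random_rows


class TestOneHotEncode:
    def test_alanine_is_first_channel(self):
        enc = pp.onehot_encode(["A"])
        expected = np.zeros(21)
        expected[0] = 1.0
        np.testing.assert_array_equal(enc.matrix[0], expected)

    def test_gap_is_last_channel(self):
        enc = pp.onehot_encode(["-"])
        expected = np.zeros(21)
        expected[-1] = 1.0
        np.testing.assert_array_equal(enc.matrix[0], expected)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.sampled_from(list(ALPHABET)), min_size=1, max_size=12))
    def test_each_position_block_sums_to_one(self, letters):
        enc = pp.onehot_encode(["".join(letters)])
        blocks = enc.matrix.reshape(1, len(letters), N_CHANNELS)
        np.testing.assert_array_equal(blocks.sum(axis=2), np.ones((1, len(letters))))

    def test_decode_inverts_encode(self):
        rows = ["EVDDH", "QTG-H"]
        assert pp.onehot_encode(rows).decode() == rows

    def test_invalid_letter_rejected(self):
        with pytest.raises(AlphabetError, match="B"):
            pp.onehot_encode(["AB"])


class TestFitPCA:
    def test_identical_sequences_give_zero_covariance(self):
        model = pp.fit_pca(pp.onehot_encode(["EVD", "EVD"]))
        assert np.abs(model.covariance).max() == 0.0
        assert np.abs(model.eigenvalues).max() <= 1e-12

    def test_two_sequence_hand_example(self):
        # rows "A","C": means 0.5 on both channels, denominator M-1 = 1
        enc = pp.onehot_encode(["A", "C"])
        model = pp.fit_pca(enc)
        a, c = enc.channel(0, "A"), enc.channel(0, "C")
        assert model.covariance[a, a] == pytest.approx(0.5)
        assert model.covariance[c, c] == pytest.approx(0.5)
        assert model.covariance[a, c] == pytest.approx(-0.5)

    def test_covariance_matches_double_loop_oracle(self, rng):
        enc = pp.onehot_encode(random_rows(rng, 10, 3))
        model = pp.fit_pca(enc)
        np.testing.assert_allclose(
            model.covariance, brute_force_covariance(enc.matrix), atol=1e-12
        )

    def test_eigenvalues_match_svd_oracle(self, rng):
        # independent route: singular values of the centered matrix
        for m, p in ((5, 2), (12, 3), (20, 3)):
            enc = pp.onehot_encode(random_rows(rng, m, p))
            model = pp.fit_pca(enc)
            Xc = enc.matrix - enc.matrix.mean(axis=0)
            s = np.linalg.svd(Xc, compute_uv=False)
            expected = np.zeros_like(model.eigenvalues)
            expected[: len(s)] = s**2 / (m - 1)
            np.testing.assert_allclose(model.eigenvalues, expected, atol=1e-8)

    def test_eigenvector_orthonormality_and_trace(self, rng):
        enc = pp.onehot_encode(random_rows(rng, 15, 4))
        model = pp.fit_pca(enc)
        V = model.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        assert model.eigenvalues.min() >= -1e-10
        assert model.eigenvalues.sum() == pytest.approx(np.trace(model.covariance), abs=1e-8)

    def test_block_sum_property(self, rng):
        # covariance rows of one position block sum to zero, hence every
        # eigenvector with nonzero eigenvalue has zero block component-sum
        enc = pp.onehot_encode(random_rows(rng, 12, 3))
        model = pp.fit_pca(enc)
        for p in range(enc.n_positions):
            block = slice(p * N_CHANNELS, (p + 1) * N_CHANNELS)
            np.testing.assert_allclose(model.covariance[block, :].sum(axis=0), 0, atol=1e-12)
            for j, lam in enumerate(model.eigenvalues):
                if lam > 1e-10:
                    assert abs(model.eigenvectors[block, j].sum()) < 1e-8

    def test_rank_bound(self, rng):
        for m, p in ((4, 6), (15, 2)):
            enc = pp.onehot_encode(random_rows(rng, m, p))
            model = pp.fit_pca(enc)
            n_effective = (model.eigenvalues > 1e-10).sum()
            assert n_effective <= min(m - 1, enc.n_channels - p)

    def test_single_sequence_rejected(self):
        with pytest.raises(InsufficientDataError):
            pp.fit_pca(pp.onehot_encode(["EVD"]))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(11)
    rows = random_rows(rng, 20, 4)
    enc = pp.onehot_encode(rows)
    return enc, pp.fit_pca(enc)


@pytest.fixture(scope="module")
def small_model():
    rng = np.random.default_rng(5)
    return pp.fit_pca(pp.onehot_encode(random_rows(rng, 15, 3)))


class TestProjection:
    def test_identical_sequences_project_identically(self):
        enc = pp.onehot_encode(["EVD", "EVD", "QTG"])
        model = pp.fit_pca(enc)
        for mode in ("centered", "raw"):
            coords = pp.project(model, enc, 1, centering=mode)
            assert coords[0] == pytest.approx(coords[1], abs=1e-12)

    def test_centered_projections_have_zero_mean(self, fitted):
        enc, model = fitted
        for k in (1, 2, 3):
            assert abs(pp.project(model, enc, k).mean()) < 1e-10

    def test_raw_minus_centered_is_the_mean_dot_product(self, fitted):
        enc, model = fitted
        for k in (1, 2):
            diff = pp.project(model, enc, k, "raw") - pp.project(model, enc, k, "centered")
            expected = model.means @ model.pc(k)
            np.testing.assert_allclose(diff, expected, atol=1e-10)

    def test_channel_mismatch_rejected(self, fitted):
        _, model = fitted
        other = pp.onehot_encode(["EV", "QT"])
        with pytest.raises(ContractError):
            pp.project(model, other, 1)

    def test_all_conserved_input_projects_to_zero(self):
        enc = pp.onehot_encode(["EVD"] * 4)
        model = pp.fit_pca(enc)
        np.testing.assert_allclose(pp.project(model, enc, 1), 0, atol=1e-12)


class TestCompositionProfile:
    def test_zero_displacement_gives_zero_deviation(self, small_model):
        prof = pp.composition_profile(small_model, 1, [0.0])
        assert np.abs(prof.deviations).max() == 0.0

    def test_linearity_in_displacement(self, small_model):
        p1 = pp.composition_profile(small_model, 1, [0.5])
        p2 = pp.composition_profile(small_model, 1, [1.0])
        np.testing.assert_allclose(2 * p1.deviations[0], p2.deviations[0], atol=1e-12)

    def test_per_position_deviations_sum_to_zero(self, small_model):
        # any nonzero-eigenvalue mode conserves within-position composition
        k = 1
        assert small_model.eigenvalues[k - 1] > 1e-10
        prof = pp.composition_profile(small_model, k, [-1.0, 0.7])
        np.testing.assert_allclose(prof.deviations.sum(axis=2), 0, atol=1e-8)

    def test_out_of_range_component_rejected(self, small_model):
        with pytest.raises(ContractError):
            pp.composition_profile(small_model, 10**6, [0.0])
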