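"""Dictionary learning: initialization, training, application, summaries."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from dfcfp import (
    ConfigError,
    DataError,
    NetworkMap,
    RoiTimeSeries,
    apply_cobe,
    init_canonical,
    load_dictionary,
    make_pair_index,
    max_components,
    network_average_basis,
    planted_dfc_blocks,
    save_dictionary,
    sliding_window_dfc,
    train_cobe,
)
from dfcfp.cobe import describe_dictionary


def random_dfc(rng, r=5, t=60, w=20, s=10):
    ts = RoiTimeSeries(
        data=rng.standard_normal((t, r)),
        tr=0.72,
        region_ids=tuple(f"r{i}" for i in range(r)),
    )
    return sliding_window_dfc(ts, w, s)


class TestInitCanonical:
    def test_rank_one_block_recovers_left_vector(self, rng):
        u = rng.standard_normal(12)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(6)
        basis = init_canonical([np.outer(u, v)], 1)
        assert abs(float(basis[:, 0] @ u)) > 1 - 1e-8

    def test_repeated_blocks_match_single_block(self, rng):
        block = rng.standard_normal((10, 4))
        one = init_canonical([block], 3)
        many = init_canonical([block] * 5, 3)
        np.testing.assert_allclose(one, many, atol=1e-10)

    def test_matches_dense_eigendecomposition(self, rng):
        blocks = [rng.standard_normal((6, 4)) for _ in range(3)]
        basis = init_canonical(blocks, 2)
        # independent oracle: explicit pooled covariance of column-normalized
        # blocks, dense symmetric eigendecomposition
        pooled = np.zeros((6, 6))
        for block in blocks:
            normed = block / np.linalg.norm(block, axis=0)
            pooled += normed @ normed.T
        eigvals, eigvecs = np.linalg.eigh(pooled)
        expected = eigvecs[:, np.argsort(eigvals)[::-1][:2]]
        for col in range(2):
            cosine = abs(float(basis[:, col] @ expected[:, col]))
            assert cosine > 1 - 1e-8

    def test_component_bound_enforced(self, rng):
        with pytest.raises(ConfigError, match=r"min\(r_tilde, w_tilde\) = 4"):
            init_canonical([rng.standard_normal((10, 4))], 5)


class TestTrainCobe:
    def test_identical_blocks_give_top_svd_subspace(self, rng):
        block = rng.standard_normal((15, 6))
        dictionary = train_cobe([block] * 4, 3)
        u, _, _ = np.linalg.svd(block, full_matrices=False)
        angles = subspace_angles(dictionary.basis, u[:, :3])
        assert angles.max() < 1e-6

    def test_planted_subspace_recovered_without_noise(self):
        blocks, d0 = planted_dfc_blocks(
            n_subjects=5, r_tilde=100, n_frames=20, n_common=4, seed=0
        )
        dictionary = train_cobe(blocks, 4)
        assert subspace_angles(dictionary.basis, d0).max() < 1e-3

    def test_planted_subspace_recovered_under_noise(self):
        blocks, d0 = planted_dfc_blocks(
            n_subjects=5, r_tilde=100, n_frames=20, n_common=4, noise_sd=0.05, seed=1
        )
        dictionary = train_cobe(blocks, 4)
        assert subspace_angles(dictionary.basis, d0).max() < 0.1

    def test_planted_recovery_across_many_seeds(self):
        for seed in range(20):
            blocks, d0 = planted_dfc_blocks(
                n_subjects=5, r_tilde=80, n_frames=16, n_common=3, seed=seed
            )
            dictionary = train_cobe(blocks, 3)
            assert subspace_angles(dictionary.basis, d0).max() < 1e-3

    def test_residual_nonincreasing_in_c(self, rng):
        blocks = [rng.standard_normal((20, 8)) for _ in range(3)]
        residuals = [
            train_cobe(blocks, c).meta["final_residual"] for c in range(1, 6)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(residuals, residuals[1:]))

    def test_incompatible_pair_index_rejected(self, rng):
        a = random_dfc(rng, r=4)
        b_ts = RoiTimeSeries(
            data=rng.standard_normal((60, 4)),
            tr=0.72,
            region_ids=("x0", "x1", "x2", "x3"),
        )
        b = sliding_window_dfc(b_ts, 20, 10)
        with pytest.raises(DataError, match="pair"):
            train_cobe([a, b], 2)

    def test_metadata_records_provenance(self, rng):
        dfc = random_dfc(rng)
        dictionary = train_cobe([dfc, random_dfc(rng)], 2)
        meta = dictionary.meta
        assert meta["n_train"] == 2
        assert meta["window"] == 20 and meta["stride"] == 10
        assert len(meta["iterations"]) == 2
        assert meta["final_residual"] >= 0


class TestApplyCobe:
    def test_in_span_input_has_zero_specific(self, rng):
        blocks, d0 = planted_dfc_blocks(3, 50, 10, 3, seed=2)
        dictionary = train_cobe(blocks, 3)
        inside = dictionary.basis @ rng.standard_normal((3, 7))
        decomp = apply_cobe(dictionary, inside)
        assert np.abs(decomp.subject_specific).max() < 1e-10

    def test_orthogonal_input_passes_through(self, rng):
        blocks, d0 = planted_dfc_blocks(3, 50, 10, 3, seed=3)
        dictionary = train_cobe(blocks, 3)
        outside = rng.standard_normal((50, 7))
        outside -= dictionary.basis @ (dictionary.basis.T @ outside)
        decomp = apply_cobe(dictionary, outside)
        assert np.abs(decomp.common).max() < 1e-10
        np.testing.assert_allclose(decomp.subject_specific, outside, atol=1e-12)

    def test_matches_projection_oracle(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((10, 3)))
        from dfcfp.cobe import CobeDictionary

        dictionary = CobeDictionary(
            basis=q, pair_index=tuple((f"p{i}", f"q{i}") for i in range(10)), meta={}
        )
        data = rng.standard_normal((10, 4))
        decomp = apply_cobe(dictionary, data)
        np.testing.assert_allclose(decomp.common, q @ q.T @ data, atol=1e-12)

    def test_reconstruction_orthogonality_idempotence(self, rng):
        dfcs = [random_dfc(rng, r=6) for _ in range(4)]
        dictionary = train_cobe(dfcs, 3)
        target = random_dfc(rng, r=6)
        decomp = apply_cobe(dictionary, target)
        # reconstruction identity to machine precision: the residual is the
        # literal subtraction, so re-adding loses at most one ulp per entry
        np.testing.assert_allclose(
            decomp.common + decomp.subject_specific, target.values, atol=1e-12
        )
        assert np.abs(dictionary.basis.T @ decomp.subject_specific).max() < 1e-8
        again = apply_cobe(dictionary, decomp.common)
        np.testing.assert_allclose(again.common, decomp.common, atol=1e-10)
        assert np.abs(again.subject_specific).max() < 1e-8

    def test_foreign_atlas_rejected(self, rng):
        dfcs = [random_dfc(rng, r=5) for _ in range(3)]
        dictionary = train_cobe(dfcs, 2)
        foreign_ts = RoiTimeSeries(
            data=rng.standard_normal((60, 5)),
            tr=0.72,
            region_ids=tuple(f"other{i}" for i in range(5)),
        )
        foreign = sliding_window_dfc(foreign_ts, 20, 10)
        with pytest.raises(DataError, match="fingerprint"):
            apply_cobe(dictionary, foreign)


class TestNetworkAverageBasis:
    def _dictionary_with_column(self, column, region_ids):
        from dfcfp.cobe import CobeDictionary

        column = np.asarray(column, dtype=float)[:, None]
        return CobeDictionary(
            basis=column / np.linalg.norm(column),
            pair_index=make_pair_index(region_ids),
            meta={},
        )

    def test_single_network_mean(self):
        dictionary = self._dictionary_with_column([1.0, 2.0, 3.0], ["a", "b", "c"])
        nmap = NetworkMap({"a": "VN", "b": "VN", "c": "VN"})
        table = network_average_basis(dictionary, nmap)
        expected = dictionary.basis[:, 0].mean()
        assert table.loc["VN", "VN"] == pytest.approx(expected)
        assert np.isnan(table.loc["DMN", "DMN"])

    def test_constant_column_gives_constant_entries(self):
        dictionary = self._dictionary_with_column(np.ones(6), list("abcd"))
        nmap = NetworkMap({"a": "VN", "b": "VN", "c": "DMN", "d": "DMN"})
        table = network_average_basis(dictionary, nmap)
        c = dictionary.basis[0, 0]
        for pair in [("VN", "VN"), ("VN", "DMN"), ("DMN", "DMN")]:
            assert table.loc[pair] == pytest.approx(c)

    def test_hand_averaged_two_networks(self):
        # pairs of a,b,c,d in row-major order: ab, ac, ad, bc, bd, cd
        column = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        dictionary = self._dictionary_with_column(column, list("abcd"))
        scale = 1.0 / np.linalg.norm(column)
        nmap = NetworkMap({"a": "VN", "b": "VN", "c": "DMN", "d": "DMN"})
        table = network_average_basis(dictionary, nmap)
        assert table.loc["VN", "VN"] == pytest.approx(1.0 * scale)  # ab
        assert table.loc["DMN", "DMN"] == pytest.approx(6.0 * scale)  # cd
        # cross pairs: ac, ad, bc, bd
        assert table.loc["VN", "DMN"] == pytest.approx(np.mean([2, 3, 4, 5]) * scale)
        assert table.loc["DMN", "VN"] == table.loc["VN", "DMN"]


def test_component_bound_helper():
    assert max_components(10, 3) == 3
    assert max_components(3, 10) == 3
    with pytest.raises(ConfigError):
        max_components(0, 5)


def test_dictionary_round_trip_and_summary(tmp_path, rng):
    dfcs = [random_dfc(rng, r=5) for _ in range(3)]
    dictionary = train_cobe(dfcs, 2)
    save_dictionary(dictionary, tmp_path / "dict.npz")
    back = load_dictionary(tmp_path / "dict.npz")
    np.testing.assert_array_equal(back.basis, dictionary.basis)
    assert back.pair_index == dictionary.pair_index
    assert back.meta["n_train"] == 3
    summary = describe_dictionary(back)
    assert "10 pairs x 2 components" in summary
    assert "orthonormality" in summary
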