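import numpy as np
import pytest

from delics.mrf_signal import (
    DictionaryGrid,
    SequenceParams,
    SignalDictionary,
    build_dictionary,
    compute_basis,
    default_grid,
    default_sequence,
    match_templates,
    simulate_fingerprint,
)

from oracles import isochromat_fingerprint


class TestFingerprint:
    def test_zero_flip_angles_give_zero_signal(self):
        seq = SequenceParams(n_tr=50, flip_deg=np.zeros(50))
        assert np.allclose(simulate_fingerprint(1000, 80, seq), 0)

    def test_reference_protocol_accepted(self):
        seq = default_sequence()
        assert (seq.n_tr, seq.ti_ms, seq.te_ms, seq.tr_ms) == (500, 20.0, 0.7, 12.0)
        assert seq.flip_deg.min() >= 10.0 and seq.flip_deg.max() <= 75.0
        sig = simulate_fingerprint(1000, 80, seq)
        assert sig.shape == (500,) and np.linalg.norm(sig) > 0

    @pytest.mark.parametrize("t1", [300.0, 1000.0, 4000.0])
    @pytest.mark.parametrize("t2", [50.0, 80.0, 500.0])
    def test_epg_matches_isochromat_oracle(self, t1, t2):
        """State-space simulation must agree with brute-force dephased spins."""
        seq = SequenceParams(n_tr=80)
        epg = simulate_fingerprint(t1, t2, seq)
        iso = isochromat_fingerprint(t1, t2, seq, n_spins=2000)
        assert np.linalg.norm(epg - iso) / np.linalg.norm(iso) < 1e-3

    def test_invalid_inputs_raise(self):
        seq = SequenceParams(n_tr=10)
        with pytest.raises(ValueError):
            simulate_fingerprint(-1.0, 80, seq)
        with pytest.raises(ValueError):
            SequenceParams(n_tr=10, te_ms=15.0, tr_ms=12.0)
        with pytest.raises(ValueError):
            SequenceParams(n_tr=10, flip_deg=np.full(10, 200.0))


class TestDictionary:
    def test_single_pair_gives_single_atom(self):
        grid = DictionaryGrid(t1_values_ms=np.array([1000.0]), t2_values_ms=np.array([80.0]))
        d = build_dictionary(grid, SequenceParams(n_tr=20))
        assert d.n_atoms == 1 and d.labels[0].tolist() == [1000.0, 80.0]

    def test_default_grid_matches_reference_t1_and_t2_sets(self):
        g = default_grid()
        expected_t1 = np.concatenate([np.arange(20, 3001, 20), np.arange(3200, 5001, 200)])
        assert np.array_equal(g.t1_values_ms, expected_t1)
        # T2: step 2 up to 200, then coarser segments
        assert np.array_equal(g.t2_values_ms[:96], np.arange(10, 201, 2))
        assert 1000.0 in g.t2_values_ms and 2000.0 in g.t2_values_ms and g.t2_values_ms[-1] == 4000.0

    def test_atom_count_equals_bruteforce_pair_enumeration(self):
        grid = DictionaryGrid(
            t1_values_ms=np.array([100.0, 500.0, 1000.0]),
            t2_values_ms=np.array([50.0, 200.0, 800.0, 1500.0]),
        )
        expected = sum(1 for t1 in grid.t1_values_ms for t2 in grid.t2_values_ms if t2 <= t1)
        d = build_dictionary(grid, SequenceParams(n_tr=20))
        assert d.n_atoms == expected
        assert np.all(d.labels[:, 1] <= d.labels[:, 0])

    def test_empty_retained_set_raises(self):
        with pytest.raises(ValueError):
            DictionaryGrid(t1_values_ms=np.array([20.0]), t2_values_ms=np.array([500.0])).pairs()


class TestBasis:
    def test_rank_one_reproduces_single_atom(self):
        grid = DictionaryGrid(t1_values_ms=np.array([900.0]), t2_values_ms=np.array([70.0]))
        d = build_dictionary(grid, SequenceParams(n_tr=30))
        basis = compute_basis(d, K=1)
        recon = basis.phi @ (basis.phi.conj().T @ d.atoms[0])
        assert np.linalg.norm(recon - d.atoms[0]) < 1e-10 * np.linalg.norm(d.atoms[0])

    def test_orthonormality_and_descending_singular_values(self, desk_setup):
        _, _, basis = desk_setup
        gram = basis.phi.conj().T @ basis.phi
        assert np.linalg.norm(gram - np.eye(basis.K)) < 1e-10
        assert np.all(np.diff(basis.singular_values) <= 1e-12)

    def test_eckart_young_residual_identity(self, desk_setup):
        """Energy left out of the rank-K basis equals the discarded singular values."""
        _, dictionary, basis = desk_setup
        proj = dictionary.atoms @ basis.phi.conj() @ basis.phi.T
        resid = np.sum(np.abs(dictionary.atoms - proj) ** 2)
        expected = np.sum(basis.singular_values[basis.K :] ** 2)
        assert np.isclose(resid, expected, rtol=1e-8)

    def test_rank5_energy_capture_on_reference_ranges(self):
        """Rank 5 captures >= 99% of fingerprint energy over the brain grid.

        The T1/T2 ranges are the reference ones, thinned 3x in each
        dimension to keep the simulation tractable; energy capture is a
        smooth property of the fingerprint manifold.
        """
        full = default_grid()
        grid = DictionaryGrid(t1_values_ms=full.t1_values_ms[::3], t2_values_ms=full.t2_values_ms[::3])
        d = build_dictionary(grid, default_sequence())
        basis = compute_basis(d, K=5)
        frac = np.sum(basis.singular_values[:5] ** 2) / np.sum(basis.singular_values**2)
        assert frac >= 0.99

    def test_k_out_of_range_raises(self, desk_setup):
        _, dictionary, _ = desk_setup
        with pytest.raises(ValueError):
            compute_basis(dictionary, K=0)


class TestMatching:
    def test_self_match_and_scale_invariance(self, desk_setup):
        _, dictionary, basis = desk_setup
        j = 137
        c = basis.compress(dictionary.atoms[j])
        vol = np.tile(c[:, None, None, None], (1, 2, 2, 2)).astype(complex)
        vol[:, 1, 1, 1] = 3.7 * c
        maps = match_templates(vol, dictionary, basis)
        assert np.all(maps.t1_ms == dictionary.labels[j, 0])
        assert np.all(maps.t2_ms == dictionary.labels[j, 1])
        assert np.isclose(abs(maps.pd[1, 1, 1]), 3.7 * abs(maps.pd[0, 0, 0]), rtol=1e-10)

    def test_matches_bruteforce_argmax_on_small_volume(self, desk_setup):
        _, dictionary, basis = desk_setup
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((basis.K, 4, 4, 4)) + 1j * rng.standard_normal((basis.K, 4, 4, 4))
        maps = match_templates(vol, dictionary, basis)
        d_hat = basis.compress(dictionary.atoms)
        d_hat /= np.linalg.norm(d_hat, axis=1, keepdims=True)
        for z in range(4):
            for y in range(4):
                for x in range(4):
                    corr = np.abs(d_hat.conj() @ vol[:, z, y, x])
                    best = int(np.argmax(corr))
                    assert maps.t1_ms[z, y, x] == dictionary.labels[best, 0]
                    assert maps.t2_ms[z, y, x] == dictionary.labels[best, 1]

    def test_zero_voxel_flagged_inside_mask(self, desk_setup):
        _, dictionary, basis = desk_setup
        vol = np.zeros((basis.K, 2, 2, 2), complex)
        vol[:, 0, 0, 0] = basis.compress(dictionary.atoms[5])
        maps = match_templates(vol, dictionary, basis)
        assert maps.degenerate[1, 1, 1] and not maps.degenerate[0, 0, 0]
        assert maps.t1_ms[1, 1, 1] == 0 and maps.pd[1, 1, 1] == 0
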