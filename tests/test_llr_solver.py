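import numpy as np
import pytest

from delics.forward_model import CoefficientImage, apply_forward
from delics.llr_solver import ReconConfig, fista_llr, gridding_init, llr_penalty, llr_prox, objective

from conftest import random_small_model
from oracles import blockwise_svt, dense_acquisition_matrix, svt


def _rand_vol(K=3, n=8, seed=0):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((K, n, n, n)) + 1j * rng.standard_normal((K, n, n, n))


class TestProx:
    def test_zero_threshold_is_identity(self):
        x = _rand_vol()
        assert np.array_equal(llr_prox(x, 0.0, 4).data, x)

    def test_large_threshold_annihilates(self):
        x = _rand_vol()
        big = 10 * np.linalg.svd(x.reshape(3, -1).T, compute_uv=False)[0]
        assert np.all(llr_prox(x, big, 8).data == 0)

    def test_single_block_matches_direct_svt(self):
        x = _rand_vol()
        thr = 0.4 * np.linalg.svd(x.reshape(3, -1).T, compute_uv=False)[0]
        out = llr_prox(x, thr, 8).data
        ref = svt(x.reshape(3, -1).T, thr).T.reshape(x.shape)
        assert np.linalg.norm(out - ref) < 1e-12 * np.linalg.norm(ref)

    def test_tiled_blocks_match_loop_oracle(self):
        x = _rand_vol(K=2, n=8, seed=4)
        out = llr_prox(x, 0.3, 4).data
        assert np.allclose(out, blockwise_svt(x, 4, 0.3), atol=1e-12)

    def test_shift_round_trip(self):
        """Shifted tiling at threshold 0 must still be the identity."""
        x = _rand_vol(seed=5)
        out = llr_prox(x, 0.0, 4, shift=(1, 2, 3)).data
        assert np.allclose(out, x)

    @pytest.mark.parametrize("seed", range(4))
    def test_nonexpansive(self, seed):
        x, y = _rand_vol(seed=seed), _rand_vol(seed=seed + 100)
        px = llr_prox(x, 0.3, 4).data
        py = llr_prox(y, 0.3, 4).data
        assert np.linalg.norm(px - py) <= np.linalg.norm(x - y) * (1 + 1e-12)

    def test_invalid_block_size(self):
        with pytest.raises(ValueError):
            llr_prox(_rand_vol(), 0.1, 0)


class TestObjective:
    def test_zero_iterate_is_weighted_data_energy(self, small_model):
        rng = np.random.default_rng(1)
        b = rng.standard_normal((2, 4, 16)) + 1j * rng.standard_normal((2, 4, 16))
        w = rng.uniform(0.5, 1.5, (4, 16))
        x0 = np.zeros((2, 8, 8, 8), complex)
        val = objective(small_model, b, w, 0.5, 4, x0)
        expected = 0.5 * np.sum(w * np.abs(b) ** 2)
        assert np.isclose(val, expected)

    def test_matches_dense_recomputation(self, small_model):
        A = dense_acquisition_matrix(
            small_model.basis.phi, small_model.coil_maps.maps, small_model.traj.coords, 8
        )
        rng = np.random.default_rng(2)
        x = _rand_vol(K=2)
        b = rng.standard_normal((2, 4, 16)) + 1j * rng.standard_normal((2, 4, 16))
        w = rng.uniform(0.5, 1.5, (4, 16))
        lam, bs = 0.7, 4
        val = objective(small_model, b, w, lam, bs, x)
        wf = np.tile(w.reshape(-1), 2)
        resid = A @ x.reshape(-1) - b.reshape(-1)
        expected = 0.5 * np.sum(wf * np.abs(resid) ** 2) + lam * llr_penalty(x, bs)
        assert np.isclose(val, expected, rtol=1e-10)


class TestFista:
    def _overdetermined(self):
        # N=4, K=1, C=2, T=8, M=20: 320 samples >> 64 unknowns
        return random_small_model(K=1, C=2, T=8, M=20, N=4, seed=9)

    def test_lambda_zero_converges_to_weighted_least_squares(self):
        model = self._overdetermined()
        A = dense_acquisition_matrix(model.basis.phi, model.coil_maps.maps, model.traj.coords, 4)
        rng = np.random.default_rng(3)
        b = rng.standard_normal((2, 8, 20)) + 1j * rng.standard_normal((2, 8, 20))
        w = rng.uniform(0.5, 1.5, (8, 20))
        wf = np.tile(w.reshape(-1), 2)
        x_ls = np.linalg.solve(A.conj().T @ (wf[:, None] * A), A.conj().T @ (wf * b.reshape(-1)))
        cfg = ReconConfig(lam=0.0, n_iter=800, block_size=2, power_iters=40, exact_trace=False)
        st = fista_llr(model, b, w, cfg)
        err = np.linalg.norm(st.x.data.reshape(-1) - x_ls) / np.linalg.norm(x_ls)
        assert err < 1e-4

    def test_exact_solution_is_fixed_point(self):
        model = self._overdetermined()
        A = dense_acquisition_matrix(model.basis.phi, model.coil_maps.maps, model.traj.coords, 4)
        rng = np.random.default_rng(4)
        b = rng.standard_normal((2, 8, 20)) + 1j * rng.standard_normal((2, 8, 20))
        x_ls = np.linalg.solve(A.conj().T @ A, A.conj().T @ b.reshape(-1)).reshape(1, 4, 4, 4)
        cfg = ReconConfig(lam=0.0, n_iter=1, normalize_b=False, block_size=2, power_iters=40)
        st = fista_llr(model, b, None, cfg, x_init=CoefficientImage(data=x_ls))
        move = np.linalg.norm(st.x.data - x_ls) / np.linalg.norm(x_ls)
        assert move < 1e-6

    def test_reference_configuration_defaults(self):
        cfg = ReconConfig()
        assert (cfg.lam, cfg.n_iter, cfg.block_size) == (5e-5, 40, 8)

    def test_returned_objective_never_exceeds_initial(self):
        model = self._overdetermined()
        rng = np.random.default_rng(5)
        b = rng.standard_normal((2, 8, 20)) + 1j * rng.standard_normal((2, 8, 20))
        cfg = ReconConfig(lam=0.05, n_iter=15, block_size=2, power_iters=20)
        st = fista_llr(model, b, None, cfg)
        x0 = gridding_init(model, b, None, power_iters=20)
        init_obj = objective(model, b / st.scale, None, cfg.lam, cfg.block_size, x0.data / st.scale)
        assert min(st.objective_trace) <= init_obj * (1 + 1e-9)
        assert all(np.isfinite(st.objective_trace))

    def test_divergence_aborts_with_diagnostic(self):
        model = self._overdetermined()
        rng = np.random.default_rng(6)
        b = rng.standard_normal((2, 8, 20)) + 1j * rng.standard_normal((2, 8, 20))
        # a grossly underestimated Lipschitz constant forces a diverging step
        cfg = ReconConfig(lam=0.0, n_iter=50, block_size=2, lipschitz=1e-6)
        with pytest.raises(RuntimeError, match="diverged"):
            fista_llr(model, b, None, cfg)
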