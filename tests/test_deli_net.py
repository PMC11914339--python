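import numpy as np
import pytest

from delics.deli_net import (
    BlendSpec,
    BlockSample,
    TrainConfig,
    augment_block_scale,
    augment_volumes,
    blend_profile,
    block_dc_spread,
    complex_to_channels,
    extract_training_blocks,
    infer_volume,
    normalize_volume,
    standardize_gain,
    train_denoiser,
    validation_loss,
)
from delics.forward_model import CoefficientImage
from delics.nn import Adam, NetConfig, ResUNet, analytic_param_count, build_network, l1_loss


def _vol(K=2, n=32, seed=0, background=False):
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((K, n, n, n)) + 1j * rng.standard_normal((K, n, n, n))
    if background:
        v[:, : n // 2] = 0
    return v


class TestNormalization:
    def test_unit_norm_and_round_trip(self):
        v = _vol()
        out, scale = normalize_volume(v)
        assert abs(np.linalg.norm(out) - 1.0) < 1e-12
        assert np.allclose(out * scale, v, rtol=1e-14)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            normalize_volume(np.zeros((2, 4, 4, 4), complex))

    def test_normalization_commutes_with_block_extraction(self):
        v = _vol(seed=3)
        w = _vol(seed=4)
        vn, scale = normalize_volume(v)
        a = extract_training_blocks(vn, w / scale, 16, filter_threshold=0.0, standardize=False)
        b = extract_training_blocks(v, w, 16, filter_threshold=0.0, standardize=False)
        for sa, sb in zip(a, b):
            assert np.allclose(sa.input_block, sb.input_block / scale, rtol=1e-5)


class TestBlockExtraction:
    def test_tiling_arithmetic(self):
        v, _ = normalize_volume(_vol(n=32))
        blocks = extract_training_blocks(v, v, 16, filter_threshold=0.0)
        assert len(blocks) == 8
        assert blocks[0].input_block.shape == (4, 16, 16, 16)

    def test_background_blocks_discarded(self):
        v = _vol(n=32, background=True)
        v, _ = normalize_volume(v)
        blocks = extract_training_blocks(v, v, 16, filter_threshold=1e-6)
        assert all(origin[1][0] >= 16 for origin in (b.origin for b in blocks))

    def test_survivor_count_matches_bruteforce_rule(self):
        v, _ = normalize_volume(_vol(n=32, seed=7))
        thr = np.median(
            [block_dc_spread(v[:, a : a + 16, b : b + 16, c : c + 16]) for a in (0, 16) for b in (0, 16) for c in (0, 16)]
        )
        blocks = extract_training_blocks(v, v, 16, filter_threshold=float(thr))
        count = 0
        for a in (0, 16):
            for b in (0, 16):
                for c in (0, 16):
                    blk = v[:, a : a + 16, b : b + 16, c : c + 16]
                    dc = blk.reshape(v.shape[0], -1).sum(axis=1)
                    if np.std(np.abs(dc)) >= thr:
                        count += 1
        assert len(blocks) == count

    def test_oversized_block_rejected(self):
        v, _ = normalize_volume(_vol(n=16))
        with pytest.raises(ValueError):
            extract_training_blocks(v, v, 32)


class _StubRng:
    """Deterministic stand-in for numpy's Generator used to force branches."""

    def __init__(self, randoms, perm=None, ints=0):
        self._randoms = list(randoms)
        self._perm = perm
        self._ints = ints

    def random(self):
        return self._randoms.pop(0)

    def permutation(self, n):
        return np.array(self._perm if self._perm is not None else range(n))

    def integers(self, lo, hi):
        return self._ints


class TestAugmentation:
    def test_deterministic_under_fixed_seed(self):
        v, w = _vol(seed=1), _vol(seed=2)
        a1 = augment_volumes(v, w, np.random.default_rng(5))
        a2 = augment_volumes(v, w, np.random.default_rng(5))
        assert np.array_equal(a1[0], a2[0]) and np.array_equal(a1[1], a2[1])

    def test_double_flip_is_identity(self):
        v, w = _vol(seed=1), _vol(seed=2)
        flip_all = _StubRng(randoms=[0.0, 0.0, 0.0])  # < 0.5 flips every axis
        once = augment_volumes(v, w, flip_all)
        twice = augment_volumes(*once, _StubRng(randoms=[0.0, 0.0, 0.0]))
        assert np.array_equal(twice[0], v) and np.array_equal(twice[1], w)

    def test_geometry_applied_identically_to_both_volumes(self):
        v = _vol(seed=3)
        out_in, out_tgt = augment_volumes(v, v, np.random.default_rng(9))
        assert np.array_equal(out_in, out_tgt)

    def test_block_scale_range_and_pairing(self):
        s = BlockSample(
            input_block=np.ones((4, 8, 8, 8), np.float32),
            target_block=2 * np.ones((4, 8, 8, 8), np.float32),
            origin=(0, (0, 0, 0)),
        )
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = augment_block_scale(s, rng)
            g = a.input_block[0, 0, 0, 0]
            assert 0.5 <= g <= 1.0
            assert np.allclose(a.target_block, 2 * a.input_block)


class TestNetwork:
    def test_output_shape_matches_input(self):
        net, _ = build_network(NetConfig(in_channels=4, widths=(4, 6, 8)))
        x = np.random.default_rng(0).standard_normal((1, 4, 8, 8, 8)).astype(np.float32)
        assert net.forward(x).shape == x.shape

    def test_full_scale_parameter_budget(self):
        """The scanner-scale network carries 23.8 million trainable parameters."""
        net, n = build_network(NetConfig(in_channels=10, widths=(160, 224, 384)))
        assert round(n / 1e6, 1) == 23.8

    def test_introspection_matches_analytic_layer_sum(self):
        for cio, widths in [(10, (160, 224, 384)), (6, (8, 16, 32)), (4, (4, 6, 8))]:
            net, n = build_network(NetConfig(in_channels=cio, widths=widths))
            assert n == analytic_param_count(cio, widths)

    def test_indivisible_block_edge_rejected(self):
        net, _ = build_network(NetConfig(in_channels=4, widths=(4, 6, 8)))
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 4, 6, 6, 6), np.float32))

    def test_gradient_matches_finite_differences(self):
        """Backprop through the full network agrees with numerical gradients."""
        net, _ = build_network(NetConfig(in_channels=2, widths=(2, 3, 4), seed=1))
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 2, 4, 4, 4)).astype(np.float32)
        y = rng.standard_normal((1, 2, 4, 4, 4)).astype(np.float32)
        net.zero_grad()
        loss, dl = l1_loss(net.forward(x), y)
        net.backward(dl)
        W, dW = net.head.W, net.head.dW
        eps = 1e-3
        for idx in [(0, 0, 1, 1, 1), (1, 1, 0, 2, 1)]:
            w0 = W[idx]
            W[idx] = w0 + eps
            lp, _ = l1_loss(net.forward(x), y)
            W[idx] = w0 - eps
            lm, _ = l1_loss(net.forward(x), y)
            W[idx] = w0
            num = (lp - lm) / (2 * eps)
            assert abs(num - dW[idx]) < 5e-4 * max(1.0, abs(num))

    def test_save_load_round_trip(self, tmp_path):
        net, _ = build_network(NetConfig(in_channels=4, widths=(4, 6, 8), seed=3))
        x = np.random.default_rng(1).standard_normal((1, 4, 8, 8, 8)).astype(np.float32)
        y1 = net.forward(x)
        net.save(tmp_path / "net.npz")
        net2 = ResUNet.load(tmp_path / "net.npz")
        assert np.allclose(net2.forward(x), y1)


class TestTraining:
    @staticmethod
    def _smooth_block(rng):
        # smooth signed fields resembling coefficient-image content
        from scipy.ndimage import gaussian_filter

        b = np.stack([gaussian_filter(rng.standard_normal((8, 8, 8)), 1.5) for _ in range(4)]).astype(np.float32)
        return b / np.abs(b).mean()

    def test_single_block_overfit(self):
        """With one training block the network nearly memorizes the target."""
        rng = np.random.default_rng(0)
        tgt = self._smooth_block(rng)
        noisy = (tgt + 0.5 * rng.standard_normal(tgt.shape)).astype(np.float32)
        s = [BlockSample(input_block=noisy, target_block=tgt, origin=(0, (0, 0, 0)))]
        net, _ = build_network(NetConfig(in_channels=4, widths=(8, 12, 16), seed=0))
        init = validation_loss(net, s)
        net, curves = train_denoiser(
            s, s, net, TrainConfig(lr=1e-2, max_epochs=1000, batch_size=1, patience=1000, augment=False)
        )
        assert min(curves["val"]) < 0.02 * init

    def test_identity_task_drives_validation_toward_identity_floor(self):
        """When target equals input, held-out loss falls toward the (zero)
        identity-map loss and the training loss drops sharply."""
        rng = np.random.default_rng(1)
        blocks = [
            BlockSample(input_block=b, target_block=b, origin=(0, (i, 0, 0)))
            for i, b in enumerate(self._smooth_block(rng) for _ in range(8))
        ]
        net, _ = build_network(NetConfig(in_channels=4, widths=(8, 12, 16), seed=1))
        init = validation_loss(net, blocks[6:])
        net, curves = train_denoiser(
            blocks[:6], blocks[6:], net, TrainConfig(lr=1e-2, max_epochs=250, batch_size=2, patience=250, augment=False)
        )
        assert min(curves["val"]) < 0.55 * init
        assert curves["train"][-1] < 0.25 * curves["train"][0]

    def test_empty_sets_rejected(self):
        net, _ = build_network(NetConfig(in_channels=4, widths=(4, 6, 8)))
        blk = BlockSample(
            input_block=np.ones((4, 8, 8, 8), np.float32),
            target_block=np.ones((4, 8, 8, 8), np.float32),
            origin=(0, (0, 0, 0)),
        )
        with pytest.raises(ValueError):
            train_denoiser([], [blk], net, TrainConfig())


class _IdentityNet:
    def __init__(self, channels):
        self.cfg = NetConfig(in_channels=channels, widths=(4, 6, 8))

    def forward(self, x):
        return x


class TestBlend:
    @pytest.mark.parametrize("L,ov", [(8, 2), (8, 4), (16, 8), (12, 7)])
    def test_weight_coverage_and_symmetry(self, L, ov):
        """Profiles are positive, symmetric, flat inside, and cover every voxel
        of a tiled line so the normalized weights sum to one everywhere."""
        p = blend_profile(L, ov)
        assert np.all(p > 0) and np.allclose(p, p[::-1])
        if L > 2 * ov:
            assert np.all(p[ov : L - ov] == 1.0)
        stride = L - ov
        length = 3 * stride + L
        acc = np.zeros(length)
        for s in range(0, length - L + 1, stride):
            acc[s : s + L] += p
        assert np.all(acc > 0)
        # cross-fade: complementary ramps sum to 1 in interior overlaps
        if L > 2 * ov:
            assert np.allclose(acc[L - ov : length - L + ov ], 1.0, atol=1e-10)

    def test_identity_model_reproduces_volume(self):
        v = _vol(K=2, n=24, seed=5)
        out = infer_volume(CoefficientImage(data=v), _IdentityNet(4), BlendSpec(8, 4))
        assert np.max(np.abs(out.data - v)) < 1e-6 * np.max(np.abs(v))

    def test_two_block_overlap_matches_hand_computed_average(self):
        """Length-8 line, blocks of 6 with overlap 4: the overlap region is the
        profile-weighted average of the two block outputs."""
        p = blend_profile(6, 4)
        assert np.allclose(p, [0.2, 0.4, 0.6, 0.6, 0.4, 0.2])

        class _CountingNet(_IdentityNet):
            def __init__(self):
                super().__init__(2)
                self.calls = 0

            def forward(self, x):
                self.calls += 1
                return np.full_like(x, float(self.calls))

        v = np.zeros((1, 8, 8, 8), complex)
        v[0, 0, 0, 0] = 1.0  # nonzero so normalization is defined
        net = _CountingNet()
        out = infer_volume(CoefficientImage(data=v), net, BlendSpec(6, 4))
        # blocks along the last axis at starts 0 and 2 get consecutive call
        # numbers; at position 3 (= index 3 of block A and 1 of block B):
        # w_A = p[3] = 0.6, w_B = p[1] = 0.4
        scale = np.linalg.norm(v) / standardize_gain(v.shape)
        got = out.data[0, 0, 0, 3].real / scale
        # recompute expected directly from the tiling order (z, then y, then x)
        c = 0
        acc = np.zeros(8)
        wacc = np.zeros(8)
        for z0 in (0, 2):
            for y0 in (0, 2):
                for x0 in (0, 2):
                    c += 1
                    if z0 == 0 and y0 == 0:
                        acc[x0 : x0 + 6] += c * p
                        wacc[x0 : x0 + 6] += p
        expected_pos3 = acc[3] / wacc[3]
        assert abs(got - expected_pos3) < 1e-6

    def test_volume_smaller_than_block_rejected(self):
        v = _vol(K=2, n=8)
        with pytest.raises(ValueError):
            infer_volume(CoefficientImage(data=v), _IdentityNet(4), BlendSpec(16, 8))

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            BlendSpec(8, 8)
        with pytest.raises(ValueError):
            BlendSpec(8, 0)
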