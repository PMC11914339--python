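import numpy as np
import pytest

from delics.coil_prep import (
    CalibrationImage,
    apply_fov_shift_kspace,
    autofov,
    build_compression,
    estimate_coil_maps,
    prewhiten,
    rovir_weights,
)
from delics.forward_model import AcquisitionModel, CoefficientImage, CoilMaps, apply_forward
from delics.nufft import nufft_adjoint, nufft_forward

from conftest import random_small_model


def _corr_noise(n_coils, n_obs, seed=0, mixing=None):
    rng = np.random.default_rng(seed)
    white = (rng.standard_normal((n_coils, n_obs)) + 1j * rng.standard_normal((n_coils, n_obs))) / np.sqrt(2)
    return white if mixing is None else mixing @ white


class TestPrewhiten:
    def test_white_noise_gives_identity(self):
        W = prewhiten(_corr_noise(6, 10_000))
        off = W - np.diag(np.diag(W))
        assert np.max(np.abs(off)) < 0.05

    def test_whitened_covariance_is_identity(self):
        rng = np.random.default_rng(1)
        mix = rng.standard_normal((6, 6)) + 1j * rng.standard_normal((6, 6))
        noise = _corr_noise(6, 10_000, seed=2, mixing=mix)
        W = prewhiten(noise)
        wn = W @ noise
        cov = wn @ wn.conj().T / wn.shape[1]
        assert np.linalg.norm(cov - np.eye(6)) < 0.05

    def test_perfectly_correlated_coils_take_regularized_path(self):
        base = _corr_noise(1, 500)
        noise = np.vstack([base, base])  # rank-1 covariance
        with pytest.warns(UserWarning, match="singular"):
            W = prewhiten(noise)
        assert np.all(np.isfinite(W))


class TestRovir:
    def test_separable_two_coil_case(self):
        img = np.zeros((2, 8, 8, 8), complex)
        roi = np.zeros((8, 8, 8), bool)
        roi[:, :, :4] = True
        inter = np.zeros((8, 8, 8), bool)
        inter[:, :, 5:] = True
        img[0][roi] = 1.0
        img[1][inter] = 1.0
        w, mu = rovir_weights(img, roi, inter, n_drop=1)
        assert abs(w[0, 0]) > 0.99  # top virtual coil is the ROI-only coil

    def test_generalized_eigen_equation_holds(self):
        rng = np.random.default_rng(3)
        img = rng.standard_normal((8, 6, 6, 6)) + 1j * rng.standard_normal((8, 6, 6, 6))
        roi = np.zeros((6, 6, 6), bool)
        roi[:3] = True
        inter = ~roi
        inter[3] = False  # guard band keeps masks disjoint with a gap
        w, mu = rovir_weights(img, roi, inter, n_drop=0, ridge=0.0)
        flat = img.reshape(8, -1)
        g_roi = flat[:, roi.ravel()] @ flat[:, roi.ravel()].conj().T
        g_int = flat[:, inter.ravel()] @ flat[:, inter.ravel()].conj().T
        for row, m in zip(w, mu):
            v = row.conj()
            resid = g_roi @ v - m * (g_int @ v)
            assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(g_roi @ v)

    def test_ratios_monotone_nonincreasing(self):
        rng = np.random.default_rng(4)
        img = rng.standard_normal((8, 6, 6, 6)) + 1j * rng.standard_normal((8, 6, 6, 6))
        roi = np.zeros((6, 6, 6), bool)
        roi[:3] = True
        w, mu = rovir_weights(img, roi, ~roi, n_drop=2)
        assert np.all(np.diff(mu) <= 1e-9)

    def test_masks_validated(self):
        img = np.ones((2, 4, 4, 4), complex)
        empty = np.zeros((4, 4, 4), bool)
        with pytest.raises(ValueError):
            rovir_weights(img, empty, ~empty)


class TestCompression:
    def test_identity_settings_preserve_energy(self):
        rng = np.random.default_rng(5)
        img = rng.standard_normal((4, 6, 6, 6)) + 1j * rng.standard_normal((4, 6, 6, 6))
        cal = CalibrationImage(image=img, voxel_size_mm=(7.0,) * 3, fov_mm=(440.0,) * 3)
        roi = np.zeros((6, 6, 6), bool)
        roi[2:4] = True
        comp = build_compression(cal, roi, ~roi, n_drop=0, n_out=4)
        out = comp.apply(img)
        assert abs(np.linalg.norm(out) - np.linalg.norm(img)) < 1e-8 * np.linalg.norm(img)

    def test_reference_channel_budget(self):
        """48 physical channels -> drop 8 ROVir coils -> 10 SVD channels."""
        rng = np.random.default_rng(6)
        img = rng.standard_normal((48, 6, 6, 6)) + 1j * rng.standard_normal((48, 6, 6, 6))
        cal = CalibrationImage(image=img, voxel_size_mm=(7.0,) * 3, fov_mm=(440.0,) * 3)
        roi = np.zeros((6, 6, 6), bool)
        roi[2:4] = True
        comp = build_compression(cal, roi, ~roi, n_drop=8, n_out=10)
        assert comp.matrix.shape == (10, 48)
        assert comp.stages["rovir_keep"] == 40 and comp.stages["svd_out"] == 10

    def test_compression_commutes_with_forward_model(self):
        """Compressing maps then simulating equals simulating then compressing."""
        model = random_small_model(K=2, C=3, seed=11)
        rng = np.random.default_rng(7)
        m = rng.standard_normal((2, 3)) + 1j * rng.standard_normal((2, 3))
        x = rng.standard_normal((2, 8, 8, 8)) + 1j * rng.standard_normal((2, 8, 8, 8))
        b_full = apply_forward(model, CoefficientImage(data=x)).samples
        compressed_maps = np.tensordot(m, model.coil_maps.maps, axes=(1, 0))
        model2 = AcquisitionModel(
            basis=model.basis, coil_maps=CoilMaps(maps=compressed_maps), traj=model.traj, engine="direct"
        )
        b_comp = apply_forward(model2, CoefficientImage(data=x)).samples
        b_mixed = np.tensordot(m, b_full, axes=(1, 0))
        assert np.linalg.norm(b_comp - b_mixed) / np.linalg.norm(b_mixed) < 1e-8


def _cal_with_blob(shift_vox=(0, 0)):
    n = 48
    z, y, x = np.meshgrid(*[np.arange(n) - n / 2] * 3, indexing="ij")
    zc, yc = shift_vox
    body = ((z - zc) / 10) ** 2 + ((y - yc) / 8) ** 2 + (x / 8) ** 2 <= 1.0
    img = np.stack([body * (1.0 + 0.2 * c) for c in range(3)]).astype(complex)
    return CalibrationImage(image=img, voxel_size_mm=(5.0,) * 3, fov_mm=(240.0,) * 3)


class TestAutoFov:
    def test_centered_object_needs_no_shift(self):
        shift = autofov(_cal_with_blob((0, 0)), (120.0,) * 3, margin_mm=10.0)
        assert np.all(np.abs(shift.shift_mm) <= 5.0)  # within one calibration voxel

    def test_known_translation_recovered(self):
        # a large margin makes the placement constraint bind in both positions,
        # so the recovered shifts differ by exactly the applied translation
        a = autofov(_cal_with_blob((0, 0)), (120.0,) * 3, margin_mm=55.0)
        b = autofov(_cal_with_blob((-4, -3)), (120.0,) * 3, margin_mm=55.0)
        delta = b.shift_mm - a.shift_mm
        assert abs(delta[0] - (-4) * 5.0) <= 5.0  # within one calibration voxel
        assert abs(delta[1] - (-3) * 5.0) <= 5.0
        assert delta[2] == 0.0

    def test_fourier_shift_recenters_object(self):
        """The linear k-space phase translates the reconstructed image."""
        n = 16
        img = np.zeros((n, n, n))
        img[6:10, 6:10, 6:10] = 1.0
        ax = np.arange(n) - n // 2
        coords = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3).astype(float)
        y = nufft_forward(img.astype(complex), coords, engine="direct")
        shifted = apply_fov_shift_kspace(y, coords, (2.0, 0.0, 0.0), n)
        back = nufft_adjoint(shifted, coords, (n, n, n), engine="direct") / n**3
        expected = np.roll(img, 2, axis=0)
        assert np.max(np.abs(back - expected)) < 1e-10

    def test_empty_foreground_raises(self):
        img = np.zeros((2, 8, 8, 8), complex)
        img += 1e-12
        cal = CalibrationImage(image=img, voxel_size_mm=(5.0,) * 3, fov_mm=(240.0,) * 3)
        with pytest.raises(ValueError):
            autofov(cal, (120.0,) * 3)


def test_smoothed_quotient_maps_recover_smooth_sensitivities():
    rng = np.random.default_rng(9)
    n = 16
    z, y, x = np.meshgrid(*[np.linspace(-1, 1, n)] * 3, indexing="ij")
    true = np.stack([np.exp(-(x - 0.3) ** 2 - y**2) * np.exp(1j * 0.5 * y), np.exp(-(x + 0.3) ** 2 - z**2)])
    sos = np.sqrt((np.abs(true) ** 2).sum(axis=0))
    true /= sos
    obj = np.exp(-(x**2 + y**2 + z**2) / 0.3)
    est = estimate_coil_maps(true * obj[None], smooth_sigma_vox=1.0)
    core = (slice(None), slice(4, 12), slice(4, 12), slice(4, 12))
    ratio = np.abs(est[core]) / np.abs(true[core])
    assert np.std(ratio) / np.mean(ratio) < 0.2
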