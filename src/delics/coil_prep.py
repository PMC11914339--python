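"""Calibration-scan coil processing.

A short large-FOV gradient-echo pre-scan drives four steps that are folded
into a single channel-compression matrix applied to the fingerprinting
k-space data:

* noise pre-whitening (Cholesky of the sample noise covariance),
* region-optimized virtual coils (ROVir): a generalized eigenproblem that
  orders virtual channels by their signal-to-interference ratio between a
  region of interest and everything outside the target FOV, dropping the
  most interference-dominated ones,
* SVD compression of the remaining channels,
* automatic FOV centering from a smoothed, binarized maximum-intensity
  projection of the coil-combined calibration image.

Channel mixing is linear and acquisition-domain-agnostic, so the matrix
computed from the calibration image applies unchanged to non-Cartesian
k-space samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "CalibrationImage",
    "CompressionMatrix",
    "FOVShift",
    "prewhiten",
    "rovir_weights",
    "build_compression",
    "autofov",
    "apply_fov_shift_kspace",
    "estimate_coil_maps",
]


@dataclass(frozen=True)
class CalibrationImage:
    """Low-resolution multi-coil calibration volume, (n_coils, Z, Y, X)."""

    image: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    fov_mm: tuple[float, float, float]

    def __post_init__(self):
        img = np.asarray(self.image, dtype=np.complex128)
        if img.ndim != 4:
            raise ValueError("image must be (n_coils, Z, Y, X)")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")
        object.__setattr__(self, "image", img)

    @property
    def n_coils(self) -> int:
        return self.image.shape[0]


@dataclass(frozen=True)
class CompressionMatrix:
    """Composite channel-mixing matrix (n_out, n_in) with stage provenance."""

    matrix: np.ndarray
    stages: dict

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.complex128)
        if m.ndim != 2 or m.shape[0] > m.shape[1]:
            raise ValueError("matrix must be (n_out, n_in) with n_out <= n_in")
        if np.linalg.matrix_rank(m) < m.shape[0]:
            raise ValueError("compression matrix must have full row rank")
        object.__setattr__(self, "matrix", m)

    def apply(self, data: np.ndarray) -> np.ndarray:
        """Mix the leading (channel) axis of ``data``."""
        d = np.asarray(data)
        return np.tensordot(self.matrix, d, axes=(1, 0))


@dataclass(frozen=True)
class FOVShift:
    shift_mm: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.shift_mm, dtype=float)
        if s.shape != (3,) or not np.all(np.isfinite(s)):
            raise ValueError("shift_mm must be a finite 3-vector")
        object.__setattr__(self, "shift_mm", s)


def prewhiten(noise_samples: np.ndarray, ridge: float = 1e-9) -> np.ndarray:
    """Whitening matrix W with W Sigma W^H = I from noise-only observations.

    ``noise_samples`` is (n_coils, n_obs).  A singular sample covariance is
    ridge-regularized with a warning.
    """
    noise = np.asarray(noise_samples, dtype=np.complex128)
    if noise.ndim != 2 or noise.shape[1] < noise.shape[0]:
        raise ValueError("need at least n_coils noise observations")
    n = noise.shape[1]
    cov = noise @ noise.conj().T / n
    scale = float(np.real(np.trace(cov)) / cov.shape[0])
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular noise covariance; ridge-regularizing")
        cov = cov + ridge * scale * np.eye(cov.shape[0])
        chol = np.linalg.cholesky(cov)
    return scipy.linalg.solve_triangular(chol, np.eye(cov.shape[0]), lower=True)


def _gram(vectors: np.ndarray) -> np.ndarray:
    # vectors: (n_coils, n_voxels)
    return vectors @ vectors.conj().T


def rovir_weights(
    cal: CalibrationImage | np.ndarray,
    roi_mask: np.ndarray,
    interference_mask: np.ndarray,
    n_drop: int = 8,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Region-optimized virtual coil weights.

    Solves the generalized eigenproblem G_roi v = mu G_int v built from the
    per-voxel coil vectors inside the two (disjoint, non-empty) masks and
    returns ``(weights, mu)`` where ``weights`` is (n_keep, n_coils) ordered
    by descending signal-to-interference ratio mu with the ``n_drop``
    lowest-ratio virtual coils removed; rows are unit-normalized.
    """
    img = cal.image if isinstance(cal, CalibrationImage) else np.asarray(cal, dtype=np.complex128)
    roi = np.asarray(roi_mask, dtype=bool)
    inter = np.asarray(interference_mask, dtype=bool)
    if not roi.any() or not inter.any():
        raise ValueError("masks must be non-empty")
    if np.any(roi & inter):
        raise ValueError("roi and interference masks must be disjoint")
    nc = img.shape[0]
    flat = img.reshape(nc, -1)
    g_roi = _gram(flat[:, roi.ravel()])
    g_int = _gram(flat[:, inter.ravel()])
    scale = float(np.real(np.trace(g_int)) / nc)
    if scale == 0 or np.linalg.matrix_rank(g_int) < nc:
        g_int = g_int + ridge * max(scale, 1.0) * np.eye(nc)
    mu, vecs = scipy.linalg.eigh(g_roi, g_int)
    order = np.argsort(mu)[::-1]
    mu = np.real(mu[order])
    vecs = vecs[:, order]
    keep = nc - n_drop
    if keep < 1:
        raise ValueError("n_drop leaves no virtual coils")
    w = vecs[:, :keep].conj().T  # rows mix physical channels
    w = w / np.linalg.norm(w, axis=1, keepdims=True)
    return w, mu[:keep]


def build_compression(
    cal: CalibrationImage,
    roi_mask: np.ndarray,
    interference_mask: np.ndarray,
    n_drop: int = 8,
    n_out: int = 10,
    noise_samples: np.ndarray | None = None,
) -> CompressionMatrix:
    """Whitening -> ROVir retention -> SVD compression to ``n_out`` channels.

    The reference protocol compresses 48 physical channels by dropping 8
    interference-dominated virtual coils and SVD-compressing the remaining
    40 to 10.  When no noise samples are given the whitening stage is the
    identity.
    """
    nc = cal.n_coils
    if n_out > nc - n_drop:
        raise ValueError("n_out exceeds the retained channel count")
    white = prewhiten(noise_samples) if noise_samples is not None else np.eye(nc, dtype=complex)
    whitened = CalibrationImage(
        image=np.tensordot(white, cal.image, axes=(1, 0)),
        voxel_size_mm=cal.voxel_size_mm,
        fov_mm=cal.fov_mm,
    )
    if n_drop > 0:
        rovir, mu = rovir_weights(whitened, roi_mask, interference_mask, n_drop=n_drop)
    else:
        rovir, mu = np.eye(nc, dtype=complex), np.full(nc, np.nan)
    mixed = np.tensordot(rovir, whitened.image, axes=(1, 0)).reshape(rovir.shape[0], -1)
    if n_out < rovir.shape[0]:
        u, _, _ = np.linalg.svd(mixed, full_matrices=False)
        svd_stage = u[:, :n_out].conj().T
    else:
        svd_stage = np.eye(rovir.shape[0], dtype=complex)
    matrix = svd_stage @ rovir @ white
    return CompressionMatrix(
        matrix=matrix,
        stages={
            "whitening": noise_samples is not None,
            "rovir_keep": int(rovir.shape[0]),
            "rovir_ratios": mu,
            "svd_out": int(matrix.shape[0]),
        },
    )


def autofov(
    cal: CalibrationImage,
    target_fov_mm: tuple[float, float, float],
    smooth_sigma_vox: float = 2.0,
    margin_mm: float = 10.0,
) -> FOVShift:
    """Shift that brings the anatomy inside the target FOV.

    Sum-of-squares coil combination, maximum-intensity projection through
    the sagittal plane (along the left-right axis), Gaussian smoothing, Otsu
    binarization, largest connected component, bounding box; the shift
    places the box's superior and anterior edges a margin inside the target
    FOV.  Axis order is (Z, Y, X) = (superior-inferior, anterior-posterior,
    left-right); the left-right shift is zero.
    """
    if any(c < t for c, t in zip(cal.fov_mm, target_fov_mm)):
        raise ValueError("calibration FOV must cover the target FOV")
    sos = np.sqrt(np.sum(np.abs(cal.image) ** 2, axis=0))
    mip = sos.max(axis=2)  # (Z, Y): project along left-right
    sm = gaussian(mip, sigma=smooth_sigma_vox)
    binary = sm > threshold_otsu(sm)
    if not binary.any():
        raise ValueError("empty foreground after binarization")
    lab = label(binary)
    regions = regionprops(lab)
    largest = max(regions, key=lambda r: r.area)
    zmin, ymin, zmax, ymax = largest.bbox
    vz, vy, _ = cal.voxel_size_mm
    nz, ny = mip.shape
    # mm coordinates of the box edges relative to the volume center
    top_mm = (zmin - nz / 2.0) * vz  # superior edge (low index = superior)
    front_mm = (ymin - ny / 2.0) * vy  # anterior edge
    half_z = target_fov_mm[0] / 2.0
    half_y = target_fov_mm[1] / 2.0
    # move the FOV only as far as needed to pull the top/front edges a
    # margin inside it; an object already inside needs no shift
    dz = min(0.0, top_mm + half_z - margin_mm)
    dy = min(0.0, front_mm + half_y - margin_mm)
    return FOVShift(shift_mm=np.array([dz, dy, 0.0]))


def apply_fov_shift_kspace(
    samples: np.ndarray, coords: np.ndarray, shift_vox, matrix_size: int
) -> np.ndarray:
    """Re-center by the Fourier shift theorem: multiply by exp(-2pi i k . d / N).

    ``coords`` are trajectory coordinates in matrix-index units with shape
    (..., 3) flattening consistently with the trailing sample axis of
    ``samples``; ``shift_vox`` is the image-domain displacement in voxels of
    the imaging grid of size ``matrix_size``.
    """
    c = np.asarray(coords, dtype=float).reshape(-1, 3)
    shift = np.asarray(shift_vox, dtype=float)
    phase = np.exp(-2j * np.pi * (c @ shift) / matrix_size)
    flat = samples.reshape(samples.shape[0], -1) if samples.ndim > 1 else samples[None]
    out = flat * phase[None, :]
    return out.reshape(samples.shape)


def estimate_coil_maps(coil_images: np.ndarray, smooth_sigma_vox: float = 3.0) -> np.ndarray:
    """Smoothed-quotient sensitivity estimate: lowpass(coil) / sum-of-squares.

    A practical fallback when ground-truth maps are unavailable; each coil
    image is smoothed (real and imaginary parts separately) and divided by
    the smoothed root-sum-of-squares magnitude.
    """
    imgs = np.asarray(coil_images, dtype=np.complex128)
    sm = np.stack(
        [
            gaussian(im.real, sigma=smooth_sigma_vox) + 1j * gaussian(im.imag, sigma=smooth_sigma_vox)
            for im in imgs
        ]
    )
    sos = np.sqrt(np.sum(np.abs(sm) ** 2, axis=0))
    sos = np.maximum(sos, 1e-12 * sos.max())
    return sm / sos
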