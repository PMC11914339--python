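"""Digital brain-like phantoms: the synthetic stand-in for scanner data.

A phantom is a nest of ellipsoids assigned brain-tissue relaxation values
(white matter, gray matter, CSF, an optional lesion), with smooth complex
coil sensitivities and a ground-truth coefficient volume obtained by
compressing each voxel's simulated fingerprint onto the temporal basis.
K-space data are generated through the same acquisition operator the
reconstruction inverts (deliberately so: the package's claims concern
solver and warm-start behaviour, not acquisition realism; a mismatched
NUFFT accuracy mode is available to break that symmetry when wanted).

Tissue (T1, T2) defaults are chosen on the reference dictionary grid so
that noiseless recovery tests can demand exact grid matches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coil_prep import CalibrationImage
from .forward_model import AcquisitionModel, CoefficientImage, CoilMaps, KSpaceData, apply_forward
from .mrf_signal import SequenceParams, SubspaceBasis, _simulate_epg_batch
from .sampling import Trajectory

__all__ = ["TissueClass", "PhantomSpec", "GroundTruth", "make_phantom", "simulate_acquisition", "simulate_calibration"]


@dataclass(frozen=True)
class TissueClass:
    name: str
    t1_ms: float
    t2_ms: float
    pd: float


DEFAULT_TISSUES = (
    TissueClass("wm", 800.0, 60.0, 0.80),
    TissueClass("gm", 1300.0, 90.0, 0.90),
    TissueClass("csf", 4000.0, 1900.0, 1.00),
    TissueClass("lesion", 1100.0, 150.0, 1.00),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue and acquisition-noise parameters of one phantom."""

    matrix_size: int = 64
    tissue_classes: tuple = DEFAULT_TISSUES
    n_coils: int = 3
    noise_sigma: float = 0.05  # complex noise std as a fraction of RMS |b|
    outside_fov_source: tuple | None = None  # (offset_fraction xyz, amplitude)
    bandlimit_fraction: float | None = None  # restrict x_true to |k| <= frac * N/2
    seed: int = 0

    def __post_init__(self):
        if self.matrix_size < 16:
            raise ValueError("matrix_size must be at least 16")
        for tc in self.tissue_classes:
            if tc.t1_ms <= 0 or tc.t2_ms <= 0:
                raise ValueError("tissue relaxation times must be positive")
        if self.n_coils < 1:
            raise ValueError("need at least one coil")


@dataclass
class GroundTruth:
    labels: np.ndarray  # int volume, 0 = background, i+1 = tissue_classes[i]
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    pd: np.ndarray
    mask: np.ndarray
    coil_maps: CoilMaps
    x_true: CoefficientImage
    spec: PhantomSpec


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return d <= 1.0


def _tissue_geometry(n: int, rng: np.random.Generator, n_classes: int) -> np.ndarray:
    """Nested-ellipsoid label volume; mild seeded jitter varies geometry."""
    jit = lambda lo, hi: lo + (hi - lo) * rng.random()
    c0 = np.array([n / 2 + rng.uniform(-0.02, 0.02) * n for _ in range(3)])
    labels = np.zeros((n, n, n), dtype=np.int16)
    head = _ellipsoid((n, n, n), c0, np.array([jit(0.40, 0.44), jit(0.34, 0.38), jit(0.34, 0.38)]) * n)
    labels[head] = 2  # gray-matter shell
    wm = _ellipsoid((n, n, n), c0, np.array([jit(0.30, 0.34), jit(0.25, 0.29), jit(0.25, 0.29)]) * n)
    labels[wm] = 1
    if n_classes >= 3:  # CSF ventricles
        for sgn in (-1.0, 1.0):
            cv = c0 + np.array([jit(-0.02, 0.02), jit(0.02, 0.05) * sgn, sgn * jit(0.06, 0.09)]) * n
            vent = _ellipsoid((n, n, n), cv, np.array([jit(0.10, 0.14), jit(0.05, 0.07), jit(0.035, 0.05)]) * n)
            labels[vent & wm] = 3
    if n_classes >= 4:  # one focal lesion inside white matter
        cl = c0 + np.array([jit(-0.12, 0.12), jit(-0.10, 0.10), jit(-0.10, 0.10)]) * n
        les = _ellipsoid((n, n, n), cl, np.full(3, jit(0.045, 0.07)) * n)
        labels[les & (labels == 1)] = 4
    if not labels.any():
        raise ValueError("degenerate geometry: empty foreground")
    return labels


def _coil_fields(n: int, n_coils: int, rng: np.random.Generator, fov_scale: float = 1.0) -> np.ndarray:
    """Smooth complex sensitivities: loop-like magnitude falloff, low-order phase.

    ``fov_scale`` > 1 evaluates the same coil geometry over an enlarged FOV
    (for calibration scans), keeping coil positions fixed relative to the
    imaging volume.
    """
    z, y, x = np.meshgrid(*[np.linspace(-fov_scale, fov_scale, n)] * 3, indexing="ij")
    maps = np.empty((n_coils, n, n, n), dtype=np.complex128)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.15, 0.15)
        pos = np.array([rng.uniform(-0.25, 0.25), 0.95 * np.sin(ang), 0.95 * np.cos(ang)])
        d2 = (z - pos[0]) ** 2 + (y - pos[1]) ** 2 + (x - pos[2]) ** 2
        mag = 1.0 / (0.35 + d2)
        ph = (
            rng.uniform(-np.pi, np.pi)
            + rng.uniform(-1.0, 1.0) * y
            + rng.uniform(-1.0, 1.0) * x
            + rng.uniform(-0.5, 0.5) * z
        )
        maps[c] = mag * np.exp(1j * ph)
    # SENSE convention: unit sum-of-squares magnitude everywhere
    sos = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= sos[None]
    return maps


def class_coefficients(spec: PhantomSpec, basis: SubspaceBasis, seq: SequenceParams) -> np.ndarray:
    """Subspace coefficient vector (K,) of each tissue class's unit-PD fingerprint."""
    t1 = np.array([tc.t1_ms for tc in spec.tissue_classes])
    t2 = np.array([tc.t2_ms for tc in spec.tissue_classes])
    fps = _simulate_epg_batch(t1, t2, seq)  # (n_classes, n_tr)
    return basis.compress(fps)  # (n_classes, K)


def make_phantom(spec: PhantomSpec, basis: SubspaceBasis, seq: SequenceParams) -> GroundTruth:
    """Deterministic (seeded) phantom with ground-truth maps and coefficients."""
    rng = np.random.default_rng(spec.seed)
    n = spec.matrix_size
    labels = _tissue_geometry(n, rng, len(spec.tissue_classes))
    t1 = np.zeros((n, n, n))
    t2 = np.zeros((n, n, n))
    pd = np.zeros((n, n, n))
    for i, tc in enumerate(spec.tissue_classes):
        sel = labels == i + 1
        t1[sel], t2[sel], pd[sel] = tc.t1_ms, tc.t2_ms, tc.pd
    coeffs = class_coefficients(spec, basis, seq)  # (n_classes, K)
    x = np.zeros((basis.K, n, n, n), dtype=np.complex128)
    for i in range(len(spec.tissue_classes)):
        sel = labels == i + 1
        for k in range(basis.K):
            x[k][sel] = coeffs[i, k] * pd[sel]
    # dedicated stream so the calibration scan sees the identical coil draws
    if spec.bandlimit_fraction is not None:
        # restrict the truth to the spherical k-space support the spiral
        # acquisition actually measures; frequencies outside it are invisible
        # to the forward model and cannot be recovered by any solver
        ax = np.arange(n) - n // 2
        kz, ky, kx = np.meshgrid(ax, ax, ax, indexing="ij")
        ball = np.sqrt(kz**2 + ky**2 + kx**2) <= spec.bandlimit_fraction * n / 2
        for k in range(basis.K):
            spec_k = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x[k])))
            x[k] = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(spec_k * ball)))
    # dedicated stream so the calibration scan sees the identical coil draws
    maps = _coil_fields(n, spec.n_coils, np.random.default_rng(spec.seed + 7))
    return GroundTruth(
        labels=labels,
        t1_ms=t1,
        t2_ms=t2,
        pd=pd,
        mask=labels > 0,
        coil_maps=CoilMaps(maps=maps),
        x_true=CoefficientImage(data=x),
        spec=spec,
    )


def simulate_acquisition(
    gt: GroundTruth,
    traj: Trajectory,
    basis: SubspaceBasis,
    noise_sigma: float | None = None,
    seed: int = 0,
    engine: str = "gridding",
) -> KSpaceData:
    """b = A x_true + complex Gaussian noise.

    ``noise_sigma`` (default: the phantom spec's value) is the per-component
    noise standard deviation expressed as a fraction of the RMS magnitude of
    the noiseless data; the same operator code path used by reconstruction
    generates the data.
    """
    model = AcquisitionModel(basis=basis, coil_maps=gt.coil_maps, traj=traj, engine=engine)
    b = apply_forward(model, gt.x_true)
    sigma_rel = gt.spec.noise_sigma if noise_sigma is None else noise_sigma
    if sigma_rel > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma_rel * float(np.sqrt(np.mean(np.abs(b.samples) ** 2)))
        noise = sigma * (
            rng.standard_normal(b.samples.shape) + 1j * rng.standard_normal(b.samples.shape)
        )
        b = KSpaceData(samples=b.samples + noise, traj=traj)
    return b


def simulate_calibration(
    gt: GroundTruth,
    large_fov_factor: float = 2.0,
    cal_matrix: int = 32,
    outside_fov_source: tuple | None = None,
) -> CalibrationImage:
    """Low-resolution multi-coil calibration volume on an enlarged FOV.

    The phantom's proton-density image sits at the center of a FOV enlarged
    by ``large_fov_factor`` (the reference protocol pairs a 440 mm
    calibration FOV with a 220 mm imaging FOV); an optional bright blob
    outside the imaging FOV emulates shoulder/neck interference for coil
    preprocessing tests.  ``outside_fov_source`` is ((dz, dy, dx) as a
    fraction of the calibration FOV, amplitude).
    """
    if large_fov_factor < 1:
        raise ValueError("large_fov_factor must be >= 1")
    spec = gt.spec
    rng = np.random.default_rng(spec.seed + 1)
    m = cal_matrix
    # proton image resampled onto the central 1/factor of the calibration grid
    n = spec.matrix_size
    inner = max(4, int(round(m / large_fov_factor)))
    stride = max(1, n // inner)
    small = np.abs(gt.pd[::stride, ::stride, ::stride])[:inner, :inner, :inner]
    proton = np.zeros((m, m, m))
    o = (m - small.shape[0]) // 2
    proton[o : o + small.shape[0], o : o + small.shape[1], o : o + small.shape[2]] = small
    src = outside_fov_source if outside_fov_source is not None else spec.outside_fov_source
    if src is not None:
        offset_frac, amp = src
        center = np.array([m / 2] * 3) + np.asarray(offset_frac) * m
        blob = _ellipsoid((m, m, m), center, np.full(3, 0.08 * m))
        proton = proton + amp * blob
    maps = _coil_fields(m, spec.n_coils, np.random.default_rng(spec.seed + 7), fov_scale=large_fov_factor)
    image = maps * proton[None]
    # small measurement noise so the calibration is not synthetically clean
    image = image + 1e-4 * proton.max() * (
        rng.standard_normal(image.shape) + 1j * rng.standard_normal(image.shape)
    )
    fov = 220.0 * large_fov_factor
    vox = fov / m
    return CalibrationImage(image=image, voxel_size_mm=(vox, vox, vox), fov_mm=(fov, fov, fov))
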