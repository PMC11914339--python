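"""Non-uniform FFT between Cartesian image volumes and arbitrary k-space samples.

Two engines are provided:

``gridding``
    Kaiser–Bessel interpolation onto an oversampled FFT grid (the standard
    gridding NUFFT).  The forward and adjoint share the same interpolation
    weights, so they form an exact adjoint pair by construction; accuracy
    relative to the exact sum is set by the oversampling factor and kernel
    width.
``direct``
    The exact (slow) discrete sum, intended for small problems and as the
    reference the gridding engine is validated against.

Conventions: k-space coordinates are in cycles/FOV scaled to matrix index
units, each axis in [-N/2, N/2); the image DC voxel sits at index N//2.
The forward transform computes  y(k) = sum_n x[n] exp(-2j pi k.(n - N//2)/N).
Kernel interpolation wraps periodically on the oversampled grid, which is
the correct topology for a sampled spectrum.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import i0 as _bessel_i0

try:  # pragma: no cover - exercised implicitly
    import numba as _nb

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["nufft_forward", "nufft_adjoint", "kernel_convolve_at_samples"]

DEFAULT_OVERSAMPLING = 1.25
DEFAULT_WIDTH = 4


def _beatty_beta(width: int, os: float) -> float:
    """Kaiser–Bessel shape parameter minimizing aliasing error (Beatty's rule)."""
    return np.pi * np.sqrt((width / os) ** 2 * (os - 0.5) ** 2 - 0.8)


def _os_grid_shape(shape: tuple[int, ...], os: float) -> tuple[int, ...]:
    return tuple(max(int(np.ceil(n * os / 2) * 2), n) for n in shape)


@lru_cache(maxsize=32)
def _apodization(shape: tuple[int, ...], os_shape: tuple[int, ...], width: int, beta: float):
    """Separable image-domain correction: the kernel's Fourier transform per axis."""
    axes = []
    for n, g in zip(shape, os_shape):
        f = (np.arange(n) - n // 2) / g
        arg = (np.pi * width * f) ** 2 - beta**2
        # sinh(sqrt(-arg))/sqrt(-arg) continued analytically through arg = 0
        with np.errstate(invalid="ignore"):
            pos = np.sqrt(np.abs(arg))
        val = np.where(arg < 0, np.sinh(pos) / np.where(pos == 0, 1.0, pos), np.sinc(pos / np.pi))
        val = np.where(np.abs(arg) < 1e-12, 1.0, val)
        axes.append(val * width / _bessel_i0(beta))
    out = axes[0]
    for a in axes[1:]:
        out = np.multiply.outer(out, a)
    return out


def _kb_weight(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser–Bessel kernel value at offset u (grid units), support |u| <= width/2."""
    inside = np.abs(u) <= width / 2
    t = np.zeros_like(u, dtype=float)
    arg = 1.0 - (2.0 * np.clip(u, -width / 2, width / 2) / width) ** 2
    t[inside] = _bessel_i0(beta * np.sqrt(np.clip(arg[inside], 0.0, None))) / _bessel_i0(beta)
    return t


# ---------------------------------------------------------------------------
# numba kernels (3-D and 2-D gather/scatter with periodic wrap)
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @_nb.njit(cache=True, fastmath=True)
    def _kb_scalar(u, width, beta, i0beta):
        if abs(u) > width / 2:
            return 0.0
        a = 1.0 - (2.0 * u / width) ** 2
        if a < 0.0:
            a = 0.0
        x = beta * np.sqrt(a)
        # I0 via series; x <= beta (~ 11 for width 4) so this converges fast
        term = 1.0
        s = 1.0
        xx = 0.25 * x * x
        for k in range(1, 30):
            term *= xx / (k * k)
            s += term
            if term < 1e-14 * s:
                break
        return s / i0beta

    @_nb.njit(cache=True, fastmath=True)
    def _i0_scalar(x):
        term = 1.0
        s = 1.0
        xx = 0.25 * x * x
        for k in range(1, 40):
            term *= xx / (k * k)
            s += term
            if term < 1e-15 * s:
                break
        return s

    @_nb.njit(cache=True, fastmath=True)
    def _gather3(grid, coords, width, beta, out):
        g0, g1, g2 = grid.shape
        i0b = _i0_scalar(beta)
        half = width // 2
        w0 = np.empty(width)
        w1 = np.empty(width)
        w2 = np.empty(width)
        for p in range(coords.shape[0]):
            k0 = coords[p, 0] + g0 // 2
            k1 = coords[p, 1] + g1 // 2
            k2 = coords[p, 2] + g2 // 2
            b0 = int(np.floor(k0)) - half + 1
            b1 = int(np.floor(k1)) - half + 1
            b2 = int(np.floor(k2)) - half + 1
            for a in range(width):
                w0[a] = _kb_scalar(k0 - (b0 + a), width, beta, i0b)
                w1[a] = _kb_scalar(k1 - (b1 + a), width, beta, i0b)
                w2[a] = _kb_scalar(k2 - (b2 + a), width, beta, i0b)
            acc = 0.0 + 0.0j
            for a in range(width):
                if w0[a] == 0.0:
                    continue
                i = (b0 + a) % g0
                for b in range(width):
                    if w1[b] == 0.0:
                        continue
                    j = (b1 + b) % g1
                    w01 = w0[a] * w1[b]
                    for c in range(width):
                        if w2[c] == 0.0:
                            continue
                        l = (b2 + c) % g2
                        acc += grid[i, j, l] * (w01 * w2[c])
            out[p] = acc

    @_nb.njit(cache=True, fastmath=True)
    def _scatter3(vals, coords, width, beta, grid):
        g0, g1, g2 = grid.shape
        i0b = _i0_scalar(beta)
        half = width // 2
        w0 = np.empty(width)
        w1 = np.empty(width)
        w2 = np.empty(width)
        for p in range(coords.shape[0]):
            k0 = coords[p, 0] + g0 // 2
            k1 = coords[p, 1] + g1 // 2
            k2 = coords[p, 2] + g2 // 2
            b0 = int(np.floor(k0)) - half + 1
            b1 = int(np.floor(k1)) - half + 1
            b2 = int(np.floor(k2)) - half + 1
            for a in range(width):
                w0[a] = _kb_scalar(k0 - (b0 + a), width, beta, i0b)
                w1[a] = _kb_scalar(k1 - (b1 + a), width, beta, i0b)
                w2[a] = _kb_scalar(k2 - (b2 + a), width, beta, i0b)
            v = vals[p]
            for a in range(width):
                if w0[a] == 0.0:
                    continue
                i = (b0 + a) % g0
                for b in range(width):
                    if w1[b] == 0.0:
                        continue
                    j = (b1 + b) % g1
                    w01 = w0[a] * w1[b]
                    for c in range(width):
                        if w2[c] == 0.0:
                            continue
                        l = (b2 + c) % g2
                        grid[i, j, l] += v * (w01 * w2[c])

    @_nb.njit(cache=True, fastmath=True)
    def _gather2(grid, coords, width, beta, out):
        g0, g1 = grid.shape
        i0b = _i0_scalar(beta)
        half = width // 2
        for p in range(coords.shape[0]):
            k0 = coords[p, 0] + g0 // 2
            k1 = coords[p, 1] + g1 // 2
            b0 = int(np.floor(k0)) - half + 1
            b1 = int(np.floor(k1)) - half + 1
            acc = 0.0 + 0.0j
            for a in range(width):
                w0 = _kb_scalar(k0 - (b0 + a), width, beta, i0b)
                if w0 == 0.0:
                    continue
                i = (b0 + a) % g0
                for b in range(width):
                    w1 = _kb_scalar(k1 - (b1 + b), width, beta, i0b)
                    if w1 == 0.0:
                        continue
                    j = (b1 + b) % g1
                    acc += grid[i, j] * (w0 * w1)
            out[p] = acc

    @_nb.njit(cache=True, fastmath=True)
    def _scatter2(vals, coords, width, beta, grid):
        g0, g1 = grid.shape
        i0b = _i0_scalar(beta)
        half = width // 2
        for p in range(coords.shape[0]):
            k0 = coords[p, 0] + g0 // 2
            k1 = coords[p, 1] + g1 // 2
            b0 = int(np.floor(k0)) - half + 1
            b1 = int(np.floor(k1)) - half + 1
            v = vals[p]
            for a in range(width):
                w0 = _kb_scalar(k0 - (b0 + a), width, beta, i0b)
                if w0 == 0.0:
                    continue
                i = (b0 + a) % g0
                for b in range(width):
                    w1 = _kb_scalar(k1 - (b1 + b), width, beta, i0b)
                    if w1 == 0.0:
                        continue
                    j = (b1 + b) % g1
                    grid[i, j] += v * (w0 * w1)


def _gather(grid: np.ndarray, coords: np.ndarray, width: int, beta: float) -> np.ndarray:
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    out = np.zeros(coords.shape[0], dtype=np.complex128)
    grid = np.ascontiguousarray(grid, dtype=np.complex128)
    if _HAVE_NUMBA and grid.ndim == 3:
        _gather3(grid, coords, width, beta, out)
        return out
    if _HAVE_NUMBA and grid.ndim == 2:
        _gather2(grid, coords, width, beta, out)
        return out
    return _gather_numpy(grid, coords, width, beta)


def _scatter(vals: np.ndarray, coords: np.ndarray, shape: tuple[int, ...], width: int, beta: float) -> np.ndarray:
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    vals = np.ascontiguousarray(vals, dtype=np.complex128)
    grid = np.zeros(shape, dtype=np.complex128)
    if _HAVE_NUMBA and len(shape) == 3:
        _scatter3(vals, coords, width, beta, grid)
        return grid
    if _HAVE_NUMBA and len(shape) == 2:
        _scatter2(vals, coords, width, beta, grid)
        return grid
    return _scatter_numpy(vals, coords, shape, width, beta)


def _offsets(width: int, ndim: int):
    rng = np.arange(width)
    grids = np.meshgrid(*([rng] * ndim), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)  # (width^d, d)


def _gather_numpy(grid, coords, width, beta):
    shape = grid.shape
    nd = grid.ndim
    pos = coords + np.array([g // 2 for g in shape])
    base = np.floor(pos).astype(np.int64) - width // 2 + 1
    out = np.zeros(coords.shape[0], dtype=np.complex128)
    for off in _offsets(width, nd):
        pts = base + off
        w = np.ones(coords.shape[0])
        for d in range(nd):
            w *= _kb_weight(pos[:, d] - pts[:, d], width, beta)
        idx = tuple((pts[:, d] % shape[d]) for d in range(nd))
        out += grid[idx] * w
    return out


def _scatter_numpy(vals, coords, shape, width, beta):
    nd = len(shape)
    pos = coords + np.array([g // 2 for g in shape])
    base = np.floor(pos).astype(np.int64) - width // 2 + 1
    grid = np.zeros(shape, dtype=np.complex128)
    for off in _offsets(width, nd):
        pts = base + off
        w = np.ones(coords.shape[0])
        for d in range(nd):
            w *= _kb_weight(pos[:, d] - pts[:, d], width, beta)
        idx = tuple((pts[:, d] % shape[d]) for d in range(nd))
        np.add.at(grid, idx, vals * w)
    return grid


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _centered_fft(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x)))


def _centered_ifft_adjoint(x: np.ndarray) -> np.ndarray:
    # exact adjoint of _centered_fft (unnormalized inverse)
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(x))) * x.size


def _pad_centered(x: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.complex128)
    sl = tuple(slice(g // 2 - n // 2, g // 2 - n // 2 + n) for n, g in zip(x.shape, shape))
    out[sl] = x
    return out


def _crop_centered(x: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    sl = tuple(slice(g // 2 - n // 2, g // 2 - n // 2 + n) for n, g in zip(shape, x.shape))
    return x[sl]


def nufft_forward(
    image: np.ndarray,
    coords: np.ndarray,
    engine: str = "gridding",
    os: float = DEFAULT_OVERSAMPLING,
    width: int = DEFAULT_WIDTH,
) -> np.ndarray:
    """Evaluate the spectrum of ``image`` at non-Cartesian ``coords`` (P, ndim)."""
    image = np.asarray(image)
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != image.ndim:
        raise ValueError("coords must be (P, ndim) matching image dimensionality")
    if not np.all(np.isfinite(image)):
        raise ValueError("non-finite image input")
    if engine == "direct":
        return _direct(image, coords, adjoint=False)
    shape = image.shape
    gshape = _os_grid_shape(shape, os)
    beta = _beatty_beta(width, os)
    apod = _apodization(shape, gshape, width, beta)
    scale = np.array([g / n for n, g in zip(shape, gshape)])
    grid = _centered_fft(_pad_centered(image / apod, gshape))
    return _gather(grid, coords * scale, width, beta)


def nufft_adjoint(
    samples: np.ndarray,
    coords: np.ndarray,
    shape: tuple[int, ...],
    engine: str = "gridding",
    os: float = DEFAULT_OVERSAMPLING,
    width: int = DEFAULT_WIDTH,
) -> np.ndarray:
    """Adjoint transform: grid samples back to an image volume of ``shape``."""
    samples = np.asarray(samples)
    coords = np.asarray(coords, dtype=float)
    if engine == "direct":
        return _direct(samples, coords, adjoint=True, shape=shape)
    gshape = _os_grid_shape(tuple(shape), os)
    beta = _beatty_beta(width, os)
    apod = _apodization(tuple(shape), gshape, width, beta)
    scale = np.array([g / n for n, g in zip(shape, gshape)])
    grid = _scatter(samples, coords * scale, gshape, width, beta)
    img = _crop_centered(_centered_ifft_adjoint(grid), tuple(shape))
    return img / apod


def _direct(x: np.ndarray, coords: np.ndarray, adjoint: bool, shape: tuple[int, ...] | None = None):
    """Exact DFT sum; O(P * N) memory-chunked, for oracle-scale problems."""
    if adjoint:
        assert shape is not None
        nd = len(shape)
        grids = np.meshgrid(*[(np.arange(n) - n // 2) / n for n in shape], indexing="ij")
        out = np.zeros(shape, dtype=np.complex128)
        chunk = max(1, int(2e7 // max(np.prod(shape), 1)))
        for lo in range(0, coords.shape[0], chunk):
            c = coords[lo : lo + chunk]
            phase = np.zeros((c.shape[0],) + shape)
            for d in range(nd):
                phase = phase + c[:, d].reshape((-1,) + (1,) * nd) * grids[d]
            out += np.tensordot(x[lo : lo + chunk], np.exp(2j * np.pi * phase), axes=(0, 0))
        return out
    nd = x.ndim
    shape = x.shape
    grids = np.meshgrid(*[(np.arange(n) - n // 2) / n for n in shape], indexing="ij")
    out = np.zeros(coords.shape[0], dtype=np.complex128)
    chunk = max(1, int(2e7 // max(np.prod(shape), 1)))
    for lo in range(0, coords.shape[0], chunk):
        c = coords[lo : lo + chunk]
        phase = np.zeros((c.shape[0],) + shape)
        for d in range(nd):
            phase = phase + c[:, d].reshape((-1,) + (1,) * nd) * grids[d]
        out[lo : lo + chunk] = np.exp(-2j * np.pi * phase).reshape(c.shape[0], -1) @ x.ravel()
    return out


def kernel_convolve_at_samples(
    weights: np.ndarray,
    coords: np.ndarray,
    grid_shape: tuple[int, ...],
    os: float = DEFAULT_OVERSAMPLING,
    width: int = DEFAULT_WIDTH,
) -> np.ndarray:
    """Scatter sample weights onto the oversampled grid and re-read them.

    This is the grid-then-regrid operation (G G^H acting on sample weights)
    used by the iterative density-compensation fixed point; no FFT is needed
    because scatter followed by gather equals convolution with the gridding
    kernel evaluated at the sample locations.
    """
    gshape = _os_grid_shape(tuple(grid_shape), os)
    beta = _beatty_beta(width, os)
    scale = np.array([g / n for n, g in zip(grid_shape, gshape)])
    sc = np.asarray(coords, dtype=float) * scale
    grid = _scatter(weights.astype(np.complex128), sc, gshape, width, beta)
    return np.abs(_gather(grid, sc, width, beta))
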