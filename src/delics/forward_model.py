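"""The subspace acquisition operator A = F S Phi and its adjoint.

A maps K subspace coefficient volumes to multi-coil non-Cartesian k-space
time series.  It is evaluated as a grid of (k, c) sub-models

    A_(k,c) = Phi_k  F  S_c

where S_c multiplies by the c-th coil sensitivity map, F is the NUFFT onto
all TR sample locations, and Phi_k scales each TR's samples by the basis
weight phi[t, k].  The sub-models are evaluated one batch at a time so the
peak transient working set stays bounded regardless of problem size, and the
outputs are summed over k (columns) before stacking over coils (rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mrf_signal import SubspaceBasis
from .nufft import DEFAULT_OVERSAMPLING, DEFAULT_WIDTH, nufft_adjoint, nufft_forward
from .sampling import DensityWeights, Trajectory

__all__ = [
    "CoilMaps",
    "CoefficientImage",
    "KSpaceData",
    "AcquisitionModel",
    "apply_forward",
    "apply_adjoint",
    "estimate_lipschitz",
]


@dataclass(frozen=True)
class CoilMaps:
    """Complex coil sensitivities, (n_coils, Nz, Ny, Nx)."""

    maps: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.maps, dtype=np.complex128)
        if m.ndim != 4 or m.shape[0] < 1:
            raise ValueError("maps must be (n_coils, Nz, Ny, Nx)")
        if not np.all(np.isfinite(m)):
            raise ValueError("coil maps must be finite")
        object.__setattr__(self, "maps", m)

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def vol_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]


@dataclass
class CoefficientImage:
    """The reconstruction unknown: (K, Nz, Ny, Nx) complex volume."""

    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, dtype=np.complex128)
        if d.ndim != 4:
            raise ValueError("data must be (K, Nz, Ny, Nx)")
        self.data = d

    @property
    def K(self) -> int:
        return self.data.shape[0]

    @property
    def vol_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class KSpaceData:
    """Acquired samples (n_coils, n_tr, n_samples_per_tr) with their trajectory."""

    samples: np.ndarray
    traj: Trajectory
    dcf: DensityWeights | None = None

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=np.complex128)
        if s.ndim != 3:
            raise ValueError("samples must be (n_coils, n_tr, n_samples_per_tr)")
        if s.shape[1:] != (self.traj.n_tr, self.traj.n_samples_per_tr):
            raise ValueError("samples inconsistent with trajectory shape")
        if self.dcf is not None and self.dcf.w.shape != s.shape[1:]:
            raise ValueError("dcf inconsistent with samples")
        self.samples = s

    @property
    def n_coils(self) -> int:
        return self.samples.shape[0]

    def subset_tr(self, mask: np.ndarray, new_traj: Trajectory) -> "KSpaceData":
        dcf = None if self.dcf is None else DensityWeights(self.dcf.w[mask])
        return KSpaceData(samples=self.samples[:, mask], traj=new_traj, dcf=dcf)


@dataclass
class AcquisitionModel:
    """A = F S Phi with its (k, c) sub-model decomposition.

    ``batch_spec`` bounds how many sub-model k-space intermediates are
    resident at once; ``engine`` selects the NUFFT implementation
    ("gridding" or the exact "direct" sum for small oracle problems).
    """

    basis: SubspaceBasis
    coil_maps: CoilMaps
    traj: Trajectory
    batch_spec: int = 1
    engine: str = "gridding"
    os: float = DEFAULT_OVERSAMPLING
    width: int = DEFAULT_WIDTH
    intermediate_hook: object = None  # callable(delta:int) for memory-contract tests

    def __post_init__(self):
        if int(np.max(self.traj.tr_index)) >= self.basis.n_tr:
            raise ValueError("trajectory TR indices exceed the basis length")
        if self.batch_spec < 1:
            raise ValueError("batch_spec must be >= 1")

    @property
    def K(self) -> int:
        return self.basis.K

    @property
    def n_coils(self) -> int:
        return self.coil_maps.n_coils

    @property
    def vol_shape(self) -> tuple[int, int, int]:
        return self.coil_maps.vol_shape

    @property
    def phi_rows(self) -> np.ndarray:
        """Basis rows aligned with the trajectory's TR axis, (n_tr, K)."""
        return self.basis.phi[self.traj.tr_index]

    def _note(self, delta: int):
        if self.intermediate_hook is not None:
            self.intermediate_hook(delta)


def _check_x(model: AcquisitionModel, x: CoefficientImage | np.ndarray) -> np.ndarray:
    data = x.data if isinstance(x, CoefficientImage) else np.asarray(x, dtype=np.complex128)
    if data.shape != (model.K,) + model.vol_shape:
        raise ValueError("coefficient image shape mismatch")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite coefficient image")
    return data


def apply_forward(model: AcquisitionModel, x: CoefficientImage | np.ndarray) -> KSpaceData:
    """b = A x: per (k, c), NUFFT(S_c * x_k) scaled by phi[t, k], summed over k."""
    data = _check_x(model, x)
    traj = model.traj
    coords = traj.flat_coords()
    phi = model.phi_rows  # (n_tr, K)
    out = np.zeros((model.n_coils, traj.n_tr, traj.n_samples_per_tr), dtype=np.complex128)
    for c in range(model.n_coils):
        for k in range(model.K):
            model._note(+1)
            y = nufft_forward(
                model.coil_maps.maps[c] * data[k], coords, engine=model.engine, os=model.os, width=model.width
            ).reshape(traj.n_tr, traj.n_samples_per_tr)
            out[c] += phi[:, k][:, None] * y
            del y
            model._note(-1)
    return KSpaceData(samples=out, traj=traj)


def apply_adjoint(
    model: AcquisitionModel,
    b: KSpaceData | np.ndarray,
    weights: DensityWeights | np.ndarray | None = None,
) -> CoefficientImage:
    """x_k = sum_c conj(S_c) * NUFFT^H(conj(phi[t, k]) * w * b_c).

    With ``weights`` set to the density compensation array this is the
    gridding initializer A^H D b; with weights absent it is the plain
    adjoint A^H b.
    """
    samples = b.samples if isinstance(b, KSpaceData) else np.asarray(b, dtype=np.complex128)
    traj = model.traj
    if samples.shape != (model.n_coils, traj.n_tr, traj.n_samples_per_tr):
        raise ValueError("k-space data shape mismatch")
    if not np.all(np.isfinite(samples)):
        raise ValueError("non-finite k-space input")
    w = None
    if weights is not None:
        w = weights.w if isinstance(weights, DensityWeights) else np.asarray(weights, dtype=float)
    coords = traj.flat_coords()
    phi = model.phi_rows
    out = np.zeros((model.K,) + model.vol_shape, dtype=np.complex128)
    for c in range(model.n_coils):
        bc = samples[c] if w is None else samples[c] * w
        for k in range(model.K):
            model._note(+1)
            y = (np.conj(phi[:, k])[:, None] * bc).ravel()
            out[k] += np.conj(model.coil_maps.maps[c]) * nufft_adjoint(
                y, coords, model.vol_shape, engine=model.engine, os=model.os, width=model.width
            )
            del y
            model._note(-1)
    return CoefficientImage(data=out)


def estimate_lipschitz(
    model: AcquisitionModel,
    weights: DensityWeights | np.ndarray | None = None,
    n_iter: int = 20,
    seed: int = 0,
) -> float:
    """Dominant eigenvalue of x -> A^H D A x by power iteration (deterministic given seed)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (model.K,) + model.vol_shape
    x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    x /= np.linalg.norm(x)
    lam = 0.0
    for _ in range(n_iter):
        b = apply_forward(model, x)
        y = apply_adjoint(model, b, weights).data
        lam = float(np.real(np.vdot(x, y)))
        nrm = np.linalg.norm(y)
        if nrm == 0:
            return 0.0
        x = y / nrm
    return lam
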