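"""3D center-out spiral k-space sampling and density compensation.

The trajectory emulates a tiny-golden-angle-shuffled spiral projection
acquisition: a single variable-density center-out spiral arm is rotated
per TR.  TRs are assigned round-robin to ``n_groups`` readout-train groups;
within a group consecutive TRs advance by a tiny-golden-angle rotation about
the arm normal, and each group's arm plane is tilted to a direction drawn
from a spiral-phyllotaxis covering of the sphere.  Retrospective
acceleration keeps a subset of groups (48 groups fully sample k-space;
keeping 16 gives R = 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nufft import DEFAULT_OVERSAMPLING, DEFAULT_WIDTH, kernel_convolve_at_samples

__all__ = [
    "Trajectory",
    "DensityWeights",
    "SpiralParams",
    "make_tgas_spiral",
    "subsample_groups",
    "pipe_menon_dcf",
]

_GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0
#: 7th tiny golden angle, pi / (golden_ratio + 6) ~ 23.628 degrees
TINY_GOLDEN_ANGLE_7 = np.pi / (_GOLDEN_RATIO + 6.0)
#: azimuthal increment of the spherical phyllotaxis group pattern
PHYLLOTAXIS_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SpiralParams:
    """Geometry of the base spiral arm and the rotation schedule."""

    n_turns: float = 8.0
    density_power: float = 1.5  # radial law r(s) = kmax * s**p
    kmax_fraction: float = 0.999  # arm endpoint as a fraction of N/2
    in_group_angle_rad: float = TINY_GOLDEN_ANGLE_7
    group_angle_rad: float = PHYLLOTAXIS_ANGLE


@dataclass(frozen=True)
class Trajectory:
    """Per-TR k-space sample coordinates.

    ``coords`` is (n_tr, n_samples_per_tr, 3) in cycles/FOV scaled to matrix
    index units (each axis within (-N/2, N/2)); ``group_index`` assigns every
    TR to a readout-train group; ``tr_index`` records each row's position in
    the original flip-angle train so that a subsampled trajectory still
    addresses the correct rows of the temporal basis.
    """

    coords: np.ndarray
    group_index: np.ndarray
    n_groups: int
    matrix_size: int
    tr_index: np.ndarray | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must be (n_tr, n_samples_per_tr, 3)")
        gi = np.asarray(self.group_index, dtype=np.int64)
        if gi.shape != (coords.shape[0],):
            raise ValueError("group_index must have one entry per TR")
        if gi.min() < 0 or gi.max() >= self.n_groups:
            raise ValueError("group_index out of [0, n_groups)")
        if coords.min() < -self.matrix_size / 2 or coords.max() >= self.matrix_size / 2:
            raise ValueError("trajectory exceeds the Nyquist box [-N/2, N/2)")
        ti = self.tr_index
        ti = np.arange(coords.shape[0]) if ti is None else np.asarray(ti, dtype=np.int64)
        if ti.shape != (coords.shape[0],):
            raise ValueError("tr_index must have one entry per TR")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "group_index", gi)
        object.__setattr__(self, "tr_index", ti)

    @property
    def n_tr(self) -> int:
        return self.coords.shape[0]

    @property
    def n_samples_per_tr(self) -> int:
        return self.coords.shape[1]

    def flat_coords(self) -> np.ndarray:
        return self.coords.reshape(-1, 3)


@dataclass(frozen=True)
class DensityWeights:
    """Strictly positive per-sample density compensation weights (n_tr, M)."""

    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2:
            raise ValueError("w must be (n_tr, n_samples_per_tr)")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("density weights must be finite and positive")
        object.__setattr__(self, "w", w)


def _rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rotation_to_axis(u: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the z unit vector onto unit vector ``u`` (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, u))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, u)
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(np.arccos(c)) * K + (1 - c) * (K @ K)


def group_rotation(g: int, n_groups: int, params: SpiralParams) -> np.ndarray:
    """Orientation of group ``g``: phyllotaxis tilt composed with an azimuthal spin."""
    zc = 1.0 - 2.0 * (g + 0.5) / n_groups
    az = g * params.group_angle_rad
    r = np.sqrt(max(0.0, 1.0 - zc * zc))
    u = np.array([r * np.cos(az), r * np.sin(az), zc])
    return _rotation_to_axis(u) @ _rotation_z(az)


def base_arm(matrix_size: int, n_samples: int, params: SpiralParams) -> np.ndarray:
    """Variable-density center-out spiral arm in the kx-ky plane, (M, 3)."""
    if n_samples < 2:
        raise ValueError("n_samples_per_tr must be at least 2")
    kmax = params.kmax_fraction * matrix_size / 2.0
    if kmax >= matrix_size / 2.0:
        raise ValueError("kmax must stay strictly inside N/2")
    s = np.linspace(0.0, 1.0, n_samples)
    r = kmax * s**params.density_power
    theta = 2.0 * np.pi * params.n_turns * s
    return np.stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(r)], axis=1)


def make_tgas_spiral(
    matrix_size: int,
    n_tr: int,
    n_samples_per_tr: int,
    n_groups: int = 48,
    params: SpiralParams | None = None,
) -> Trajectory:
    """Deterministic tiny-golden-angle-shuffled spiral-projection trajectory.

    TR ``t`` belongs to group ``t % n_groups``; its arm is the base spiral
    rotated about z by (occurrence index within the group) times the tiny
    golden angle, then tilted by the group's phyllotaxis rotation.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    params = params or SpiralParams()
    arm = base_arm(matrix_size, n_samples_per_tr, params)
    coords = np.empty((n_tr, n_samples_per_tr, 3))
    group_index = np.arange(n_tr) % n_groups
    for t in range(n_tr):
        g = int(group_index[t])
        j = t // n_groups  # occurrence of this group so far
        rot = group_rotation(g, n_groups, params) @ _rotation_z(j * params.in_group_angle_rad)
        coords[t] = arm @ rot.T
    return Trajectory(coords=coords, group_index=group_index, n_groups=n_groups, matrix_size=matrix_size)


def make_cartesian_planes(matrix_size: int, n_tr: int) -> Trajectory:
    """Fully-sampled oracle trajectory: each TR reads one complete kz-plane.

    Planes cycle through all matrix_size kz values, so with n_tr >= K *
    matrix_size every k-space cell is measured under at least K different
    temporal basis rows and the lambda = 0 inverse problem is well posed.
    Intended for inverse-crime recovery experiments, not as an emulation of
    the spiral protocol.
    """
    n = matrix_size
    ax = np.arange(n) - n // 2
    ky, kx = np.meshgrid(ax, ax, indexing="ij")
    plane = np.stack([np.zeros(n * n), ky.ravel(), kx.ravel()], axis=1)
    coords = np.empty((n_tr, n * n, 3))
    for t in range(n_tr):
        kz = ax[t % n]
        coords[t] = plane + np.array([kz, 0.0, 0.0])
    # clip the +N/2-less convention: ax already spans [-N/2, N/2)
    return Trajectory(
        coords=coords,
        group_index=np.arange(n_tr) % n,
        n_groups=n,
        matrix_size=matrix_size,
    )


def subsample_groups(traj: Trajectory, data=None, keep: int = 16):
    """Retain every ceil(n_groups/keep)-th readout-train group.

    Pure selection along the TR axis: retained samples are bit-identical.
    ``data`` may be a KSpaceData (its samples/dcf are subset consistently) or
    None.  Returns ``(trajectory, data)``; the acceleration factor is
    ``traj.n_groups / keep``.
    """
    if keep <= 0:
        raise ValueError("keep must be positive")
    if keep > traj.n_groups:
        raise ValueError("keep exceeds the number of groups")
    step = int(np.ceil(traj.n_groups / keep))
    kept_groups = np.arange(traj.n_groups)[::step][:keep]
    mask = np.isin(traj.group_index, kept_groups)
    remap = -np.ones(traj.n_groups, dtype=np.int64)
    remap[kept_groups] = np.arange(kept_groups.size)
    new_traj = Trajectory(
        coords=traj.coords[mask],
        group_index=remap[traj.group_index[mask]],
        n_groups=int(kept_groups.size),
        matrix_size=traj.matrix_size,
        tr_index=traj.tr_index[mask],
    )
    if data is None:
        return new_traj, None
    new_data = data.subset_tr(mask, new_traj)
    return new_traj, new_data


def pipe_menon_dcf(
    traj: Trajectory | np.ndarray,
    grid_shape,
    n_iter: int = 30,
    os: float = 2.0,
    width: int = DEFAULT_WIDTH,
    eps: float = 1e-12,
) -> DensityWeights | np.ndarray:
    """Iterative density compensation: w <- w / (G G^H w), starting from w = 1.

    ``G G^H`` is gridding of the weights onto the oversampled grid followed
    by re-evaluation at the sample points (magnitude taken).  The output is
    strictly positive and scaled so max(w) = 1.  Passing a bare (P, ndim)
    coordinate array returns a bare weight array of length P.
    """
    import warnings

    if isinstance(traj, Trajectory):
        coords = traj.flat_coords()
    else:
        coords = np.asarray(traj, dtype=float)
    w = np.ones(coords.shape[0])
    for _ in range(n_iter):
        den = kernel_convolve_at_samples(w, coords, tuple(grid_shape), os=os, width=width)
        if np.any(den <= eps):
            warnings.warn("density compensation denominator clamped at epsilon")
            den = np.maximum(den, eps)
        w = w / den
    w = w / w.max()
    if isinstance(traj, Trajectory):
        return DensityWeights(w=w.reshape(traj.n_tr, traj.n_samples_per_tr))
    return w
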