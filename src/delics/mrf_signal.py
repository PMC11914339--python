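"""MR fingerprinting signal simulation, subspace basis, and template matching.

This module owns the temporal side of the subspace reconstruction:

* extended-phase-graph (EPG) simulation of an inversion-prepared,
  gradient-spoiled (FISP-type) fingerprinting sequence,
* dictionary construction over a (T1, T2) grid,
* the rank-K temporal basis ``phi`` from the dictionary SVD,
* per-voxel dictionary matching of subspace coefficient images back to
  quantitative T1/T2/PD maps.

All relaxation times are in milliseconds and flip angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SequenceParams",
    "DictionaryGrid",
    "SignalDictionary",
    "SubspaceBasis",
    "TissueMaps",
    "default_flip_schedule",
    "default_sequence",
    "default_grid",
    "simulate_fingerprint",
    "build_dictionary",
    "compute_basis",
    "match_templates",
]


def default_flip_schedule(n_tr: int, lo_deg: float = 10.0, hi_deg: float = 75.0) -> np.ndarray:
    """Half-sine flip-angle ramp from ``lo_deg`` up to ``hi_deg`` over the train.

    The acquisition this package models uses flip angles varying between 10
    and 75 degrees; the exact waveform is sequence-specific, so a smooth
    half-sine ramp is used as the default and any per-TR array may be
    supplied instead.  The subspace basis is built from the same schedule
    used for matching, so the pipeline is consistent for any choice.
    """
    t = np.arange(n_tr)
    return lo_deg + (hi_deg - lo_deg) * np.sin(0.5 * np.pi * t / n_tr)


@dataclass(frozen=True)
class SequenceParams:
    """Timing and RF schedule of the inversion-prepared FISP-MRF train."""

    n_tr: int
    ti_ms: float = 20.0
    te_ms: float = 0.7
    tr_ms: float = 12.0
    flip_deg: np.ndarray | None = None
    inversion_efficiency: float = 1.0

    def __post_init__(self):
        if self.n_tr <= 0:
            raise ValueError("n_tr must be positive")
        flips = self.flip_deg
        if flips is None:
            flips = default_flip_schedule(self.n_tr)
        flips = np.asarray(flips, dtype=float)
        if flips.shape != (self.n_tr,):
            raise ValueError("flip_deg must have length n_tr")
        if np.any(flips < 0) or np.any(flips > 180):
            raise ValueError("flip angles must lie in [0, 180] degrees")
        if not (self.te_ms < self.tr_ms):
            raise ValueError("te_ms must be smaller than tr_ms")
        if not (0 < self.inversion_efficiency <= 1):
            raise ValueError("inversion_efficiency must be in (0, 1]")
        object.__setattr__(self, "flip_deg", flips)


def default_sequence(n_tr: int = 500) -> SequenceParams:
    """Reference protocol: inversion + 500 TRs, TI/TE/TR = 20/0.7/12 ms."""
    return SequenceParams(n_tr=n_tr)


@dataclass(frozen=True)
class DictionaryGrid:
    """Sorted T1/T2 grids whose Cartesian product defines the dictionary."""

    t1_values_ms: np.ndarray
    t2_values_ms: np.ndarray
    enforce_t2_le_t1: bool = True

    def __post_init__(self):
        for name in ("t1_values_ms", "t2_values_ms"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or v.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if np.any(v <= 0):
                raise ValueError(f"{name} must be positive")
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, v)

    def pairs(self) -> np.ndarray:
        """Retained (T1, T2) pairs, shape (n_atoms, 2), T1-major order."""
        t1, t2 = np.meshgrid(self.t1_values_ms, self.t2_values_ms, indexing="ij")
        p = np.stack([t1.ravel(), t2.ravel()], axis=1)
        if self.enforce_t2_le_t1:
            p = p[p[:, 1] <= p[:, 0]]
        if p.shape[0] == 0:
            raise ValueError("no (T1, T2) pairs retained by the pairing rule")
        return p


def default_grid() -> DictionaryGrid:
    """The reference dictionary grid for brain tissue.

    T1: {20, 40, ..., 3000} ∪ {3200, 3400, ..., 5000} ms.
    T2: {10, 12, ..., 200} ∪ {220, 240, ..., 1000} ∪ {1050, 1100, ..., 2000}
        ∪ {2100, 2200, ..., 4000} ms.
    """
    t1 = np.concatenate([np.arange(20, 3001, 20), np.arange(3200, 5001, 200)])
    t2 = np.concatenate(
        [
            np.arange(10, 201, 2),
            np.arange(220, 1001, 20),
            np.arange(1050, 2001, 50),
            np.arange(2100, 4001, 100),
        ]
    )
    return DictionaryGrid(t1_values_ms=t1.astype(float), t2_values_ms=t2.astype(float))


@dataclass
class SignalDictionary:
    """Simulated fingerprints: ``atoms`` is (n_atoms, n_tr), labels (n_atoms, 2)."""

    atoms: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.atoms = np.asarray(self.atoms, dtype=np.complex128)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.atoms.ndim != 2 or self.labels.shape != (self.atoms.shape[0], 2):
            raise ValueError("atoms (n_atoms, n_tr) and labels (n_atoms, 2) required")
        if np.any(np.all(self.atoms == 0, axis=1)):
            raise ValueError("dictionary contains an all-zero atom")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_tr(self) -> int:
        return self.atoms.shape[1]


@dataclass
class SubspaceBasis:
    """Orthonormal temporal basis ``phi`` (n_tr, K) plus all singular values."""

    phi: np.ndarray
    singular_values: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=np.complex128)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.phi.ndim != 2 or self.phi.shape[1] < 1:
            raise ValueError("phi must be (n_tr, K) with K >= 1")
        gram = self.phi.conj().T @ self.phi
        # loose enough to accept a basis persisted in single precision
        if not np.allclose(gram, np.eye(self.K), atol=1e-5):
            raise ValueError("phi columns are not orthonormal")

    @property
    def n_tr(self) -> int:
        return self.phi.shape[0]

    @property
    def K(self) -> int:
        return self.phi.shape[1]

    def compress(self, signals: np.ndarray) -> np.ndarray:
        """Project time courses (..., n_tr) onto the K-dimensional subspace."""
        return np.asarray(signals) @ self.phi.conj()


@dataclass
class TissueMaps:
    """Voxelwise quantitative maps from dictionary matching."""

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    pd: np.ndarray
    mask: np.ndarray
    degenerate: np.ndarray | None = None  # zero-signal voxels inside the mask


# ---------------------------------------------------------------------------
# EPG simulation
# ---------------------------------------------------------------------------


def _epg_rf_matrix(alpha_rad: np.ndarray) -> np.ndarray:
    """EPG mixing matrices for RF pulses of flip ``alpha`` about a fixed axis.

    Returns an array (n, 3, 3) acting on (F+, F-, Z) configuration states;
    RF phase is held at 0 (FISP convention, no RF spoiling).
    """
    a = np.asarray(alpha_rad, dtype=float)
    c2 = np.cos(a / 2.0) ** 2
    s2 = np.sin(a / 2.0) ** 2
    sa = np.sin(a)
    ca = np.cos(a)
    T = np.zeros(a.shape + (3, 3), dtype=np.complex128)
    T[..., 0, 0] = c2
    T[..., 0, 1] = s2
    T[..., 0, 2] = -1j * sa
    T[..., 1, 0] = s2
    T[..., 1, 1] = c2
    T[..., 1, 2] = 1j * sa
    T[..., 2, 0] = -0.5j * sa
    T[..., 2, 1] = 0.5j * sa
    T[..., 2, 2] = ca
    return T


def _simulate_epg_batch(
    t1_ms: np.ndarray, t2_ms: np.ndarray, seq: SequenceParams, max_states: int | None = None
) -> np.ndarray:
    """EPG fingerprints for a batch of (T1, T2) pairs; returns (n, n_tr) complex.

    Sequence model per TR: RF(alpha_t) -> relax TE and record F0 -> relax
    TR - TE -> one unit of gradient dephasing (state shift).  The train is
    preceded by an adiabatic inversion (Mz -> -eff * Mz) and a TI delay.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float))
    if t1.shape != t2.shape:
        raise ValueError("t1_ms and t2_ms must have matching shapes")
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("relaxation times must be positive")
    n = t1.size
    n_tr = seq.n_tr
    n_states = max_states or min(n_tr + 1, 100)

    flips = np.deg2rad(seq.flip_deg)
    if flips.size == 0:
        raise ValueError("empty flip schedule")
    T_rf = _epg_rf_matrix(flips)  # (n_tr, 3, 3)

    e1_te = np.exp(-seq.te_ms / t1)
    e2_te = np.exp(-seq.te_ms / t2)
    tau = seq.tr_ms - seq.te_ms
    e1_tr = np.exp(-tau / t1)
    e2_tr = np.exp(-tau / t2)

    Fp = np.zeros((n_states, n), dtype=np.complex128)
    Fm = np.zeros((n_states, n), dtype=np.complex128)
    Z = np.zeros((n_states, n), dtype=np.complex128)

    # inversion and TI delay
    Z[0] = -seq.inversion_efficiency
    e1_ti = np.exp(-seq.ti_ms / t1)
    Z[0] = Z[0] * e1_ti + (1.0 - e1_ti)

    out = np.zeros((n, n_tr), dtype=np.complex128)
    for t in range(n_tr):
        M = T_rf[t]
        Fp, Fm, Z = (
            M[0, 0] * Fp + M[0, 1] * Fm + M[0, 2] * Z,
            M[1, 0] * Fp + M[1, 1] * Fm + M[1, 2] * Z,
            M[2, 0] * Fp + M[2, 1] * Fm + M[2, 2] * Z,
        )
        # relax to TE, record the acquired F0 state
        out[:, t] = Fp[0] * e2_te
        Fp = Fp * e2_te
        Fm = Fm * e2_te
        Z = Z * e1_te
        Z[0] += 1.0 - e1_te
        # relax over the remainder of the TR
        Fp = Fp * e2_tr
        Fm = Fm * e2_tr
        Z = Z * e1_tr
        Z[0] += 1.0 - e1_tr
        # unit gradient dephasing: shift transverse configuration orders
        Fp[1:] = Fp[:-1]
        Fp[0] = np.conj(Fm[1])
        Fm[:-1] = Fm[1:]
        Fm[-1] = 0.0
    return out


def simulate_fingerprint(t1_ms: float, t2_ms: float, seq: SequenceParams) -> np.ndarray:
    """Transverse signal at TE for each TR of the inversion-prepared FISP train."""
    return _simulate_epg_batch(np.array([t1_ms]), np.array([t2_ms]), seq)[0]


def build_dictionary(grid: DictionaryGrid, seq: SequenceParams, chunk: int = 4096) -> SignalDictionary:
    """Simulate one fingerprint per retained (T1, T2) grid pair.

    Atoms are stored unnormalized; matching normalizes internally.
    """
    pairs = grid.pairs()
    atoms = np.empty((pairs.shape[0], seq.n_tr), dtype=np.complex128)
    for lo in range(0, pairs.shape[0], chunk):
        hi = min(lo + chunk, pairs.shape[0])
        atoms[lo:hi] = _simulate_epg_batch(pairs[lo:hi, 0], pairs[lo:hi, 1], seq)
    return SignalDictionary(atoms=atoms, labels=pairs)


def compute_basis(dictionary: SignalDictionary, K: int = 5) -> SubspaceBasis:
    """Rank-K temporal basis: first K left singular vectors of the (n_tr, n_atoms) matrix."""
    n_tr, n_atoms = dictionary.n_tr, dictionary.n_atoms
    if not (1 <= K <= min(n_tr, n_atoms)):
        raise ValueError(f"K must be in [1, {min(n_tr, n_atoms)}]")
    u, s, _ = np.linalg.svd(dictionary.atoms.T, full_matrices=False)
    return SubspaceBasis(phi=u[:, :K], singular_values=s)


def match_templates(
    coeffs: np.ndarray,
    dictionary: SignalDictionary,
    basis: SubspaceBasis,
    mask: np.ndarray | None = None,
    chunk: int = 16384,
) -> TissueMaps:
    """Per-voxel dictionary matching of subspace coefficient images.

    ``coeffs`` is (K, Nz, Ny, Nx).  For each voxel coefficient vector c the
    atom maximizing |<c, d_hat>| over the l2-normalized compressed atoms
    d_hat = phi^H a is selected (ties go to the lowest atom index); PD is the
    complex projection onto the winning normalized atom.  Zero-signal voxels
    inside the mask get (T1, T2, PD) = (0, 0, 0) and are flagged.
    """
    coeffs = np.asarray(coeffs)
    if coeffs.ndim != 4 or coeffs.shape[0] != basis.K:
        raise ValueError("coeffs must be (K, Nz, Ny, Nx) with K matching the basis")
    vol_shape = coeffs.shape[1:]
    if mask is None:
        mask = np.ones(vol_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    d_hat = basis.compress(dictionary.atoms)  # (n_atoms, K)
    norms = np.linalg.norm(d_hat, axis=1)
    d_hat = d_hat / norms[:, None]

    flat = coeffs.reshape(basis.K, -1)
    sel = np.flatnonzero(mask.ravel())
    t1 = np.zeros(flat.shape[1])
    t2 = np.zeros(flat.shape[1])
    pd = np.zeros(flat.shape[1], dtype=np.complex128)
    degen = np.zeros(flat.shape[1], dtype=bool)

    for lo in range(0, sel.size, chunk):
        idx = sel[lo : lo + chunk]
        c = flat[:, idx]  # (K, m)
        proj = d_hat.conj() @ c  # (n_atoms, m)
        best = np.argmax(np.abs(proj), axis=0)
        zero = np.all(c == 0, axis=0)
        t1[idx] = np.where(zero, 0.0, dictionary.labels[best, 0])
        t2[idx] = np.where(zero, 0.0, dictionary.labels[best, 1])
        pd[idx] = np.where(zero, 0.0, proj[best, np.arange(best.size)])
        degen[idx] = zero

    return TissueMaps(
        t1_ms=t1.reshape(vol_shape),
        t2_ms=t2.reshape(vol_shape),
        pd=pd.reshape(vol_shape),
        mask=mask,
        degenerate=degen.reshape(vol_shape),
    )
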