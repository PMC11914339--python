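"""Independent reference implementations used only by the tests.

Everything here is deliberately brute force: isochromat Bloch simulation
with explicit rotation matrices, dense acquisition matrices assembled from
the defining exponential sums, and direct per-block SVD soft-thresholding.
"""

from __future__ import annotations

import numpy as np


def isochromat_fingerprint(t1_ms: float, t2_ms: float, seq, n_spins: int = 2000) -> np.ndarray:
    """Brute-force Bloch simulation of the inversion-prepared FISP train.

    ``n_spins`` isochromats with uniformly spaced intra-voxel dephasing
    angles; each TR applies RF about x (right-handed), relaxation to TE
    (signal recorded as Mx + i My averaged over spins), relaxation over the
    rest of the TR, then one unit of gradient dephasing.
    """
    theta = 2 * np.pi * np.arange(n_spins) / n_spins
    M = np.zeros((n_spins, 3))
    M[:, 2] = -seq.inversion_efficiency

    def relax(M, dt):
        e1, e2 = np.exp(-dt / t1_ms), np.exp(-dt / t2_ms)
        M[:, :2] *= e2
        M[:, 2] = M[:, 2] * e1 + (1 - e1)
        return M

    M = relax(M, seq.ti_ms)
    out = np.zeros(seq.n_tr, complex)
    for t in range(seq.n_tr):
        a = np.deg2rad(seq.flip_deg[t])
        Rx = np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])
        M = M @ Rx.T
        M = relax(M, seq.te_ms)
        out[t] = np.mean(M[:, 0] + 1j * M[:, 1])
        M = relax(M, seq.tr_ms - seq.te_ms)
        c, s = np.cos(theta), np.sin(theta)
        x, y = M[:, 0].copy(), M[:, 1].copy()
        M[:, 0] = c * x - s * y
        M[:, 1] = s * x + c * y
    return out


def dense_acquisition_matrix(phi: np.ndarray, maps: np.ndarray, coords: np.ndarray, matrix_size: int) -> np.ndarray:
    """Monolithic A as an explicit (C*T*M, K*N^3) matrix from first principles.

    Row (c, t, m) holds phi[t, k] * exp(-2 pi i k_{t,m} . (n - N//2)/N) * S_c[n]
    at column (k, n).
    """
    C = maps.shape[0]
    T, M, _ = coords.shape
    K = phi.shape[1]
    N = matrix_size
    n_idx = np.stack(np.meshgrid(*[np.arange(N)] * 3, indexing="ij"), axis=-1).reshape(-1, 3)
    F = np.exp(-2j * np.pi * (coords.reshape(-1, 3) @ ((n_idx - N // 2) / N).T))  # (T*M, N^3)
    A = np.zeros((C * T * M, K * N**3), dtype=complex)
    for c in range(C):
        for k in range(K):
            phi_rows = np.repeat(phi[:, k], M)[:, None]
            A[c * T * M : (c + 1) * T * M, k * N**3 : (k + 1) * N**3] = phi_rows * F * maps[c].ravel()[None, :]
    return A


def svt(matrix: np.ndarray, threshold: float) -> np.ndarray:
    """Direct singular-value soft-thresholding of one matrix."""
    u, s, vh = np.linalg.svd(matrix, full_matrices=False)
    return (u * np.maximum(s - threshold, 0.0)[None, :]) @ vh


def blockwise_svt(vol: np.ndarray, block_size: int, threshold: float) -> np.ndarray:
    """Loop-based block SVT over a (K, Z, Y, X) volume (shift 0, exact multiples)."""
    K = vol.shape[0]
    out = np.zeros_like(vol)
    B = block_size
    for z in range(0, vol.shape[1], B):
        for y in range(0, vol.shape[2], B):
            for x in range(0, vol.shape[3], B):
                blk = vol[:, z : z + B, y : y + B, x : x + B]
                mat = blk.reshape(K, -1).T
                out[:, z : z + B, y : y + B, x : x + B] = svt(mat, threshold).T.reshape(blk.shape)
    return out
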