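"""Single-file HDF5 interchange container and NIfTI map export.

Layout (datasets are created lazily; a file may hold any subset):

    /kspace/samples        complex64  (C, T, M)
    /trajectory/coords     float32    (T, M, 3)
    /trajectory/group_index int32     (T,)
    /trajectory/tr_index   int32      (T,)
    /dcf/w                 float32    (T, M)
    /seq/flip_deg          float32    (T,)
    /dictionary/atoms      complex64  (n_atoms, T)
    /dictionary/t1_ms, /dictionary/t2_ms
    /basis/phi             complex64  (T, K)
    /basis/singular_values
    /calib/image           complex64  (C, Z, Y, X)
    /coils/maps            complex64  (C, Z, Y, X)
    /prep/compression      complex64  (n_out, n_in)
    /recon/coeffs          complex64  (K, Z, Y, X)
    /truth/...             ground-truth volumes

Root attributes: matrix_size, fov_mm, ti_ms, te_ms, tr_ms, n_groups.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .forward_model import CoefficientImage, CoilMaps, KSpaceData
from .mrf_signal import SequenceParams, SignalDictionary, SubspaceBasis, TissueMaps
from .sampling import DensityWeights, Trajectory

__all__ = [
    "save_sequence", "load_sequence",
    "save_trajectory", "load_trajectory",
    "save_dcf", "load_dcf",
    "save_kspace", "load_kspace",
    "save_dictionary", "load_dictionary",
    "save_basis", "load_basis",
    "save_coeffs", "load_coeffs",
    "save_coil_maps", "load_coil_maps",
    "write_tissue_maps", "write_nifti",
]


def _require(f: h5py.File, name: str):
    if name not in f:
        raise KeyError(f"container is missing {name}")
    return f[name]


def save_sequence(path, seq: SequenceParams, matrix_size: int | None = None, fov_mm: float | None = None):
    with h5py.File(path, "a") as f:
        if "seq/flip_deg" in f:
            del f["seq/flip_deg"]
        f.create_dataset("seq/flip_deg", data=seq.flip_deg.astype(np.float32))
        f.attrs["ti_ms"] = seq.ti_ms
        f.attrs["te_ms"] = seq.te_ms
        f.attrs["tr_ms"] = seq.tr_ms
        f.attrs["inversion_efficiency"] = seq.inversion_efficiency
        if matrix_size is not None:
            f.attrs["matrix_size"] = matrix_size
        if fov_mm is not None:
            f.attrs["fov_mm"] = fov_mm


def load_sequence(path) -> SequenceParams:
    with h5py.File(path, "r") as f:
        flips = _require(f, "seq/flip_deg")[()]
        return SequenceParams(
            n_tr=len(flips),
            ti_ms=float(f.attrs["ti_ms"]),
            te_ms=float(f.attrs["te_ms"]),
            tr_ms=float(f.attrs["tr_ms"]),
            flip_deg=flips.astype(float),
            inversion_efficiency=float(f.attrs.get("inversion_efficiency", 1.0)),
        )


def _replace(f: h5py.File, name: str, data, dtype=None):
    if name in f:
        del f[name]
    f.create_dataset(name, data=data if dtype is None else np.asarray(data).astype(dtype))


def save_trajectory(path, traj: Trajectory):
    with h5py.File(path, "a") as f:
        _replace(f, "trajectory/coords", traj.coords, np.float32)
        _replace(f, "trajectory/group_index", traj.group_index, np.int32)
        _replace(f, "trajectory/tr_index", traj.tr_index, np.int32)
        f.attrs["matrix_size"] = traj.matrix_size
        f.attrs["n_groups"] = traj.n_groups


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as f:
        return Trajectory(
            coords=_require(f, "trajectory/coords")[()].astype(float),
            group_index=_require(f, "trajectory/group_index")[()],
            n_groups=int(f.attrs["n_groups"]),
            matrix_size=int(f.attrs["matrix_size"]),
            tr_index=_require(f, "trajectory/tr_index")[()],
        )


def save_dcf(path, dcf: DensityWeights):
    with h5py.File(path, "a") as f:
        _replace(f, "dcf/w", dcf.w, np.float32)


def load_dcf(path) -> DensityWeights:
    with h5py.File(path, "r") as f:
        return DensityWeights(w=_require(f, "dcf/w")[()].astype(float))


def save_kspace(path, data: KSpaceData):
    save_trajectory(path, data.traj)
    with h5py.File(path, "a") as f:
        _replace(f, "kspace/samples", data.samples, np.complex64)
    if data.dcf is not None:
        save_dcf(path, data.dcf)


def load_kspace(path) -> KSpaceData:
    traj = load_trajectory(path)
    with h5py.File(path, "r") as f:
        samples = _require(f, "kspace/samples")[()].astype(np.complex128)
        dcf = DensityWeights(w=f["dcf/w"][()].astype(float)) if "dcf/w" in f else None
    return KSpaceData(samples=samples, traj=traj, dcf=dcf)


def save_dictionary(path, d: SignalDictionary):
    with h5py.File(path, "a") as f:
        _replace(f, "dictionary/atoms", d.atoms, np.complex64)
        _replace(f, "dictionary/t1_ms", d.labels[:, 0], np.float32)
        _replace(f, "dictionary/t2_ms", d.labels[:, 1], np.float32)


def load_dictionary(path) -> SignalDictionary:
    with h5py.File(path, "r") as f:
        atoms = _require(f, "dictionary/atoms")[()].astype(np.complex128)
        labels = np.stack([f["dictionary/t1_ms"][()], f["dictionary/t2_ms"][()]], axis=1)
    return SignalDictionary(atoms=atoms, labels=labels.astype(float))


def save_basis(path, b: SubspaceBasis):
    with h5py.File(path, "a") as f:
        _replace(f, "basis/phi", b.phi, np.complex64)
        _replace(f, "basis/singular_values", b.singular_values, np.float32)


def load_basis(path) -> SubspaceBasis:
    with h5py.File(path, "r") as f:
        return SubspaceBasis(
            phi=_require(f, "basis/phi")[()].astype(np.complex128),
            singular_values=f["basis/singular_values"][()].astype(float),
        )


def save_coeffs(path, x: CoefficientImage, group: str = "recon/coeffs"):
    with h5py.File(path, "a") as f:
        _replace(f, group, x.data, np.complex64)


def load_coeffs(path, group: str = "recon/coeffs") -> CoefficientImage:
    with h5py.File(path, "r") as f:
        return CoefficientImage(data=_require(f, group)[()].astype(np.complex128))


def save_coil_maps(path, maps: CoilMaps):
    with h5py.File(path, "a") as f:
        _replace(f, "coils/maps", maps.maps, np.complex64)


def load_coil_maps(path) -> CoilMaps:
    with h5py.File(path, "r") as f:
        return CoilMaps(maps=_require(f, "coils/maps")[()].astype(np.complex128))


def write_nifti(path, volume: np.ndarray, voxel_size_mm: float = 1.0):
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def write_coefficient_niftis(outdir, x: CoefficientImage, voxel_size_mm: float = 1.0):
    """One magnitude and one phase NIfTI volume per subspace coefficient."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(x.K):
        for name, vol in (("mag", np.abs(x.data[k])), ("phase", np.angle(x.data[k]))):
            p = outdir / f"coeff{k:02d}_{name}.nii.gz"
            write_nifti(p, vol, voxel_size_mm)
            paths.append(p)
    return paths


def save_blocks(path, samples, group: str = "blocks"):
    """Cache training block pairs: /blocks/input, /blocks/target, /blocks/origin."""
    import json as _json

    with h5py.File(path, "a") as f:
        for name in (f"{group}/input", f"{group}/target", f"{group}/origin"):
            if name in f:
                del f[name]
        f.create_dataset(f"{group}/input", data=np.stack([s.input_block for s in samples]))
        f.create_dataset(f"{group}/target", data=np.stack([s.target_block for s in samples]))
        f.create_dataset(
            f"{group}/origin",
            data=np.array([_json.dumps(s.origin) for s in samples], dtype=h5py.string_dtype()),
        )


def load_blocks(path, group: str = "blocks"):
    import json as _json

    from .deli_net import BlockSample

    with h5py.File(path, "r") as f:
        inputs = _require(f, f"{group}/input")[()]
        targets = f[f"{group}/target"][()]
        origins = [tuple(_json.loads(o)) for o in f[f"{group}/origin"].asstr()[()]]
    return [
        BlockSample(input_block=i, target_block=t, origin=o)
        for i, t, o in zip(inputs, targets, origins)
    ]


def write_tissue_maps(outdir, maps: TissueMaps, voxel_size_mm: float = 1.0):
    """Write t1_ms / t2_ms / pd_abs NIfTI volumes; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in [("t1_ms", maps.t1_ms), ("t2_ms", maps.t2_ms), ("pd_abs", np.abs(maps.pd))]:
        p = outdir / f"{name}.nii.gz"
        write_nifti(p, vol, voxel_size_mm)
        paths[name] = p
    return paths
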