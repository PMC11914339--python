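"""End-to-end reconstruction pipeline: staged, idempotent, file-based.

Stages (each reads its upstream artifacts from the working directory and
writes its own, logging parameters and content hashes):

    phantom     synthesize dictionary, basis, trajectory, k-space, truth
    calib-prep  coil-compression matrix + automatic FOV shift from the calibration scan
    dcf         density-compensation weights for the trajectory
    grid-init   gridding reconstruction A^H D b
    train       train the block denoiser on synthetic phantom pairs
    infer       denoise the gridding init blockwise
    refine      FISTA refinement (warm-started when an inference exists,
                otherwise the adjoint-initialized baseline with a warning)
    match       template-match the refined coefficients to T1/T2/PD maps
    report      RMSE/bias of the maps against ground truth per tissue mask

Two scale profiles are provided: ``desk`` (small matrices, rank 3, runs on
a laptop CPU in minutes — the default everywhere in this package) and
``full`` (the reference scanner-scale settings).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as dio
from .coil_prep import autofov, build_compression
from .deli_net import (
    BlendSpec,
    TrainConfig,
    extract_training_blocks,
    augment_volumes,
    infer_volume,
    normalize_volume,
    train_denoiser,
)
from .forward_model import AcquisitionModel, CoefficientImage, apply_adjoint
from .llr_solver import ReconConfig, fista_llr
from .mrf_signal import (
    DictionaryGrid,
    SequenceParams,
    build_dictionary,
    compute_basis,
    match_templates,
)
from .nn import NetConfig, ResUNet, build_network
from .phantom import PhantomSpec, make_phantom, simulate_acquisition, simulate_calibration
from .sampling import make_tgas_spiral, pipe_menon_dcf, subsample_groups

log = logging.getLogger("delics")

STAGES = ["phantom", "calib-prep", "dcf", "grid-init", "train", "infer", "refine", "match", "report"]

#: profile -> scale parameters (the desk profile is the package's reference
#: testing scale; full mirrors the scanner protocol)
PROFILES = {
    "desk": dict(
        matrix_size=32, n_tr=240, n_samples_per_tr=240, n_groups=48, keep_groups=16,
        K=3, n_coils=2, t1_step=100.0, t2_step=10.0, widths=(8, 16, 32),
        block_size=16, overlap=8, lam=0.2, n_iter=40, llr_block=8,
        lr=1e-3, max_epochs=60, n_train_phantoms=5, dcf_iters=30, noise_sigma=0.05,
    ),
    "full": dict(
        matrix_size=256, n_tr=500, n_samples_per_tr=1024, n_groups=48, keep_groups=16,
        K=5, n_coils=10, t1_step=20.0, t2_step=2.0, widths=(160, 224, 384),
        block_size=64, overlap=16, lam=5e-5, n_iter=40, llr_block=8,
        lr=1e-5, max_epochs=540, n_train_phantoms=10, dcf_iters=30, noise_sigma=0.05,
    ),
}

_SCHEMA = {
    "profile": str,
    "seed": int,
    "output_dir": str,
    **{k: type(v) if not isinstance(v, tuple) else tuple for k, v in PROFILES["desk"].items()},
}


class ConfigError(ValueError):
    pass


def resolve_config(cfg: dict | None = None) -> dict:
    """Validate a config mapping against the schema and fill profile defaults.

    Unknown keys are rejected so typos cannot silently disable a setting.
    """
    cfg = dict(cfg or {})
    profile = cfg.get("profile", "desk")
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}")
    out = dict(PROFILES[profile])
    out.update({"profile": profile, "seed": 0, "output_dir": "delics_out"})
    for key, val in cfg.items():
        if key not in _SCHEMA:
            raise ConfigError(f"unknown configuration key {key!r}")
        want = _SCHEMA[key]
        if want is tuple:
            val = tuple(val)
        elif want is float and isinstance(val, int):
            val = float(val)
        elif not isinstance(val, want):
            raise ConfigError(f"{key} must be of type {want.__name__}")
        out[key] = val
    return out


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class Workspace:
    """Filesystem layout + idempotence bookkeeping for one pipeline run."""

    def __init__(self, cfg: dict):
        self.cfg = resolve_config(cfg)
        self.root = Path(self.cfg["output_dir"])
        self.root.mkdir(parents=True, exist_ok=True)
        self.state_path = self.root / "state.json"
        self.state = json.loads(self.state_path.read_text()) if self.state_path.exists() else {}

    # artifact paths -----------------------------------------------------
    @property
    def bundle(self) -> Path:
        return self.root / "bundle.h5"

    @property
    def net_path(self) -> Path:
        return self.root / "denoiser.npz"

    def _save_state(self):
        self.state_path.write_text(json.dumps(self.state, indent=1))

    def _inputs_of(self, name: str) -> list[Path]:
        deps = {
            "phantom": [],
            "calib-prep": [self.bundle],
            "dcf": [self.bundle],
            "grid-init": [self.bundle],
            "train": [self.bundle],
            "infer": [self.bundle, self.net_path],
            "refine": [self.bundle],
            "match": [self.bundle],
            "report": [self.bundle],
        }
        return deps[name]

    def signature(self, name: str) -> str:
        files = [p for p in self._inputs_of(name) if p.exists()]
        return _hash({"cfg": self.cfg, "stage": name, "files": {str(p): _file_hash(p) for p in files}})


def run_stage(name: str, cfg: dict, force: bool = False) -> Path:
    """Execute one pipeline stage; a stage whose inputs and config are
    unchanged is a no-op (content-hash match)."""
    if name not in STAGES:
        raise ConfigError(f"unknown stage {name!r}; stages are {STAGES}")
    ws = Workspace(cfg)
    for dep in ws._inputs_of(name):
        if not dep.exists():
            producer = "phantom" if dep == ws.bundle else "train"
            raise FileNotFoundError(
                f"stage '{name}' needs {dep.name}, produced by stage '{producer}'; run it first"
            )
    sig = ws.signature(name)
    if not force and ws.state.get(name) == sig:
        log.info("stage %s: inputs unchanged, skipping (hash %s)", name, sig)
        return ws.root
    t0 = time.time()
    _DISPATCH[name](ws)
    log.info("stage %s finished in %.1f s", name, time.time() - t0)
    ws.state[name] = ws.signature(name)
    ws._save_state()
    return ws.root


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _require_dataset(ws: Workspace, name: str, producer: str):
    import h5py

    with h5py.File(ws.bundle, "r") as f:
        if name not in f:
            raise FileNotFoundError(
                f"bundle is missing {name}, produced by stage '{producer}'; run it first"
            )


def _grid(cfg) -> DictionaryGrid:
    t1 = np.arange(cfg["t1_step"], 3000.1, cfg["t1_step"])
    t1 = np.concatenate([t1, np.arange(3200.0, 5000.1, 200.0)])
    t2 = np.arange(cfg["t2_step"], 200.1, cfg["t2_step"])
    t2 = np.concatenate([t2, np.arange(220.0, 1000.1, 20.0), np.arange(1050.0, 2000.1, 50.0), np.arange(2100.0, 4000.1, 100.0)])
    return DictionaryGrid(t1_values_ms=np.unique(t1), t2_values_ms=np.unique(t2))


def _seq(cfg) -> SequenceParams:
    return SequenceParams(n_tr=cfg["n_tr"])


def _stage_phantom(ws: Workspace):
    cfg = ws.cfg
    seq = _seq(cfg)
    dictionary = build_dictionary(_grid(cfg), seq)
    basis = compute_basis(dictionary, K=cfg["K"])
    spec = PhantomSpec(
        matrix_size=cfg["matrix_size"], n_coils=cfg["n_coils"], seed=cfg["seed"],
        noise_sigma=cfg["noise_sigma"],
    )
    gt = make_phantom(spec, basis, seq)
    traj_full = make_tgas_spiral(cfg["matrix_size"], cfg["n_tr"], cfg["n_samples_per_tr"], cfg["n_groups"])
    data_full = simulate_acquisition(gt, traj_full, basis, seed=cfg["seed"])
    traj, data = subsample_groups(traj_full, data_full, keep=cfg["keep_groups"])
    calib = simulate_calibration(gt, outside_fov_source=((0.0, 0.30, 0.0), 2.0))
    p = ws.bundle
    if p.exists():
        p.unlink()
    dio.save_sequence(p, seq, matrix_size=cfg["matrix_size"], fov_mm=220.0)
    dio.save_dictionary(p, dictionary)
    dio.save_basis(p, basis)
    dio.save_kspace(p, data)
    dio.save_coil_maps(p, gt.coil_maps)
    dio.save_coeffs(p, gt.x_true, "truth/x_true")
    import h5py

    with h5py.File(p, "a") as f:
        f.create_dataset("truth/labels", data=gt.labels.astype(np.int16))
        f.create_dataset("truth/t1_ms", data=gt.t1_ms.astype(np.float32))
        f.create_dataset("truth/t2_ms", data=gt.t2_ms.astype(np.float32))
        f.create_dataset("truth/pd", data=gt.pd.astype(np.float32))
        f.create_dataset("calib/image", data=calib.image.astype(np.complex64))
        f.attrs["calib_fov_mm"] = calib.fov_mm[0]
        f.attrs["calib_voxel_mm"] = calib.voxel_size_mm[0]


def _stage_calib_prep(ws: Workspace):
    import h5py

    from .coil_prep import CalibrationImage

    with h5py.File(ws.bundle, "r") as f:
        img = f["calib/image"][()].astype(np.complex128)
        fov = float(f.attrs["calib_fov_mm"])
        vox = float(f.attrs["calib_voxel_mm"])
    cal = CalibrationImage(image=img, voxel_size_mm=(vox,) * 3, fov_mm=(fov,) * 3)
    m = img.shape[1]
    inner = slice(m // 4, 3 * m // 4)
    roi = np.zeros(img.shape[1:], bool)
    roi[inner, inner, inner] = True
    interference = ~roi
    # 1-voxel guard band around the target FOV cube
    guard = np.zeros_like(roi)
    g = slice(m // 4 - 1, 3 * m // 4 + 1)
    guard[g, g, g] = True
    interference = interference & ~guard
    n_coils = img.shape[0]
    n_drop = min(max(n_coils // 6, 1), n_coils - 1)
    n_out = max(1, min(n_coils - n_drop, max(n_coils // 5, 2)))
    comp = build_compression(cal, roi, interference, n_drop=n_drop, n_out=n_out)
    shift = autofov(cal, (fov / 2,) * 3)
    with h5py.File(ws.bundle, "a") as f:
        for k in ("prep/compression", "prep/fov_shift_mm"):
            if k in f:
                del f[k]
        f.create_dataset("prep/compression", data=comp.matrix.astype(np.complex64))
        f["prep/compression"].attrs["rovir_keep"] = comp.stages["rovir_keep"]
        f["prep/compression"].attrs["svd_out"] = comp.stages["svd_out"]
        f.create_dataset("prep/fov_shift_mm", data=shift.shift_mm)


def _stage_dcf(ws: Workspace):
    traj = dio.load_trajectory(ws.bundle)
    n = ws.cfg["matrix_size"]
    dcf = pipe_menon_dcf(traj, (n, n, n), n_iter=ws.cfg["dcf_iters"])
    dio.save_dcf(ws.bundle, dcf)


def _model(ws: Workspace) -> AcquisitionModel:
    basis = dio.load_basis(ws.bundle)
    traj = dio.load_trajectory(ws.bundle)
    maps = dio.load_coil_maps(ws.bundle)
    return AcquisitionModel(basis=basis, coil_maps=maps, traj=traj)


def _stage_grid_init(ws: Workspace):
    _require_dataset(ws, "dcf/w", "dcf")
    data = dio.load_kspace(ws.bundle)
    model = _model(ws)
    x0 = apply_adjoint(model, data, data.dcf)
    dio.save_coeffs(ws.bundle, x0, "recon/init")


def _training_pair(cfg, seed: int):
    """One synthetic (gridding init, converged reconstruction) volume pair."""
    sub = dict(cfg)
    sub["seed"] = seed
    seq = _seq(sub)
    dictionary = build_dictionary(_grid(sub), seq)
    basis = compute_basis(dictionary, K=sub["K"])
    spec = PhantomSpec(matrix_size=sub["matrix_size"], n_coils=sub["n_coils"], seed=seed, noise_sigma=sub["noise_sigma"])
    gt = make_phantom(spec, basis, seq)
    traj_full = make_tgas_spiral(sub["matrix_size"], sub["n_tr"], sub["n_samples_per_tr"], sub["n_groups"])
    data_full = simulate_acquisition(gt, traj_full, basis, seed=seed)
    traj, data = subsample_groups(traj_full, data_full, keep=sub["keep_groups"])
    n = sub["matrix_size"]
    dcf = pipe_menon_dcf(traj, (n, n, n), n_iter=sub["dcf_iters"])
    model = AcquisitionModel(basis=basis, coil_maps=gt.coil_maps, traj=traj)
    x0 = apply_adjoint(model, data, dcf)
    rc = ReconConfig(lam=sub["lam"], n_iter=sub["n_iter"], block_size=sub["llr_block"])
    ref = fista_llr(model, data, dcf, rc, x_init=None)
    return x0.data, ref.x.data


def _stage_train(ws: Workspace):
    cfg = ws.cfg
    rng = np.random.default_rng(cfg["seed"] + 100)
    train_blocks, val_blocks = [], []
    n_ph = max(2, cfg["n_train_phantoms"])
    for i in range(n_ph):
        x0, ref = _training_pair(cfg, seed=cfg["seed"] + 1000 + i)
        x0n, s = normalize_volume(x0)
        refn = ref / s
        dest = val_blocks if i == n_ph - 1 else train_blocks
        if dest is train_blocks:
            x0n, refn = augment_volumes(x0n, refn, rng)
        dest.extend(extract_training_blocks(x0n, refn, cfg["block_size"], volume_id=i))
    dio.save_blocks(ws.root / "blocks.h5", train_blocks, "blocks/train")
    dio.save_blocks(ws.root / "blocks.h5", val_blocks, "blocks/val")
    net, n_par = build_network(NetConfig(in_channels=2 * cfg["K"], widths=tuple(cfg["widths"]), seed=cfg["seed"]))
    log.info("training denoiser with %d parameters on %d/%d blocks", n_par, len(train_blocks), len(val_blocks))
    tcfg = TrainConfig(lr=cfg["lr"], max_epochs=cfg["max_epochs"], seed=cfg["seed"])
    net, curves = train_denoiser(train_blocks, val_blocks, net, tcfg)
    net.save(ws.net_path)
    with open(ws.root / "training_curves.csv", "w") as f:
        f.write("epoch,train_l1,val_l1\n")
        for i, (tr, va) in enumerate(zip(curves["train"], curves["val"])):
            f.write(f"{i},{tr:.6e},{va:.6e}\n")


def _stage_infer(ws: Workspace):
    _require_dataset(ws, "recon/init", "grid-init")
    x0 = dio.load_coeffs(ws.bundle, "recon/init")
    net = ResUNet.load(ws.net_path)
    blend = BlendSpec(block_size=ws.cfg["block_size"], overlap=ws.cfg["overlap"])
    x_deli = infer_volume(x0, net, blend)
    dio.save_coeffs(ws.bundle, x_deli, "recon/deli")


def _stage_refine(ws: Workspace):
    import h5py

    _require_dataset(ws, "dcf/w", "dcf")
    cfg = ws.cfg
    data = dio.load_kspace(ws.bundle)
    model = _model(ws)
    with h5py.File(ws.bundle, "r") as f:
        has_deli = "recon/deli" in f
    if has_deli:
        x_init = dio.load_coeffs(ws.bundle, "recon/deli")
    else:
        log.warning("no denoiser inference found; refining from the adjoint init (baseline mode)")
        x_init = None
    rc = ReconConfig(lam=cfg["lam"], n_iter=cfg["n_iter"], block_size=cfg["llr_block"])
    state = fista_llr(model, data, data.dcf, rc, x_init=x_init)
    dio.save_coeffs(ws.bundle, state.x, "recon/coeffs")
    dio.write_coefficient_niftis(ws.root / "coeffs", state.x, voxel_size_mm=220.0 / cfg["matrix_size"])
    np.savetxt(ws.root / "objective_trace.csv", np.asarray(state.objective_trace), header="objective")


def _stage_match(ws: Workspace):
    import h5py

    _require_dataset(ws, "recon/coeffs", "refine")
    x = dio.load_coeffs(ws.bundle, "recon/coeffs")
    dictionary = dio.load_dictionary(ws.bundle)
    basis = dio.load_basis(ws.bundle)
    with h5py.File(ws.bundle, "r") as f:
        mask = f["truth/labels"][()] > 0
    maps = match_templates(x.data, dictionary, basis, mask)
    dio.write_tissue_maps(ws.root / "maps", maps, voxel_size_mm=220.0 / ws.cfg["matrix_size"])
    with h5py.File(ws.bundle, "a") as f:
        for k in ("maps/t1_ms", "maps/t2_ms"):
            if k in f:
                del f[k]
        f.create_dataset("maps/t1_ms", data=maps.t1_ms.astype(np.float32))
        f.create_dataset("maps/t2_ms", data=maps.t2_ms.astype(np.float32))


def masked_rmse(est: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> dict:
    if not mask.any():
        raise ValueError("empty mask")
    d = est[mask] - truth[mask]
    return {"rmse": float(np.sqrt(np.mean(d**2))), "bias": float(np.mean(d)), "n_voxels": int(mask.sum())}


def report(t1_est, t2_est, gt_t1, gt_t2, masks: dict) -> dict:
    """Per-tissue-mask T1/T2 RMSE and bias (the evaluation protocol uses
    white-matter and gray-matter masks)."""
    out = {}
    for name, m in masks.items():
        out[name] = {
            "t1": masked_rmse(t1_est, gt_t1, m),
            "t2": masked_rmse(t2_est, gt_t2, m),
        }
    return out


def _stage_report(ws: Workspace):
    import h5py

    _require_dataset(ws, "maps/t1_ms", "match")
    with h5py.File(ws.bundle, "r") as f:
        t1 = f["maps/t1_ms"][()]
        t2 = f["maps/t2_ms"][()]
        gt1 = f["truth/t1_ms"][()]
        gt2 = f["truth/t2_ms"][()]
        labels = f["truth/labels"][()]
    masks = {"wm": labels == 1, "gm": labels == 2, "foreground": labels > 0}
    rep = report(t1, t2, gt1, gt2, masks)
    (ws.root / "report.json").write_text(json.dumps(rep, indent=1))
    with open(ws.root / "report.csv", "w") as f:
        f.write("mask,map,rmse,bias,n_voxels\n")
        for mask_name, entry in rep.items():
            for which, stats in entry.items():
                f.write(f"{mask_name},{which},{stats['rmse']:.4f},{stats['bias']:.4f},{stats['n_voxels']}\n")


_DISPATCH = {
    "phantom": _stage_phantom,
    "calib-prep": _stage_calib_prep,
    "dcf": _stage_dcf,
    "grid-init": _stage_grid_init,
    "train": _stage_train,
    "infer": _stage_infer,
    "refine": _stage_refine,
    "match": _stage_match,
    "report": _stage_report,
}
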