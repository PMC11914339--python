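"""Self-contained in-memory studies at the package's desk scale.

These functions run the same science as the file-based pipeline but return
their results directly, sized so each completes on one CPU core in minutes:

* :func:`warm_start_study` — the package's central experiment: train the
  block denoiser on synthetic (gridding init, converged reconstruction)
  pairs, then compare FISTA convergence (T1/T2 RMSE in a white+gray matter
  mask) between adjoint initialization and denoiser initialization on a
  held-out phantom.
* :func:`recovery_study` — inverse-crime sanity: noiseless data on a
  fully-sampled Cartesian-plane trajectory, solved with lambda = 0, must
  return the ground-truth coefficients.

Desk-scale study conditions (fixed): 32^3 matrix, 240-TR train, rank-3
basis, 2 coils, 240-sample spiral arms in 48 groups with 16 kept (R = 3),
5% complex k-space noise, lambda = 0.2 after unit-norm scaling, LLR block
8, 40 FISTA iterations, 16^3 denoiser blocks with 8-voxel overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deli_net import (
    BlendSpec,
    TrainConfig,
    augment_volumes,
    extract_training_blocks,
    infer_volume,
    normalize_volume,
    train_denoiser,
)
from .forward_model import AcquisitionModel
from .llr_solver import ReconConfig, estimate_lipschitz, fista_llr, gridding_init
from .mrf_signal import (
    DictionaryGrid,
    SequenceParams,
    build_dictionary,
    compute_basis,
    match_templates,
)
from .nn import NetConfig, build_network
from .phantom import PhantomSpec, make_phantom, simulate_acquisition
from .sampling import SpiralParams, make_cartesian_planes, make_tgas_spiral, pipe_menon_dcf, subsample_groups

__all__ = ["desk_dictionary_basis", "warm_start_study", "recovery_study"]

DESK = dict(
    matrix_size=32, n_tr=240, n_samples_per_tr=240, n_groups=48, keep_groups=16,
    K=3, n_coils=2, n_turns=8.0, lam=0.2, n_iter=40, llr_block=8,
    block_size=16, overlap=8, widths=(8, 16, 32), lr=1e-3, max_epochs=60,
    noise_sigma=0.05, dcf_iters=30,
)


def desk_dictionary_basis(n_tr: int = DESK["n_tr"], K: int = DESK["K"]):
    """Reduced-resolution dictionary (T1 step 100, T2 step 10 in the brain
    range) and its rank-K basis; the reference grids at full resolution are
    in :func:`delics.mrf_signal.default_grid`."""
    seq = SequenceParams(n_tr=n_tr)
    grid = DictionaryGrid(
        t1_values_ms=np.unique(np.concatenate([np.arange(100.0, 3000.1, 100.0), np.arange(3200.0, 5000.1, 200.0)])),
        t2_values_ms=np.unique(
            np.concatenate([np.arange(10.0, 200.1, 10.0), np.arange(220.0, 1000.1, 20.0), np.arange(1050.0, 2000.1, 50.0)])
        ),
    )
    dictionary = build_dictionary(grid, seq)
    basis = compute_basis(dictionary, K=K)
    return seq, dictionary, basis


@dataclass
class _Case:
    gt: object
    model: AcquisitionModel
    b: object
    dcf: object
    L: float
    x0: object


def _make_case(seed: int, seq, basis, p=DESK) -> _Case:
    spec = PhantomSpec(matrix_size=p["matrix_size"], n_coils=p["n_coils"], seed=seed, noise_sigma=p["noise_sigma"])
    gt = make_phantom(spec, basis, seq)
    traj_full = make_tgas_spiral(
        p["matrix_size"], p["n_tr"], p["n_samples_per_tr"], p["n_groups"], SpiralParams(n_turns=p["n_turns"])
    )
    b_full = simulate_acquisition(gt, traj_full, basis, seed=seed)
    traj, b = subsample_groups(traj_full, b_full, keep=p["keep_groups"])
    n = p["matrix_size"]
    dcf = pipe_menon_dcf(traj, (n, n, n), n_iter=p["dcf_iters"])
    model = AcquisitionModel(basis=basis, coil_maps=gt.coil_maps, traj=traj)
    L = estimate_lipschitz(model, dcf.w, n_iter=12)
    x0 = gridding_init(model, b, dcf, lipschitz=L)
    return _Case(gt=gt, model=model, b=b, dcf=dcf, L=L, x0=x0)


def _rmse_wm_gm(x_data, gt, dictionary, basis):
    mask = (gt.labels == 1) | (gt.labels == 2)
    maps = match_templates(x_data, dictionary, basis, mask)
    d1 = maps.t1_ms[mask] - gt.t1_ms[mask]
    d2 = maps.t2_ms[mask] - gt.t2_ms[mask]
    return float(np.sqrt(np.mean(d1**2))), float(np.sqrt(np.mean(d2**2)))


def warm_start_study(seed: int = 0, n_train: int = 4, p=DESK) -> dict:
    """Train the denoiser and measure warm-start vs adjoint-start convergence.

    Returns a dict with the per-iteration (T1, T2) RMSE curves of both runs
    on the held-out test phantom, the iteration at which the warm-started
    run first matches the adjoint-started run's final RMSE on both maps, and
    that iteration as a percentage of the adjoint run's iteration count.
    """
    seq, dictionary, basis = desk_dictionary_basis(p["n_tr"], p["K"])
    rng = np.random.default_rng(seed)

    def refine(case: _Case, x_init=None, callback=None):
        cfg = ReconConfig(
            lam=p["lam"], n_iter=p["n_iter"], block_size=p["llr_block"],
            lipschitz=case.L, callback=callback, exact_trace=False, shift_seed=seed,
        )
        return fista_llr(case.model, case.b, case.dcf, cfg, x_init=x_init)

    # --- training/validation pairs (one phantom family, disjoint seeds) ---
    train_blocks, val_blocks = [], []
    for i in range(n_train + 1):
        case = _make_case(seed + 1000 + i, seq, basis)
        ref = refine(case).x.data
        x0n, sc = normalize_volume(case.x0.data)
        refn = ref / sc
        if i < n_train:
            x0n, refn = augment_volumes(x0n, refn, rng)
            train_blocks += extract_training_blocks(x0n, refn, p["block_size"], volume_id=i)
        else:
            val_blocks += extract_training_blocks(x0n, refn, p["block_size"], volume_id=i)

    net, n_params = build_network(NetConfig(in_channels=2 * p["K"], widths=p["widths"], seed=seed))
    net, curves = train_denoiser(
        train_blocks, val_blocks, net,
        TrainConfig(lr=p["lr"], max_epochs=p["max_epochs"], seed=seed),
    )

    # --- held-out test phantom ---
    test = _make_case(seed + 2000, seq, basis)
    base_curve, deli_curve = [], []
    refine(test, callback=lambda it, xc: base_curve.append(_rmse_wm_gm(xc.data, test.gt, dictionary, basis)))
    x_deli = infer_volume(test.x0, net, BlendSpec(p["block_size"], p["overlap"]))
    refine(test, x_init=x_deli, callback=lambda it, xc: deli_curve.append(_rmse_wm_gm(xc.data, test.gt, dictionary, basis)))

    t1_target, t2_target = base_curve[-1]
    matched = [i + 1 for i, (r1, r2) in enumerate(deli_curve) if r1 <= t1_target and r2 <= t2_target]
    iters_to_match = matched[0] if matched else None
    return {
        "baseline_curve": base_curve,
        "deli_curve": deli_curve,
        "init_rmse": _rmse_wm_gm(test.x0.data, test.gt, dictionary, basis),
        "deli_rmse": _rmse_wm_gm(x_deli.data, test.gt, dictionary, basis),
        "baseline_final": (t1_target, t2_target),
        "baseline_iters": p["n_iter"],
        "iters_to_match": iters_to_match,
        "iter_percent": None if iters_to_match is None else 100.0 * iters_to_match / p["n_iter"],
        "n_params": n_params,
        "val_loss": min(curves["val"]),
        "n_blocks": (len(train_blocks), len(val_blocks)),
    }


def recovery_study(seed: int = 0, matrix_size: int = 64, n_tr: int = 256, n_iter: int = 14) -> dict:
    """Noiseless, fully-sampled, unregularized inverse-crime recovery.

    Every kz-plane is read n_tr/matrix_size times across the train, making
    the lambda = 0 problem well posed; FISTA must return the ground-truth
    coefficient volume.  Returns the relative l2 error per iteration.
    """
    seq, dictionary, basis = desk_dictionary_basis(n_tr=n_tr, K=DESK["K"])
    spec = PhantomSpec(matrix_size=matrix_size, n_coils=2, seed=seed, noise_sigma=0.0)
    gt = make_phantom(spec, basis, seq)
    traj = make_cartesian_planes(matrix_size, n_tr)
    b = simulate_acquisition(gt, traj, basis, noise_sigma=0.0, seed=seed)
    model = AcquisitionModel(basis=basis, coil_maps=gt.coil_maps, traj=traj)
    errs = []
    ref_norm = np.linalg.norm(gt.x_true.data)
    cfg = ReconConfig(
        lam=0.0, n_iter=n_iter, block_size=8, power_iters=8, exact_trace=False,
        callback=lambda it, xc: errs.append(float(np.linalg.norm(xc.data - gt.x_true.data) / ref_norm)),
    )
    fista_llr(model, b, None, cfg)
    return {"errors": errs, "final_error": errs[-1]}
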