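# delics — warm-started subspace reconstruction for volumetric MR fingerprinting

Volumetric MR fingerprinting (MRF) acquires a long train of differently
weighted images (here an inversion-prepared FISP sequence, 500 TRs with flip
angles ramping 10–75°, TI/TE/TR = 20/0.7/12 ms) over a 3D center-out spiral
trajectory, and estimates per-voxel T1/T2/PD by matching each voxel's signal
evolution against a simulated dictionary.  Reconstruction is posed in a
temporal subspace: the dictionary's SVD yields an orthonormal basis
Φ ∈ ℂ^{T×K} (K = 5 suffices) and the unknown becomes K coefficient volumes
x, linked to the multi-coil k-space data b through

    A = F S Φ,        min_x  ½‖D^{1/2}(A x − b)‖₂² + λ·LLR(x)

with S the SENSE coil projection, F the non-uniform FFT onto the spiral
samples, D the Pipe–Menon density-compensation weights that precondition the
problem, and LLR the locally-low-rank penalty (soft-thresholding the
singular values of 8³-voxel blocks reshaped to voxels × K).  The problem is
solved with FISTA, evaluating A sub-model by sub-model over (k, c) pairs so
peak memory stays bounded.

The package's central feature is the **deep-learning warm start**: a small
3D residual U-net, trained on blocks of (density-compensated gridding
reconstruction, converged LLR reconstruction) pairs, denoises the cheap
gridding initializer; FISTA started from that prediction reaches the
converged accuracy in a fraction of the iterations, while still *certifying*
the result against the acquired data (hallucinations are removed because the
iterations converge to the same optimum regardless of the starting point).

Everything runs on synthetic digital phantoms (nested-ellipsoid brain-like
geometry with on-grid tissue T1/T2, smooth coil maps, simulated spiral
acquisition with complex Gaussian noise), so no scanner data is needed.

For whom: researchers prototyping subspace/MRF reconstruction methods, and
anyone needing a self-contained, CPU-only, dependency-light testbed for
density-compensated LLR solvers and learned initializers.

## Worked example

`examples/04_warm_start.py` runs the full desk-scale study — training the
denoiser on four synthetic phantoms, validating on a fifth, racing the two
initializations on a held-out sixth:

```
training blocks (train/val): (28, 8)
denoiser parameters: 130790
best validation l1 loss: 1.519
T1/T2 RMSE [ms] of gridding init:       999.1 /   84.9
T1/T2 RMSE [ms] of denoiser inference:  172.1 /   15.6
T1/T2 RMSE [ms] of 40-iter baseline:    225.3 /   23.1
warm start matches the baseline at iteration 1 of 40  (2.5% of the iterations)
```

Reading: the plain gridding initializer is heavily aliased (T1 error ~1000 ms
in white+gray matter); the trained denoiser alone already beats the
40-iteration adjoint-initialized baseline (172 vs 225 ms T1, 16 vs 23 ms
T2), so the certified refinement matches the baseline's accuracy
immediately and far inside the half-iteration budget.  The other examples
(`01`–`03`, `05`) demonstrate dictionary/basis construction, trajectory and
density compensation, a complete accelerated reconstruction with T1/T2
mapping, and ROVir coil preprocessing.

There is also a staged command-line pipeline operating on an HDF5 bundle:

```sh
delics all --profile desk --seed 1 --output-dir out/
```

with stages `phantom calib-prep dcf grid-init train infer refine match
report` runnable individually and idempotent under unchanged inputs.

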