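# Methods

This note documents the models, numerical choices and scale profiles behind
`delics`, in the order data flows through the pipeline.

## Signal model and dictionary

Fingerprints are simulated with the extended phase graph (EPG) formalism
for an inversion-prepared, gradient-spoiled (FISP-type) train: adiabatic
inversion (Mz → −η·Mz, efficiency η ∈ (0,1], default 1), TI delay, then per
TR an RF pulse of the scheduled flip angle (phase fixed at 0°, no RF
spoiling — the FISP convention), relaxation to TE where the F₀ state is
recorded, relaxation over TR−TE, and one unit of gradient dephasing
(configuration-state shift).  Configuration orders are capped at
min(T+1, 100); with a 2.38 ms excitation ignored, timing is TI/TE/TR =
20/0.7/12 ms.  The EPG implementation is validated against a brute-force
isochromat simulation (2000 uniformly dephased spins) to ~1e−15 relative
error — the two formalisms are algebraically equivalent at uniform
dephasing, so the agreement is exact up to rounding.

The flip-angle waveform of the original sequence is not public; the default
is a half-sine ramp from 10° to 75° over the train, overridable per TR.
Because the basis, the phantom truth and the matching all use the same
schedule, downstream behaviour is insensitive to its exact shape.

The reference dictionary grid is T1 ∈ {20,40,…,3000} ∪ {3200,…,5000} ms and
T2 ∈ {10,12,…,200} ∪ {220,…,1000} ∪ {1050,…,2000} ∪ {2100,…,4000} ms (the
first T2 segment's step is 2 ms; pairs with T2 > T1 are discarded as
unphysical).  Desk-scale work uses the same ranges thinned to steps of
100/10 ms.  The temporal basis Φ holds the first K left singular vectors of
the (T × atoms) matrix; rank 5 captures ≥ 99% of dictionary energy at the
reference sequence, and rank 3 suffices for the desk profile.

Template matching maximizes the magnitude correlation between a voxel's
coefficient vector and the ℓ2-normalized compressed atoms Φᴴa; ties break
to the lowest atom index, zero voxels are flagged.  PD is the complex
projection onto the winning normalized atom.

## Sampling geometry

One variable-density center-out spiral arm (r(s) = kmax·s^p, p = 1.5,
kmax = 0.999·N/2, 8 turns by default) is rotated per TR.  TRs are assigned
round-robin to 48 readout-train groups; each group's arm plane comes from a
spiral-phyllotaxis covering of the sphere, and successive TRs of a group
advance by the 7th tiny golden angle (π/(φ+6) ≈ 23.63°) about the arm
normal.  Retrospective acceleration keeps every third group (16 of 48,
R = 3), thinning the TR axis; a `tr_index` field keeps the retained rows
aligned with the basis.

This is an *analogue*, not a replica, of the scanner protocol: the real
acquisition repeats the 500-TR train once per readout train (48 × 500
arms), which cannot be expressed in a single (TR × samples) trajectory
array.  Interleaving the groups along the TR axis preserves the
R = groups/kept arithmetic, the per-TR basis weighting, and the qualitative
(k,t)-incoherence that the LLR prior exploits.

A consequence worth stating: with tiny-golden-angle shuffling every TR
carries a unique arm, so a peripheral k-space cell is observed under a
single temporal basis row and the K coefficients are not separable there
without the prior — exactly why the λ = 0 problem is ill-posed on this
protocol at any "full" sampling.  For inverse-crime recovery experiments
the package therefore provides a genuinely fully-sampled oracle trajectory
(`make_cartesian_planes`): complete kz-planes cycling across the train, so
every cell is measured under ≥ K well-separated basis rows.  Spiral
phantoms can additionally be bandlimited to the sampled sphere
(`bandlimit_fraction`), since spectrum outside it is invisible to the
operator.

Density compensation follows the iterative fixed point w ← w/(G Gᴴ w),
where G Gᴴ scatters the weights onto an oversampled grid with the gridding
kernel and re-reads them at the sample points (no FFT needed); 30
iterations, Kaiser–Bessel width 4, oversampling 2 (the finer DCF grid makes
uniform Cartesian sampling exactly flat), output clamped positive and
scaled to max 1.

## NUFFT

Kaiser–Bessel gridding with Beatty's shape parameter, default oversampling
1.25 and kernel width 4 (≈1% accuracy against the exact sum; width 6 /
oversampling 1.5 reaches ~1e−4 when needed), periodic wrap on the
oversampled grid, and closed-form sinh apodization.  Forward and adjoint
share interpolation weights, so they form an exact adjoint pair by
construction — the property the solver actually requires; absolute spectral
accuracy only rescales the data consistently on both sides of the inverse
crime.  An exact direct-DFT engine backs the small dense-matrix oracle
tests (agreement to 1e−10 and better).  Inner scatter/gather loops are
numba-compiled with a vectorized numpy fallback.

## Forward model and solver

A = FSΦ is evaluated as A_(k,c) = Φ_k F S_c sub-models: per coil, per
coefficient, one NUFFT of S_c ⊙ x_k, its TR rows scaled by φ[t,k], summed
over k before stacking over c.  Peak transient memory is bounded by
`batch_spec` resident sub-model intermediates (an instrumentation hook lets
tests assert the bound).  The step size is 1/L with L from seeded power
iteration on AᴴDA.

FISTA uses the standard Nesterov t-sequence; the prox of λ·(block nuclear
norm) under step α is blockwise singular-value soft-thresholding with
threshold α·λ.  Blocks are 8³ voxels reshaped to (voxels × K); a seeded
random cyclic shift per iteration (on by default) suppresses blocking
artifacts, with the deterministic shift-0 tiling used when reporting the
objective.  The solver is made monotone by returning the best-objective
iterate; `exact_trace=False` replaces the per-iterate objective evaluation
with the residual already computed at the momentum point, saving one
operator pass per iteration.  Divergence (objective exceeding 10× the
initial value) aborts with a diagnostic.

When no initializer is given the solver starts from the gridding
reconstruction AᴴDb scaled by 1/L — one preconditioned gradient step from
zero, which lands the initializer on the scale of the converged solution.

Regularization is quoted after D^{1/2}b is scaled to unit ℓ2 norm.  The
reference value for the accelerated protocol at full scale is λ = 5e−5 with
40 iterations and block size 8.  λ does not transfer across problem scales:
at 32³ with 64 LLR blocks the corresponding prox threshold (λ/L ≈ 5e−8) is
four orders of magnitude below the block singular values (~5e−3), i.e.
numerically zero.  The desk profile therefore fixes λ = 0.2, chosen once by
scanning the *adjoint-initialized baseline* for the qualitative regime the
method operates in (T2 RMSE converging over the full 40 iterations, T1
within ~20); it was not revisited afterwards.

## Coil preprocessing

Noise pre-whitening uses the Cholesky factor of the sample noise
covariance (ridge-regularized with a warning when singular).  ROVir solves
G_roi v = μ G_int v (Gram matrices of per-voxel coil vectors over the
region of interest and the interference region), orders virtual coils by
descending signal-to-interference ratio μ and drops the worst n (reference
protocol: 8 of 48), followed by SVD compression to n_out channels
(reference: 10).  The composite matrix applies unchanged to non-Cartesian
k-space because channel mixing is acquisition-domain-agnostic.

autoFOV: sum-of-squares combine, maximum-intensity projection along the
left-right axis, Gaussian smoothing (σ = 2 calibration voxels), Otsu
binarization, largest connected component, bounding box; the shift moves
the FOV only as far as needed to pull the box's superior/anterior edges a
margin (default 10 mm) inside the target FOV — a centered subject yields a
zero shift.  Shifts are applied to k-space as the exact linear phase
exp(−2πi k·Δ/N).  Since scanner coil-map estimation is out of scope, the
phantom supplies ground-truth maps and a smoothed-quotient estimator
(lowpass coil image / smoothed root-sum-of-squares) is provided as a
practical fallback.

## Block denoiser

The network is a residual U-net on 2K-channel blocks (real and imaginary
parts stacked): three encoder residual blocks (two 3³ convolutions + ReLU
with a kernel-1 dimension-matching skip), strided-conv downsampling,
mirrored decoder with nearest-neighbor upsampling and additive skip
connections, a final full-resolution residual block and a linear 3³ head.
At the full-scale widths (160, 224, 384) with 10 channels this carries
23.8 million trainable parameters (verified analytically and by
introspection).  The published figure annotating the per-level widths is
not available in extracted form, so the widths were fixed by matching that
printed parameter count under the stated layer structure.  Desk-scale
widths are (8, 16, 32) (~131k parameters).

Training pairs are non-overlapping L³ blocks from volumes normalized to
unit ℓ2 norm; a block survives when the standard deviation across the K
channels of its per-channel DC terms (voxel sums, magnitudes) reaches 0.3 —
the reading of the published background filter that yields one scalar per
block; at desk scale foreground blocks sit at ~0.4–1.7 and empty ones near
0.  Because unit-norm volumes have per-voxel values ~1e−3 (worse at larger
matrices), blocks are additionally scaled by √(volume elements) to unit
per-voxel RMS before entering the network; the gain is applied
symmetrically at inference and cancels end to end, but keeps activations
and gradients O(1) so CPU-scale training budgets work.

Augmentation: whole-volume axis flips, axis permutation and cyclic integer
shifts (applied identically to input and target), plus per-block amplitude
scaling uniform in [0.5, 1].  Loss is mean absolute error under Adam with
early stopping on validation loss and halving of the learning rate when
the validation loss plateaus (the ℓ1 loss floor scales with the step
size).  Full-scale reference settings are lr 1e−5 over up to 540 epochs;
the desk profile uses lr 1e−3 for ≤ 60 epochs on ~30 blocks from 4+1
phantoms — minutes on one core.

Inference tiles the volume with stride L − overlap (reference 64/16, desk
16/8) and recombines with separable linear cross-blend weights (0→1 ramp
across each overlap, flat interior, complementary ramps summing to one;
accumulated weights are normalized so an identity network reproduces its
input to machine precision).  The network input is the same
density-compensated gridding reconstruction the training inputs came from.

## Phantoms and study conditions

Phantoms are nested ellipsoids with seeded geometric jitter: white matter
(T1/T2 800/60 ms, PD 0.8), a gray-matter shell (1300/90, 0.9), CSF
ventricles (4000/1900, 1.0) and one white-matter lesion (1100/150, 1.0) —
all on both the reference and desk dictionary grids so noiseless matching
is exact.  Coil sensitivities are smooth loop-like magnitudes with
low-order phase, normalized to unit sum-of-squares (the SENSE convention;
also what keeps AᴴDA well conditioned).  In parenchyma the first
coefficient channel dominates voxelwise; CSF legitimately loads the second
channel.  K-space noise is complex Gaussian with per-component σ equal to
5% of the RMS sample magnitude (seeded).  Data are generated through the
same operator code path the solver inverts — a deliberate inverse crime,
appropriate because every claim made here concerns solver and warm-start
behaviour, not acquisition realism; a lower-accuracy NUFFT setting is
available to break the symmetry.

Desk-scale study conditions, fixed once: 32³ matrix, 240-TR train, K = 3,
2 coils, 240-sample arms, 48 groups with 16 kept (R = 3), λ = 0.2, 40
FISTA iterations, denoiser trained on 4 phantoms and validated on 1, tested
on a held-out 1.  The inverse-crime recovery study runs at 64³ with 256
Cartesian-plane TRs (4 basis rows per cell) and λ = 0, converging below 1%
relative error in ~13 iterations.  Accuracy is reported as T1/T2 RMSE over
the white+gray matter mask, mirroring the segmentation-mask evaluation
protocol of the source method.

What passing these studies does *not* show: performance on real scanner
data (B0/B1 effects, fat signal, motion, gradient imperfections and
realistic coil noise are all absent), behaviour at 256³/rank-5 scale, or
robustness of the denoiser to anatomy outside the ellipsoid family it was
trained on.

## Known limitations

* No B0/B1 correction; no Toeplitz/PSF fast normal operator (the sub-model
  split exists precisely to avoid its memory cost); no JSENSE.
* The numpy network trains small models at desk block sizes; it is not a
  general deep-learning framework and has no GPU path.
* The trajectory is an interleaved-group analogue of the multi-train
  protocol (see above) and makes no claim of gradient-hardware feasibility.
* Training micro-benchmarks (single-block overfit, identity task) reach
  floors of a few percent of the initial loss within CPU budgets; the
  meaningful training validation is the end-to-end warm-start study.
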