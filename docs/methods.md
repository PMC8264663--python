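# Methods

## Problem and model

The package targets the quasi-steady concentration field of a fast-diffusing
species (oxygen is the motivating case) in a two-dimensional tissue patch
with constant-value circular sources — a caricature of two parallel blood
vessels seen in cross section. On an `L x L` pixel lattice (reference
`L = 100`), the stationary field `u` solves

    D ∇²u − γ u = 0

outside the sources, with `u` clamped to each disk's value inside it and
absorbing (Dirichlet-0) conditions at the boundary. With `D = 1` px²/s and
`γ = 1/400` s⁻¹ the diffusion length `l_D = sqrt(D/γ) = 20` px: four source
radii and a fifth of the domain, so sources interact with each other and
with the boundary.

Discretization: unit pixel spacing, 5-point Laplacian, ghost pixels outside
the lattice held at zero. Source pixels are Dirichlet constraints (identity
rows). The resulting sparse linear system is solved directly with a sparse
LU factorization to a residual 2-norm of 1e-10 — far below every downstream
loss or metric scale. A direct stationary solve is exact and faster than
time stepping; Jacobi relaxation and explicit-Euler time stepping are kept
in the test suite as independent oracles, which agree with the sparse solve
to better than 1e-6 on small grids. The stencil assembly is
dimension-generic, which lets the test suite also pin the solver against the
closed-form solution of the 1D two-term recurrence
`D(u_{k+1} − 2u_k + u_{k−1}) = γ u_k` (agreement to 1e-8).

Geometry conventions (the continuous problem statement does not fix them;
declared once and used everywhere): pixel centers at integer coordinates,
0-based row-major; a pixel belongs to a disk iff its center lies within the
radius; disk centers are sampled at integer coordinates uniformly over the
admissible box; non-overlap is strict (`center distance > 2R`, so disks
cannot touch and never share pixels); the free disk's value is drawn as
`1 − U[0,1)`, i.e. uniform on `(0, 1]`.

## Synthetic data

`generate_dataset` emulates the study conditions: two radius-5 disks per
layout, one at value 1, placed by rejection sampling; the paired target is
the exact stationary solve. Reference scale is 20,000 pairs split 80/20;
desk-scale work uses the same generator on smaller grids (32x32) and sample
counts. The generator reproduces the value imbalance that motivates the
weighted loss (roughly 2πR²/L² ≈ 2% of pixels near value 1 at reference
geometry). It does not emulate anything beyond the stated idealization: no
source-shape or source-count variation, no spatially varying or anisotropic
diffusivity, no measurement noise. Passing tests therefore demonstrate that
the surrogate machinery works under these idealized conditions, not that a
trained model transfers to real vasculature geometries.

## Surrogate architecture

Two branches, combined as `ŷ = p₁·NN1(x) + p₂·NN2(x)` with fixed Boolean
mixing weights in all presets.

* NN 1: six size-preserving 3x3 convolutions, channels 1-4-8-16-8-4-1,
  leaky-ReLU (slope 0.01) on layers 1–5, ReLU on layer 6, batch
  normalization after every layer, dropout D1 after layer 1 and D2 after
  layer 6. It localizes sources but cannot propagate long-range field
  information.
* NN 2: a convolutional autoencoder. Encoder stages are [3x3 padded
  convolution, leaky-ReLU, 2x2 mean-pool (floor mode)], with batch norm and
  dropout D3 after the first convolution; spatial sizes trace
  100-50-25-12-6-3 with channels 1-64-128-256-512-1024, and an unpadded 3x3
  convolution collapses the 3x3 map to a 2048-channel 1x1 bottleneck.
  The decoder's transposed convolutions trace 1-3-7-13-25-51-100 with
  channels 2048-1024-512-256-128-64-1; dropout D4 sits before the final
  4x4 transposed convolution. Squeezing through the 1x1 bottleneck forces a
  global representation of the field.

Numerical/architectural choices the layer listing leaves open:

* Transposed-convolution stride/padding per decoder step are chosen to
  realize the target size sequence exactly (1→3: 3x3 stride 1; 3→7: 3x3
  stride 2; 7→13, 13→25: 3x3 stride 2 pad 1; 25→51: 3x3 stride 2; 51→100:
  4x4 stride 2 pad 2).
* Mean-pool uses floor mode (25→12 drops the odd remainder) — the only
  convention consistent with the target sizes.
* The final batch norm of each branch is placed before the final ReLU
  rather than after it. Taken literally, a trailing affine batch norm could
  emit negative field values; non-negative output (the field is a
  concentration) is the stronger contract, so the order conv → [dropout] →
  batch norm → ReLU is used for the last layer only. Inner layers follow
  the listed conv → activation → [dropout] → batch norm order.
* Weight initialization is uniform Kaiming-style (bound `1/sqrt(fan_in)`)
  from an explicitly passed generator; the run seed is recorded in the
  checkpoint sidecar.

Grids other than 100x100 keep NN 1 unchanged (it is size-preserving) and
shorten NN 2's schedule: halve until the map is ≤ 3 px, collapse to 1x1
with a valid convolution of that size, and mirror the reversed size list in
the decoder (doubling steps use 4x4 stride 2 pad 1; `2n+1` steps use 3x3
stride 2). Channel widths scale with `nn2_base_channels` (64 reproduces the
reference; desk-scale tests use 8, giving a 128-channel bottleneck and
~136k parameters against ~50.3M at reference scale).

The layers themselves (convolution, transposed convolution, batch norm,
dropout, mean-pool, ReLU family) and the ADAM optimizer are implemented
in-package as a small float64 numpy layer library with hand-written
backward passes, lowered to BLAS matrix multiplies via im2col. Every
gradient is validated against central finite differences in the test suite
(relative error ≤ 1e-5 at probe points). Inference mode freezes batch-norm
statistics and disables dropout, so predictions are deterministic.

## Loss

Per pixel: `exp(−(1 − y)/w) · |ŷ − y|^α`, averaged jointly over pixels and
batch items; `α = 1` (MAE) or `2` (MSE). The weight uses the ground truth
only and is treated as a constant in the gradient. `α = 1` takes the
absolute difference (a signed first power would not be a norm). Minibatch
training optimizes per-minibatch means; the epoch loss reported to the
roll-back rule is the sample-weighted mean of minibatch losses. The weight
compensates for the ~2% frequency of near-1 pixels; `w → ∞` recovers the
plain norm (verified to 1e-9).

## Training and roll-back

ADAM (lr 1e-3, betas 0.9/0.999, minibatch 32 by default; learning rate and
batch size are conventional defaults and stay configurable), 800 epochs at
reference scale, with per-epoch reshuffling.
Stochastic training occasionally jumps to a much worse loss and stays
there; the roll-back rule rejects an epoch whose loss exceeds
`C × (trailing mean of the last m accepted epoch losses)` — `C = 5`,
`m = 20` — and restores the snapshot from `s = 5` epochs earlier. Details
that required a decision:

* The trigger compares the candidate loss against C times the trailing
  mean (equivalently, candidate/mean > C): the only dimensionally
  consistent reading of a "ratio" threshold.
* No roll-back during the first `m` epochs (the trailing mean is not yet
  representative).
* Snapshots capture parameters, batch-norm buffers and ADAM moments
  together, so a revert is bit-exact (round-trip tested).
* After a revert the shuffle/dropout streams continue advancing; replaying
  the identical stream would deterministically reproduce the jump.
* Rejected epochs consume epoch budget (the run always executes exactly
  `epochs` optimization epochs) and are logged but excluded from the
  accepted history and the trailing mean.
* A safety cap (`max_rollbacks`, default 200, an order of magnitude above
  the counts a healthy full-scale run should need) aborts pathological
  runs; so does a non-finite loss.

Independently of roll-back, the returned model is the snapshot with the
lowest accepted epoch training loss, whenever it occurred. (A rejected
epoch can never hold the minimum: its loss exceeds five times a trailing
mean that is itself bounded below by the running minimum.) Selection on
training loss matches the quantity the roll-back rule monitors; validation
selection can be layered on via the per-epoch callback.

## Evaluation

Residuals `|y − ŷ|` are pooled across all pixels of all test pairs (the
per-image alternative is deliberately not used). The 99th percentile uses
linear interpolation between order statistics; standard deviations use the
population convention. The relative residual is masked where the ground
truth falls below a floor (default 1e-3, configurable): the field vanishes
at the absorbing boundary, where relative error diverges and carries no
information. Slice statistics bin pixels by ground-truth value into ten
bands of width 0.1 (left-closed, last band closed, so source pixels at 1.0
land in band 10) and report per-band residual mean/std plus equal-weight
aggregates — the band view compensates for low-value pixels outnumbering
high-value ones by ~50:1. Field-value PDFs are density histograms on [0, 1]
(100 bins by default); the histogram-intersection overlap (1 = identical)
quantifies how well the predicted value distribution matches the truth,
the check on which MAE-trained models visibly beat MSE-trained ones.

## Break-even model

`t_direct = Nδ` against `t_neuro = Mδ + E + Nε` gives
`N_min = (M + E/δ)/(1 − ε/δ)`. With the reference workflow numbers
(M = 20,000, δ = 1.16 s, E = 12 h, ε = δ/1000) the package computes
N_min ≈ 57,299 — the surrogate pays off only for workflows that evaluate
tens of thousands of replicas, e.g. parameter sweeps or uncertainty
quantification. The tool reports; it does not benchmark the user's
hardware.

## Desk-scale study conditions

Full-scale training (20k samples at 100x100, 800 epochs) is a GPU-days
workload and is not reproduced here. The package's end-to-end checks use a
scaled-down analogue chosen once: 32x32 grid (l_D = 20 px still exceeds
the half-domain, keeping the sources-interacting regime), radius-5 disks,
640 pairs (512 train / 128 test), the width-8 autoencoder plus full NN 1,
MAE with w = 100 and the reference dropout rates (0.4, 0.4, 0.1, 0.1), 60
epochs. Under these conditions a seeded run reaches a test mean residual
in the 0.03–0.035 range (untrained baseline ~0.26–0.30), and the
MAE-trained model's value-distribution overlap with ground truth (~0.88)
exceeds an equally budgeted MSE twin's (~0.78), reproducing the
qualitative MAE-vs-MSE distribution claim at desk scale. These numbers are
recomputed at run time — the MAE/MSE comparison by the end-to-end tests,
the MAE training cycle by `scripts/acceptance.py` — never hard-coded.

## Known limitations

* Two circular sources, absorbing boundaries, uniform isotropic `D` only;
  reflecting/periodic/mixed boundaries, other source counts/shapes and 3D
  are out of scope.
* The numpy layer library is single-threaded CPU code built for
  correctness and desk-scale work; reference-scale training is possible in
  principle but impractically slow without a GPU framework.
* Desk-scale residuals (~3e-2) are far above what reference-scale
  training budgets can reach; the scaled study demonstrates the pipeline's
  behavior, not full-scale accuracy.
* Relative-residual summaries depend on the chosen floor near the
  boundary; the floor is configurable and recorded in reports.
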