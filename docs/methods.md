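# Methods

This note records the models implemented by `unicorn_hic`, the
conventions and defaults that shift numeric results, and what the
synthetic test bed does and does not demonstrate.

## Contact-map model and I/O

A contact map is a dense, square, symmetric, non-negative matrix with
binning metadata (bin size, chromosome label, start coordinate).  Maps
are symmetrized on load with `(M + Mᵀ)/2`; triplet records are
accumulated by summing duplicates in either orientation before
mirroring, so the sparse round trip is exact for integer counts.  Dense
storage is deliberate: per-chromosome maps at 100–500 kb are at most a
few thousand bins.  Raw counts are used throughout; no ICE/KR
normalization is applied or assumed.

## Degradation model and alternating restoration

The super-resolution stage treats low depth as a *learnable*
degradation rather than a fixed downsampling ratio:

* `T` is a same-shape convolution (odd kernel, default 5×5, identity
  initialization) times a positive scalar scale (`exp` of a learned
  log-scale), clamped at zero.  This encodes read-depth degradation:
  low- and high-depth maps have identical dimensions.
* The objective `J(H,T) = mean((L − T(H))²) + β·P(H)` uses the mean
  (not summed) squared form — this affects only the scale of β — with
  `P` either mean |H| (sparsity) or anisotropic total variation.

The restoration network unrolls `N` alternations (default 5, following
the ablation of the deep-alternating design it adopts) of:

1. **Estimator**: convolution over the concatenation of the head's
   low-depth features and the current restored map, global average
   pooling, and a two-layer MLP producing a low-dimensional degradation
   representation (default 8).
2. **Restorer**: FiLM conditioning — the representation is mapped to
   per-channel scale/shift applied to convolutional features of `L` —
   followed by a residual projection back to map space and a ReLU
   clamp.

A final image tail applies one more residual refinement.  Widths and
depths are not prescribed by the underlying design, so the blocks are
kept small (default 8 channels) to train in seconds-to-minutes on one
CPU; all sizes are configuration.  Estimator and Restorer are trained
jointly with one Adam optimizer — the alternation is architectural
(an unrolled loop), not alternating freezing.

Training minimizes
`w_restore·mean|Ĥ − H_GT| + w_kernel·mean|T(H_GT) − L| + β·P(Ĥ)`
on patch pairs.  The L1 data terms are an engineering choice (robust to
count outliers); the squared-norm `J` above remains available as the
stated degradation objective.  Inputs are divided by a single
`input_scale` (the mean of the training patches) so convolutions see
O(1) values.  Symmetry is enforced after reassembly rather than
architecturally; non-negativity by output clamp.  One master seed fans
out to weight initialization, batch sampling and thinning draws, making
loss traces bit-identical across runs on one platform.

Because no deep-learning framework is part of the dependency set, the
network runs on a compact reverse-mode autodiff engine
(`unicorn_hic.autograd`) whose primitives (broadcast arithmetic,
convolution, dense layers, reductions) are verified against central
finite differences in the test suite.

## Wish distances and the reconstruction likelihood

The contact–distance conversion is the reciprocal power law
`X_ij = IF_ij^(−α)` — the convention of the maximum-likelihood
reconstruction family this stage follows.  Pairs with zero contact
frequency are excluded rather than imputed; `n` counts only scored
pairs.  The log-likelihood

`L(S) = −n/2 − n·log(max(mean((Xˢ − X)²), ε))`

uses a floor `ε = 1e-12` because the expression is otherwise unbounded
above as the fit becomes exact; on the floor the gradient is zero.
Pairwise distances are floored at 1e-9 inside the likelihood and its
analytic gradient so coincident loci cannot divide by zero.

Optimization is gradient ascent with backtracking: a step is accepted
only if it increases the likelihood (step then grows 10%), otherwise
halved; convergence is declared when the relative improvement of an
accepted step falls below `tol` (1e-9).  Initial coordinates are
uniform in a cube scaled to the mean wish distance, seeded.  The
likelihood depends only on pairwise distances, so results are defined
up to rigid transforms (including reflection — contact data carry no
chirality); all structure comparisons therefore superpose first, with
reflections allowed by default.

**α estimation** runs the optimizer (reduced iteration cap, shared seed
across candidates) for each grid value (default 0.1–2.0, step 0.1) and
scores by the Pearson correlation between reconstructed and wish
distances.  Correlation rather than raw likelihood is used because wish
distances at different α live on different scales, making likelihoods
incomparable across the grid; ties break toward the smaller α.
Ensembles rerun the optimizer at the selected α with distinct derived
seeds; both a best-likelihood and a TM-score-medoid representative
selector are provided, since either is a defensible "representative
model".  Model units are arbitrary; no calibration to micrometers is
attempted, so probe-distance validation is correlation-based.

## Metrics and their conventions

Absolute values of the map metrics depend on conventions, which are
echoed alongside every score:

* **PSNR** `10·log10(MAX²/MSE)`: `MAX` defaults to the maximum over
  both matrices; identical maps report the capped sentinel 99 dB with a
  flag.
* **SSIM**: uniform sliding window (default 7×7), population variance
  and covariance, stabilization constants `D1 = (0.01·M)²`,
  `D2 = (0.03·M)²`; the mean over the fully covered region is reported,
  with a single global window for matrices smaller than the window.
  Matches `skimage.metrics.structural_similarity` with uniform windows
  and population covariance, which the tests use as an independent
  oracle.
* **GenomeDISCO**: each map row-normalized to a random-walk transition
  matrix (zero rows left zero), raised to the power `t` (default 3);
  score `1 − Σ|Aᵗ − Bᵗ| / mean(nonzero rows)`.  Identical maps score
  exactly 1; the score has no lower bound.
* **TM-score**: `d0 = max(1.24·(L−15)^⅓ − 1.8, 0.5)` (the floor covers
  short chains, L ≤ 21); superposition starts from the least-squares
  Kabsch solution and is iteratively reweighted toward the TM objective
  with weights `1/(1 + (d/d0)²)²`.
* **Insulation scores**: for each interior bin, the mean count in the
  off-diagonal square `[i−w, i) × (i, i+w]`, log2-normalized by the
  profile mean, edge bins excluded; window means are floored at 1e-12
  so profiles stay finite when a window is empty.  The L2 distance
  between two profiles is the TAD-consistency statistic.  This is the
  standard sliding-square insulation scheme, used here as a consistency
  analogue — it is not a graph-based TAD caller.

## Synthetic data: what it emulates and what it does not

The generator produces chains with unit bonds and bounded turning angle
(uniform turn in [0, 60°] about a random orthogonal axis) — locally
stiff like chromatin fiber, but not a polymer-physics simulation.
Expected counts follow `λ_ij = scale·d_ij^(−1/α_true)`, the exact
inverse of the wish-distance rule, so noiseless recovery experiments
have a known optimum; Poisson noise and TAD-like block enrichment add
the dominant statistical features of real scHi-C (counting noise,
distance decay, domain structure).  Low-depth maps are binomial
thinnings of high-depth maps with per-sample retention drawn from a
configurable range, default [0.3, 0.95] — chosen to span severe to mild
depth loss around the 0.75 retention conventionally used for fixed
downsampling.

What passing tests show: the estimator/restorer machinery learns a real
inverse-degradation signal (enhanced maps beat their low-depth inputs
on PSNR/SSIM on held-out pairs); the likelihood machinery recovers
structures and exponents exactly in the noiseless limit and
reproducibly under random restarts.  What they do not show: performance
on real scHi-C coverage distributions, cross-species generalization, or
absolute metric levels comparable to trained-at-scale models — real
maps have heavier-tailed coverage, structural zeros and mappability
artifacts the generator does not emulate.

## Problem sizes and defaults

Desk-scale defaults keep every experiment in seconds to a minute or two
on one CPU: 60-locus chains for reconstruction experiments (2000
iteration cap, ~500 typically used), a 20×0.1 α grid with a
400-iteration search cap, ensembles of 20, and training on 36 patches
of 40×40 for 400 Adam steps (batch 4, learning rate 2e-3).  All are
configuration, not limits of the method.

## Known limitations

* The unrolled network is intentionally small; it demonstrates the
  blind-degradation mechanism rather than maximizing benchmark scores.
* The degradation kernel is a single linear convolution with scale —
  adequate for thinning-like degradations, not for spatially varying
  artifacts.
* `estimate_alpha` assumes a single global exponent; locus-dependent
  conversion is out of scope.
* Structures are reconstructed per map (one chromosome at a time);
  multi-chromosome and genome-wide modelling are out of scope.
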