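# Methods

## Model

The displacement field is a blend of local rigid deformations carried by
mobile anisotropic 3D Gaussian primitives. All geometry lives in the
canonical cube [−1, 1]³: the fixed image's voxel grid is mapped per axis with
index 0 → −1 and index n−1 → +1. Anisotropic voxel spacing enters only when
converting displacements to millimetres (factor (n−1)/2 voxels per canonical
unit, then spacing). The moving image is sampled — never indexed — at
x + φ(x), with trilinear interpolation and border clamping, so fixed and
moving volumes may have different shapes (both are assumed to span the same
physical extent via their own canonical maps).

Each primitive holds five parameter blocks: centre μ (canonical), log-scales
(exponentiated to s > 0, which keeps Σ = Q S S ᵀ Qᵀ positive definite under
unconstrained optimization), an orientation quaternion q for the covariance,
a rigid-rotation quaternion r, and a translation t (canonical units).
Quaternions are scalar-first and normalized at every matrix conversion rather
than constrained, so the parameterization is invariant to their raw norm.

A voxel's displacement per lattice scale is the Gaussian-density-weighted
mean of its K nearest primitives' rigid offsets (K-NN by Euclidean distance
to centres; the full covariance enters the weights only). The density
normalizer (2π)^{3/2}|Σ|^{1/2} is computed, not dropped — it cancels for
congruent neighbours but reweights anisotropic mixtures. With two lattice
scales the final field is the unweighted mean of the per-scale blends. KNN
index selection is treated as non-differentiable; gradients flow through the
weights (to μ, s, q) and the transforms (to μ, r, t).

Weight normalization runs in log space (softmax with max-subtraction), which
makes under/overflow of the raw densities harmless; a configurable floor
`eps` (default 1e−12) guards the normalizer and a uniform-1/K fallback covers
fully degenerate points.

## Gradients and optimization

The whole computation graph — blending, trilinear warp-sampling, NCC, TV —
carries hand-derived analytic gradients, verified against central finite
differences in the test suite (all five parameter blocks, the sampler and
both losses). Adam (β₁ = 0.9, β₂ = 0.999) is implemented directly; the
learning rate ramps linearly over a warm-up phase and then follows cosine
annealing down to `min_lr_frac` × base (default 0.01×). Per-block base rates
default to 1e−2 for μ, q, r, t and 5e−3 for the log-scales, in canonical
units. KD-trees over the centres are rebuilt every `knn_refresh` iterations
(default every iteration).

The similarity loss is the negative Pearson correlation of warped-moving vs
fixed intensities over a mini-batch of B uniformly sampled voxels. Because
the batch is scattered, windowed NCC degenerates to this global form; it is
invariant to positive affine intensity rescaling and returns 0 (with a
warning) for zero-variance batches. The regularizer is a stochastic total
variation: ⌊B/4⌋ seed voxels, each with its three forward neighbours, and the
mean over seeds of the L1 norms of the one-voxel forward differences
(isotropic L2 selectable). The estimator is unbiased for the full-grid mean
TV, which the suite checks to within three standard errors. Differences are
per voxel step on the canonical grid, with no division by the step size.

### λ and resolution

Because the TV differences are not divided by the canonical voxel step
h = 2/(n−1), the effective gradient penalty is λ·h: the same λ regularizes
more strongly on coarser grids. The default λ = 8 is calibrated to clinical
resolutions (~200–256 voxels per axis). Test-scale volumes must scale λ
accordingly to represent the same operating point: on a 48³ grid,
λ ≈ 8 × 47/255 ≈ 1.5. The acceptance runs use exactly this value; with an
unscaled λ = 8 at 48³ the TV cost of the true field exceeds the total
attainable similarity gain and the optimum is over-smoothed.

### Adaptive density control

At a configurable interval (default every 200 iterations within
[200, 1500]), primitives whose mean accumulated positional-gradient magnitude
exceeds a threshold (default: 95th percentile at the first invocation) are
densified — split into two offset children with halved scales when their
largest scale exceeds their lattice's node spacing, cloned in place otherwise
— and primitives whose maximum blending weight stayed below ε_p = 1e−4 are
pruned (never emptying a scale). The total count is capped at 4× the initial.
Adam state rows follow the surviving primitives; new primitives start fresh.
The exact split geometry and thresholds are deliberate, configurable choices;
the mechanism follows the split/clone/prune pattern established for
point-primitive scene representations.

## Defaults

| parameter | default | notes |
|---|---|---|
| iterations | 2000 | full-quality runs; 500 suffices at 48³ |
| batch size B | 20 000 | 4096 at 48³ |
| λ | 8 | scale by (n−1)/255 on an n³ grid (see above) |
| K | 8 | one lattice cell's corner count, per scale |
| lattices | 6³ + 12³ | two scales; single 8³ for 48³ volumes |
| warm-up | 100 iterations | linear ramp, then cosine decay |
| initial s | lattice node spacing | neighbouring kernels overlap at init |

## Synthetic data

`gsdir.fixtures` generates complete registration problems with exact ground
truth. The true deformation is produced by the model's own representation — a
4³ primitive lattice with spatially correlated node translations
(lattice-smoothed white noise; anatomical motion is dominated by smooth bulk
components, and i.i.d. node motions would be the roughest field the lattice
can express) plus small rotations, rescaled so the peak blended displacement
equals the requested voxel magnitude, and rejected/redrawn if the field folds
anywhere (non-positive Jacobian determinant). The moving image is a texture
of ~400 Gaussian blobs per 48³ (widths 1–4 voxels) plus fine smoothed noise:
the phantom must carry intensity gradients at the scale of the deformation,
otherwise sub-voxel recovery is ill-posed for any similarity measure. The
fixed image is the warped moving image; landmark pairs satisfy
p_m = p_f + φ(p_f) exactly in continuous coordinates; labels are thresholded
smooth blobs warped with nearest-neighbour interpolation.

Because the ground truth comes from the same representation family that the
optimizer fits, recovery tests are well-posed model-inversion problems. They
demonstrate correctness of the pipeline — gradients, sampling, optimization,
metrics — not clinical accuracy: the generator does not emulate modality
physics (CT attenuation ranges, MR bias fields), occlusion/appearance
changes, sliding interfaces, or deformations outside the primitive family's
span.

## Numerical choices

- Trilinear interpolation with border clamping for all intensity sampling;
  out-of-cube queries clamp and receive zero gradient along clamped axes.
- KNN ties break toward the lower primitive index; neighbours are recomputed
  from mutable centres, so a primitive outside every K-neighbourhood has
  bitwise zero influence.
- NCC of a zero-variance batch is defined as 0; NaN inputs are rejected.
- The deformation Jacobian for the folding metric uses central differences on
  interior voxels in voxel units; det J ≤ 0 counts as folded (threshold
  configurable).
- HD95 surfaces are 6-connectivity boundary voxels; distances use the exact
  Euclidean distance transform with spacing; the symmetric value is the max
  of the two directed 95th percentiles. Dice is macro-averaged over labels.
- Dense fields are materialized once, in chunks (default 65 536 voxels), to
  bound memory.
- Seeds: every stochastic component (batch sampler, generator) derives from a
  single integer seed; equal seeds give bitwise-equal loss histories and DVF
  files.

## Problem sizes

The test suite and the acceptance script run on 16³–48³ volumes with 64–512
primitives, 500-iteration registrations and mini-batches of 512–4096 voxels —
sizes chosen so the whole suite completes in minutes on one CPU while still
exercising every code path end to end. The full-resolution defaults above are
what one would use on clinical volumes.

## Known limitations

- Single-modality similarity only (NCC); no mutual information.
- No GPU path; the KD-tree KNN and numpy blending are the throughput
  bottleneck at clinical sizes.
- Orientation matrices beyond spacing/origin are passed through, not
  resliced; inputs are assumed co-oriented.
- The density-control procedure is a documented default, exposed in
  configuration, rather than a uniquely determined rule.
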