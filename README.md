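# gsdir — deformable image registration with mobile 3D Gaussian primitives

`gsdir` performs pairwise deformable image registration (DIR) of 3D medical
volumes — the problem of finding, for a fixed image I_f and a moving image
I_m, a displacement vector field (DVF) φ such that I_m(x + φ(x)) aligns with
I_f(x). DIR underpins contour propagation, dose accumulation and motion
modelling in radiotherapy, where both accuracy and speed matter.

Instead of a dense voxel grid, a B-spline lattice or an implicit neural
network, the DVF here is carried by a sparse set of N mobile anisotropic 3D
Gaussian primitives

    G_i = {μ_i, s_i, q_i, r_i, t_i},   Σ_i = Q_i S_i S_iᵀ Q_iᵀ,

each combining a Gaussian kernel (centre μ_i, per-axis scales s_i, orientation
quaternion q_i) with a local rigid deformation (rotation quaternion r_i,
translation t_i). A voxel x_j takes its displacement from its K nearest
primitives per lattice scale:

    x̂_jk = R_k (x_j − μ_k) + μ_k + t_k
    ŵ_jk = (2π)^{-3/2} |Σ_k|^{-1/2} exp(−½ (x_j−μ_k)ᵀ Σ_k^{-1} (x_j−μ_k))
    φ_j  = Σ_k (ŵ_jk / Σ_l ŵ_jl) (x̂_jk − x_j),

averaged over two lattice scales when both are used. All five parameter
blocks are optimized per case by mini-batch Adam against

    L = Ls + λ Lr,

where Ls is the negative normalized cross-correlation (Pearson correlation
over a mini-batch of B randomly scattered voxels) and Lr is a mini-batch
total-variation estimate (B/4 seed voxels plus their three forward
neighbours). Defaults: 2000 iterations, B = 20 000, λ = 8, K = 8, warm-up
plus cosine-annealed learning rates, and optional adaptive density control
(split/clone high-gradient primitives, prune never-contributing ones).

The model, its analytic gradients and the optimizer are implemented in
numpy/scipy; volumes, landmark files and displacement fields go through
SimpleITK (NIfTI / MetaImage, DIR-Lab-style landmark text files).

## Worked example

Everything below runs on synthetic data generated by the package itself
(`gsdir.fixtures`), so no downloads are needed:

```python
import numpy as np
from gsdir import make_case, register, RegistrationConfig, tre
from gsdir.core_model import DisplacementField

case = make_case((48, 48, 48), deform_magnitude_vox=3.0, seed=1)
cfg = RegistrationConfig(iterations=500, warmup_iters=50, grids=((8, 8, 8),),
                         batch_size=4096, K=8, seed=1,
                         density_control=False, lambda_reg=1.5)
prims, dvf, state = register(case.fixed, case.moving, cfg)

zero = DisplacementField(np.zeros(case.gt_dvf.values.shape))
before = tre(case.fixed_landmarks, case.moving_landmarks, zero, case.fixed.spacing)
after = tre(case.fixed_landmarks, case.moving_landmarks, dvf, case.fixed.spacing)
print(f"TRE {before.mean():.3f} -> {after.mean():.3f} mm")
```

prints

```
TRE 1.319 -> 0.179 mm
```

i.e. the mean landmark misalignment of a 3-voxel-peak synthetic deformation
drops from 1.32 mm to 0.18 mm (1 mm voxels) — an 86 % reduction — after 500
optimization steps on one CPU. (λ = 1.5 here is the 48³-grid equivalent of
the default λ = 8 at clinical resolution; see `docs/methods.md`.)

The same pipeline is available from the shell:

```sh
gsdir make-fixture --out-dir case --shape 48 --magnitude 3 --seed 1
gsdir register --fixed case/fixed.nii.gz --moving case/moving.nii.gz \
    --out-dir run --iterations 500 --lambda 1.5 --batch-size 4096 --grid 8 --seed 1
gsdir evaluate --dvf run/dvf.nii.gz \
    --fixed-landmarks case/fixed_landmarks.txt \
    --moving-landmarks case/moving_landmarks.txt --out run/metrics
```

`register` writes the warped image, the DVF (mm, vector NIfTI), the optimized
primitive set (JSON), a per-iteration loss log and a manifest; `evaluate`
reports TRE, Dice, HD95 and the folding percentage (voxels with non-positive
Jacobian determinant).

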