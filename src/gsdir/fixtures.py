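"""Synthetic registration problems with exact ground truth.

Ground-truth deformations are generated by the package's own representation: a
random primitive set with small rotations/translations, evaluated through the
blending module, gives a smooth known displacement field. The moving image is
a textured volume (random Gaussian blobs plus smoothed noise); the fixed image
is the moving image warped by the ground-truth field, so the field that
registers fixed->moving is exactly the generated one. Landmarks are random
interior points paired through the continuous field, and label maps are
thresholded blobs deformed with nearest-neighbour interpolation.

Texture randomness prevents trivial inversion while parameter/field recovery
stays well-posed. The generator does not emulate modality physics (CT HU
ranges, MR bias fields).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .blending import BlendConfig, blend_displacements
from .core_model import (
    CanonicalMap,
    DisplacementField,
    GaussianPrimitiveSet,
    Volume,
    init_grid_primitives,
)
from .image_io import LabelVolume, LandmarkSet, warp, warp_labels
from .metrics import njd

__all__ = ["SyntheticCase", "make_texture", "make_case"]


@dataclass
class SyntheticCase:
    fixed: Volume
    moving: Volume
    gt_dvf: DisplacementField
    fixed_landmarks: LandmarkSet
    moving_landmarks: LandmarkSet
    fixed_labels: LabelVolume
    moving_labels: LabelVolume
    gt_prims: GaussianPrimitiveSet
    seed: int


def make_texture(
    shape: tuple[int, int, int],
    n_blobs: int | None = None,
    smooth_sigma: float = 0.8,
    seed: int = 0,
    noise_level: float = 0.8,
) -> Volume:
    """Textured volume: random anisotropic Gaussian blobs plus smoothed noise.

    Blob widths span 1-4 voxels so the image carries intensity gradients at
    the scale of the deformations being recovered; without contrast at that
    scale, sub-voxel registration is ill-posed for any similarity measure.
    ``n_blobs`` defaults to a fixed density (400 blobs per 48^3 voxels).

    Regenerated (up to 10 attempts) until every 8^3 block has nonzero
    intensity variance, so NCC has signal everywhere. ``n_blobs=0`` with
    ``noise_level=0`` yields a constant volume for degenerate-similarity tests.
    """
    shape = tuple(int(n) for n in shape)
    if n_blobs is None:
        n_blobs = max(20, round(400 * float(np.prod(shape)) / 48**3))
    rng = np.random.default_rng(seed)
    for _ in range(10):
        vol = np.zeros(shape)
        grid = np.stack(
            np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"),
            axis=-1,
        )
        for _b in range(n_blobs):
            centre = rng.uniform(0, np.asarray(shape) - 1)
            width = rng.uniform(1.0, 4.0, size=3)
            amp = rng.uniform(0.5, 2.0)
            d2 = (((grid - centre) / width) ** 2).sum(-1)
            vol += amp * np.exp(-0.5 * d2)
        if noise_level > 0:
            vol += noise_level * ndimage.gaussian_filter(
                rng.standard_normal(shape), smooth_sigma
            )
        if n_blobs == 0 and noise_level == 0:
            return Volume(vol)
        if _blocks_have_variance(vol):
            return Volume(vol)
    return Volume(vol)  # best effort; variance check is advisory for tiny shapes


def _blocks_have_variance(vol: np.ndarray, block: int = 8, floor: float = 1e-12) -> bool:
    nx, ny, nz = vol.shape
    for i in range(0, nx, block):
        for j in range(0, ny, block):
            for k in range(0, nz, block):
                if vol[i : i + block, j : j + block, k : k + block].var() <= floor:
                    return False
    return True


def _random_gt_prims(
    magnitude_canon: float,
    rng: np.random.Generator,
    grid: tuple[int, int, int],
    eval_points: np.ndarray,
    half_extent: np.ndarray,
    magnitude_vox: float,
    blend_cfg: BlendConfig,
) -> GaussianPrimitiveSet:
    """Random primitive set whose blended field peaks at ``magnitude_vox``.

    Node translations are spatially correlated (white noise smoothed over the
    lattice, one-node sigma): anatomical motion is dominated by bulk,
    low-frequency components with local variation, and uncorrelated node
    motions would produce an unrealistically rough field. Small rotations are
    added; both blocks are rescaled (fixed-point, 3 passes) so the maximum
    blended displacement magnitude over ``eval_points`` equals the requested
    voxel magnitude.
    """
    prims = init_grid_primitives([grid])
    n = prims.n
    t_raw = rng.standard_normal(tuple(grid) + (3,))
    t_raw = ndimage.gaussian_filter(t_raw, sigma=(1.0, 1.0, 1.0, 0.0), mode="nearest")
    prims.t[:] = t_raw.reshape(n, 3)
    angle = rng.standard_normal(n)
    angle *= 0.2 * magnitude_canon / max(np.abs(angle).max(), 1e-12)
    axis = rng.standard_normal((n, 3))
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    for _ in range(3):
        prims.r[:, 0] = np.cos(angle / 2)
        prims.r[:, 1:] = np.sin(angle / 2)[:, None] * axis
        phi = blend_displacements(prims, eval_points, blend_cfg).displacement
        peak = np.linalg.norm(phi * half_extent, axis=1).max()
        c = magnitude_vox / max(peak, 1e-12)
        prims.t *= c
        angle *= c
    return prims


def make_case(
    shape: tuple[int, int, int] = (48, 48, 48),
    deform_magnitude_vox: float = 3.0,
    n_prims: tuple[int, int, int] = (4, 4, 4),
    seed: int = 0,
    n_landmarks: int = 50,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> SyntheticCase:
    """A complete synthetic registration case with exact ground truth.

    ``deform_magnitude_vox`` bounds the generating translations (in voxels;
    keep it below shape/8 so the map stays diffeomorphic). The generated field
    is rejected and redrawn if it folds (non-zero NJD), up to 10 attempts.
    """
    shape = tuple(int(n) for n in shape)
    if deform_magnitude_vox > min(shape) / 8:
        raise ValueError("deform_magnitude_vox too large for this volume")
    cmap = CanonicalMap(shape)
    magnitude_canon = float(
        deform_magnitude_vox / cmap.half_extent.min()
    )

    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = cmap.voxel_to_canonical(idx)
    cfg = BlendConfig(K=min(8, int(np.prod(n_prims))))
    for attempt in range(10):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        gt_prims = _random_gt_prims(
            magnitude_canon, rng, n_prims, pts, cmap.half_extent,
            deform_magnitude_vox, cfg,
        )
        if deform_magnitude_vox == 0:
            gt_prims.t[:] = 0.0
            gt_prims.r[:] = [1.0, 0.0, 0.0, 0.0]
        phi = blend_displacements(gt_prims, pts, cfg).displacement
        gt_dvf = DisplacementField(phi.reshape(tuple(shape) + (3,)))
        if njd(gt_dvf) == 0.0:
            break
    else:
        raise RuntimeError(
            "could not generate a fold-free deformation; reduce deform_magnitude_vox"
        )

    moving = make_texture(shape, seed=seed)
    moving = Volume(moving.data, spacing=spacing)
    fixed = warp(moving, gt_dvf)
    fixed = Volume(fixed.data, spacing=spacing)

    # paired landmarks: p_m = p_f + phi(p_f), phi evaluated exactly (continuous)
    margin = max(2.0, deform_magnitude_vox + 1.0)
    p_f = rng.uniform(margin, np.asarray(shape) - 1 - margin, size=(n_landmarks, 3))
    phi_lm = blend_displacements(gt_prims, cmap.voxel_to_canonical(p_f), cfg).displacement
    p_m = p_f + cmap.canonical_vec_to_voxel(phi_lm)

    # labels: thresholded smooth blobs on the moving grid, NN-deformed to fixed
    lbl_field = ndimage.gaussian_filter(
        np.random.default_rng(seed + 1).standard_normal(shape), 6.0
    )
    q1, q2 = np.quantile(lbl_field, [0.6, 0.85])
    moving_lab = np.zeros(shape, dtype=np.int32)
    moving_lab[lbl_field > q1] = 1
    moving_lab[lbl_field > q2] = 2
    moving_labels = LabelVolume(moving_lab, spacing=spacing)
    fixed_labels = warp_labels(moving_labels, gt_dvf)

    return SyntheticCase(
        fixed=fixed,
        moving=moving,
        gt_dvf=gt_dvf,
        fixed_landmarks=LandmarkSet(p_f),
        moving_landmarks=LandmarkSet(p_m),
        fixed_labels=fixed_labels,
        moving_labels=moving_labels,
        gt_prims=gt_prims,
        seed=seed,
    )
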