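"""Registration loss: mini-batch negative NCC plus mini-batch total variation.

The full objective is ``L = Ls + lambda * Lr``. Ls is the negative normalized
cross-correlation between warped-moving and fixed intensities over a
mini-batch of B uniformly sampled voxels; because the batch is scattered
across the volume, NCC reduces to the (negated) Pearson correlation of the
two intensity vectors.

Dense total variation is incompatible with scattered mini-batches, so Lr is
estimated stochastically: each iteration draws B/(D+1) seed voxels (D = 3),
adds each seed's forward neighbour along the three orthogonal axes (about B
displacement evaluations in total), and averages the L1 norms of the forward
differences over the seeds. Differences are taken per one-voxel step on the
canonical grid without dividing by the step size; the step is absorbed into
lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossConfig",
    "SampleBatch",
    "sample_batch",
    "ncc_loss",
    "ncc_loss_grad",
    "tv_loss",
    "tv_loss_grad",
    "total_loss",
]

logger = logging.getLogger(__name__)


@dataclass
class LossConfig:
    lambda_reg: float = 8.0
    batch_size: int = 20_000
    dim: int = 3
    tv_norm: str = "l1"  # "l1" (anisotropic) or "l2" (isotropic)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.dim != 3:
            raise ValueError("only 3D volumes are supported")
        if self.batch_size < self.dim + 1:
            raise ValueError("batch_size must be >= dim + 1")
        if self.tv_norm not in ("l1", "l2"):
            raise ValueError("tv_norm must be 'l1' or 'l2'")


@dataclass
class SampleBatch:
    """Voxel indices of one mini-batch.

    sim_voxels   : (B, 3) similarity-term voxels
    tv_seeds     : (B // (D+1), 3) TV seed voxels
    tv_neighbors : (B // (D+1), 3, 3) each seed's forward neighbour per axis
    """

    sim_voxels: np.ndarray
    tv_seeds: np.ndarray
    tv_neighbors: np.ndarray


def _draw(rng: np.random.Generator, count: int, total: int) -> np.ndarray:
    if count > total:
        logger.warning("batch of %d exceeds %d voxels; sampling with replacement", count, total)
        return rng.integers(0, total, size=count)
    return rng.choice(total, size=count, replace=False)


def sample_batch(
    shape: tuple[int, int, int],
    config: LossConfig,
    rng: np.random.Generator,
) -> SampleBatch:
    """Draw the similarity batch and the TV seed/neighbour batch.

    Similarity voxels are uniform over the full grid; TV seeds are uniform
    over the sub-grid whose three forward neighbours stay in bounds. Both
    draws are without replacement (falling back to replacement only if the
    request exceeds the voxel count) and deterministic under a seeded ``rng``.
    """
    shape_arr = np.asarray(shape, dtype=int)
    if np.any(shape_arr < 2):
        raise ValueError("image shape must be >= 2 per axis")
    B, D = config.batch_size, config.dim

    flat = _draw(rng, B, int(shape_arr.prod()))
    sim = np.stack(np.unravel_index(flat, tuple(shape_arr)), axis=1)

    inner = shape_arr - 1  # seeds need one spare voxel per axis
    n_seeds = B // (D + 1)
    flat_s = _draw(rng, n_seeds, int(inner.prod()))
    seeds = np.stack(np.unravel_index(flat_s, tuple(inner)), axis=1)
    nbrs = seeds[:, None, :] + np.eye(3, dtype=int)[None, :, :]
    return SampleBatch(sim_voxels=sim, tv_seeds=seeds, tv_neighbors=nbrs)


def ncc_loss(warped_vals: np.ndarray, fixed_vals: np.ndarray) -> float:
    """Negative Pearson correlation of the two intensity batches, in [-1, 1].

    Invariant to positive affine rescaling of either argument. Returns 0.0
    when either side has zero variance (no similarity signal).
    """
    loss, _ = ncc_loss_grad(warped_vals, fixed_vals)
    return loss


def ncc_loss_grad(
    warped_vals: np.ndarray, fixed_vals: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss plus its analytic gradient w.r.t. the warped intensities."""
    w = np.asarray(warped_vals, dtype=float).ravel()
    f = np.asarray(fixed_vals, dtype=float).ravel()
    if w.shape != f.shape or w.size < 2:
        raise ValueError("batches must share a length of >= 2")
    if not (np.isfinite(w).all() and np.isfinite(f).all()):
        raise ValueError("NCC input contains NaN/inf")
    wc = w - w.mean()
    fc = f - f.mean()
    nw = np.linalg.norm(wc)
    nf = np.linalg.norm(fc)
    if nw == 0.0 or nf == 0.0:
        logger.warning("zero-variance batch in NCC; returning 0")
        return 0.0, np.zeros_like(w)
    corr = float(wc @ fc / (nw * nf))
    # d corr / d w (centring terms vanish because fc, wc are zero-mean)
    grad = -(fc / (nw * nf) - corr * wc / (nw * nw))
    return -corr, grad


def tv_loss(dvf_at, batch: SampleBatch, tv_norm: str = "l1") -> float:
    """Mini-batch TV: mean over seeds of the summed forward-difference norms.

    ``dvf_at`` maps (M, 3) voxel indices to (M, 3) displacements (canonical
    units on the canonical grid).
    """
    phi_seed = np.asarray(dvf_at(batch.tv_seeds), dtype=float)
    phi_nbr = np.asarray(dvf_at(batch.tv_neighbors.reshape(-1, 3)), dtype=float)
    diff = phi_nbr.reshape(phi_seed.shape[0], 3, 3) - phi_seed[:, None, :]
    return _tv_reduce(diff, tv_norm)


def _tv_reduce(diff: np.ndarray, tv_norm: str) -> float:
    if tv_norm == "l1":
        per_seed = np.abs(diff).sum(axis=(1, 2))
    else:
        per_seed = np.linalg.norm(diff, axis=2).sum(axis=1)
    return float(per_seed.mean())


def tv_loss_grad(
    phi_seed: np.ndarray, phi_nbr: np.ndarray, tv_norm: str = "l1"
) -> tuple[float, np.ndarray, np.ndarray]:
    """TV value plus gradients w.r.t. the evaluated displacements.

    ``phi_seed`` is (S, 3); ``phi_nbr`` is (S, 3, 3) (seed, axis, component).
    Returns ``(value, g_seed, g_nbr)`` with matching shapes.
    """
    diff = phi_nbr - phi_seed[:, None, :]
    S = phi_seed.shape[0]
    if tv_norm == "l1":
        g_diff = np.sign(diff) / S
    else:
        norms = np.linalg.norm(diff, axis=2, keepdims=True)
        g_diff = np.where(norms > 0, diff / np.where(norms == 0, 1.0, norms), 0.0) / S
    return _tv_reduce(diff, tv_norm), -g_diff.sum(axis=1), g_diff


def total_loss(sim: float, reg: float, config: LossConfig) -> float:
    """L = Ls + lambda * Lr."""
    if not (np.isfinite(sim) and np.isfinite(reg)):
        raise ValueError("non-finite loss terms")
    return float(sim + config.lambda_reg * reg)
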