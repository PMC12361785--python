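"""Case-specific optimization loop for the Gaussian-primitive registration.

Each iteration: draw a mini-batch, blend displacements at the batch voxels,
sample the moving image at the displaced positions, evaluate
``L = Ls + lambda * Lr`` and take one Adam step on all five parameter blocks
(centres, log-scales, orientation quaternions, rigid-rotation quaternions,
translations). The learning rate ramps up linearly over a warm-up phase and
then decays with cosine annealing. Adaptive density control periodically
splits/clones primitives that accumulate large positional gradients and prunes
primitives whose blending weight never rises above a floor.

Gradients are analytic (see :mod:`gsdir.blending`) and Adam is implemented
here directly, so runs are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .blending import BlendConfig, blend_backward, blend_forward, build_trees
from .core_model import (
    CanonicalMap,
    DisplacementField,
    GaussianPrimitiveSet,
    Volume,
    init_grid_primitives,
)
from .image_io import sample_with_grad
from .objective import LossConfig, ncc_loss_grad, sample_batch, total_loss, tv_loss_grad

__all__ = ["RegistrationConfig", "OptState", "lr_at", "density_control", "register",
           "evaluate_dense_dvf"]

logger = logging.getLogger(__name__)

PARAM_BLOCKS = ("mu", "log_s", "q", "r", "t")


@dataclass
class RegistrationConfig:
    """All hyperparameters of the optimization.

    Defaults follow the method's standard operating point: 2000 iterations of
    Adam on mini-batches of B = 20,000 voxels with regularization weight
    lambda = 8, primitives on two lattices (coarse 6^3, fine 12^3) blended
    with K = 8 neighbours per scale.
    """

    iterations: int = 2000
    warmup_iters: int = 100
    base_lr: dict = field(
        default_factory=lambda: {
            "mu": 1e-2, "log_s": 5e-3, "q": 1e-2, "r": 1e-2, "t": 1e-2,
        }
    )
    min_lr_frac: float = 0.01
    K: int = 8
    grids: tuple = ((6, 6, 6), (12, 12, 12))
    lambda_reg: float = 8.0
    batch_size: int = 20_000
    tv_norm: str = "l1"
    knn_refresh: int = 1          # rebuild neighbour lists every this many iters
    # density control
    density_control: bool = True
    dc_interval: int = 200
    dc_start: int = 200
    dc_stop: int = 1500
    dc_grad_threshold: float | None = None  # None: 95th percentile at first call
    dc_prune_weight: float = 1e-4
    dc_max_factor: float = 4.0
    seed: int = 0
    dense_chunk: int = 65_536

    def __post_init__(self) -> None:
        if not (self.iterations >= self.warmup_iters >= 0):
            raise ValueError("need iterations >= warmup_iters >= 0")
        if any(lr <= 0 for lr in self.base_lr.values()):
            raise ValueError("learning rates must be > 0")
        if self.dc_prune_weight < 0 or (
            self.dc_grad_threshold is not None and self.dc_grad_threshold < 0
        ):
            raise ValueError("density-control thresholds must be >= 0")

    def loss_config(self) -> LossConfig:
        return LossConfig(
            lambda_reg=self.lambda_reg, batch_size=self.batch_size,
            tv_norm=self.tv_norm, seed=self.seed,
        )

    def blend_config(self) -> BlendConfig:
        return BlendConfig(K=self.K)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OptState:
    """Bookkeeping: loss history and density-control statistics."""

    iteration: int = 0
    loss_history: list = field(default_factory=list)   # (total, sim, reg) rows
    prim_count_history: list = field(default_factory=list)
    grad_accum: np.ndarray | None = None    # accumulated |grad mu| per primitive
    grad_count: int = 0
    max_weight: np.ndarray | None = None    # max blend weight seen this interval
    dc_threshold: float | None = None

    def reset_interval(self, n: int) -> None:
        self.grad_accum = np.zeros(n)
        self.grad_count = 0
        self.max_weight = np.zeros(n)


def lr_at(iteration: int, config: RegistrationConfig) -> float:
    """Learning-rate multiplier: linear warm-up to 1, then cosine decay to
    ``min_lr_frac``."""
    if not 0 <= iteration < config.iterations:
        raise ValueError("iteration out of range")
    if config.warmup_iters > 0 and iteration < config.warmup_iters:
        return (iteration + 1) / config.warmup_iters
    span = config.iterations - config.warmup_iters
    p = (iteration - config.warmup_iters) / max(span - 1, 1)
    lo = config.min_lr_frac
    return lo + (1.0 - lo) * 0.5 * (1.0 + np.cos(np.pi * p))


class _Adam:
    """Minimal Adam with one slot per parameter block."""

    def __init__(self, shapes: dict[str, tuple], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.step_count = 0

    def step(self, params: dict, grads: dict, lrs: dict) -> None:
        self.step_count += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.step_count
        bc2 = 1 - b2 ** self.step_count
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            params[k] -= lrs[k] * mhat / (np.sqrt(vhat) + self.eps)

    def extend_rows(self, keep: np.ndarray, n_new: int) -> None:
        """Keep optimizer state for surviving primitives, zeros for new ones."""
        for slot in (self.m, self.v):
            for k, arr in slot.items():
                kept = arr[keep]
                slot[k] = np.concatenate(
                    [kept, np.zeros((n_new,) + arr.shape[1:])]
                )


def density_control(
    prims: GaussianPrimitiveSet,
    state: OptState,
    config: RegistrationConfig,
    adam: _Adam | None = None,
) -> GaussianPrimitiveSet:
    """Split/clone high-gradient primitives; prune never-contributing ones.

    A primitive whose mean accumulated positional-gradient magnitude exceeds
    the threshold is densified: if its largest scale exceeds its lattice's
    node spacing it is split in two (centres offset +- one current scale along
    the dominant principal axis, scales halved), otherwise cloned in place. A
    primitive whose maximum blending weight over the interval stayed below the
    prune floor is removed, unless that would empty its scale. The total count
    is capped at ``dc_max_factor`` times the current count before control.
    """
    if state.grad_count == 0 or state.grad_accum is None:
        return prims
    mean_grad = state.grad_accum / state.grad_count
    if state.dc_threshold is None:
        thr = (
            config.dc_grad_threshold
            if config.dc_grad_threshold is not None
            else float(np.percentile(mean_grad, 95))
        )
        state.dc_threshold = thr
    thr = state.dc_threshold

    n = prims.n
    max_count = int(config.dc_max_factor * n)
    prune = state.max_weight < config.dc_prune_weight
    # never empty a scale
    for sc in prims.scales_present():
        idx = prims.scale_indices(int(sc))
        if prune[idx].all():
            logger.warning("pruning would empty scale %d; skipped", sc)
            prune[idx] = False
    keep = ~prune
    densify = np.flatnonzero((mean_grad > thr) & keep)

    s = prims.s
    Q = prims.orientation_matrices()
    new_rows: dict[str, list] = {k: [] for k in ("mu", "log_s", "q", "r", "t", "sid")}
    split_mask = np.zeros(n, dtype=bool)
    budget = max_count - int(keep.sum())
    for i in densify:
        if budget <= 0:
            break
        sid = int(prims.scale_id[i])
        lattice = (
            prims.lattice_spacing[sid]
            if sid < prims.lattice_spacing.size
            else float(s[i].max())
        )
        axis = int(np.argmax(s[i]))
        if s[i].max() > lattice:  # oversized: split into two smaller kernels
            offset = Q[i, :, axis] * s[i, axis]
            split_mask[i] = True
            for sign in (+1.0, -1.0):
                new_rows["mu"].append(prims.mu[i] + sign * offset)
                new_rows["log_s"].append(prims.log_s[i] - np.log(2.0))
                new_rows["q"].append(prims.q[i])
                new_rows["r"].append(prims.r[i])
                new_rows["t"].append(prims.t[i])
                new_rows["sid"].append(sid)
            budget -= 1  # one replaced by two
        else:  # clone in place
            new_rows["mu"].append(prims.mu[i].copy())
            new_rows["log_s"].append(prims.log_s[i].copy())
            new_rows["q"].append(prims.q[i].copy())
            new_rows["r"].append(prims.r[i].copy())
            new_rows["t"].append(prims.t[i].copy())
            new_rows["sid"].append(sid)
            budget -= 1

    keep &= ~split_mask
    n_new = len(new_rows["sid"])
    out = GaussianPrimitiveSet(
        mu=np.concatenate([prims.mu[keep]] + ([np.array(new_rows["mu"])] if n_new else [])),
        log_s=np.concatenate([prims.log_s[keep]] + ([np.array(new_rows["log_s"])] if n_new else [])),
        q=np.concatenate([prims.q[keep]] + ([np.array(new_rows["q"])] if n_new else [])),
        r=np.concatenate([prims.r[keep]] + ([np.array(new_rows["r"])] if n_new else [])),
        t=np.concatenate([prims.t[keep]] + ([np.array(new_rows["t"])] if n_new else [])),
        scale_id=np.concatenate(
            [prims.scale_id[keep]] + ([np.array(new_rows["sid"], dtype=int)] if n_new else [])
        ),
        lattice_spacing=prims.lattice_spacing.copy(),
    )
    if adam is not None:
        adam.extend_rows(keep, n_new)
    return out


def _params_dict(prims: GaussianPrimitiveSet) -> dict[str, np.ndarray]:
    return {"mu": prims.mu, "log_s": prims.log_s, "q": prims.q, "r": prims.r, "t": prims.t}


def evaluate_dense_dvf(
    prims: GaussianPrimitiveSet,
    shape: tuple[int, int, int],
    config: RegistrationConfig,
) -> DisplacementField:
    """Materialize the displacement field on the whole fixed grid, chunked to
    bound memory."""
    cmap = CanonicalMap(shape)
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = cmap.voxel_to_canonical(idx)
    bcfg = config.blend_config()
    out = np.empty_like(pts)
    for lo in range(0, pts.shape[0], config.dense_chunk):
        chunk = pts[lo : lo + config.dense_chunk]
        res, _ = blend_forward(prims, chunk, bcfg)
        out[lo : lo + config.dense_chunk] = res.displacement
    return DisplacementField(out.reshape(tuple(shape) + (3,)))


def register(
    fixed: Volume,
    moving: Volume,
    config: RegistrationConfig | None = None,
    prims: GaussianPrimitiveSet | None = None,
) -> tuple[GaussianPrimitiveSet, DisplacementField, OptState]:
    """Optimize a primitive set aligning ``moving`` to ``fixed``.

    Returns the final primitives, the dense displacement field on the fixed
    grid (canonical units) and the optimization state. Reproducible under a
    fixed ``config.seed``.
    """
    config = config or RegistrationConfig()
    if not np.allclose(fixed.spacing, moving.spacing):
        logger.warning(
            "fixed and moving spacing differ (%s vs %s)", fixed.spacing, moving.spacing
        )
    rng = np.random.default_rng(config.seed)
    if prims is None:
        prims = init_grid_primitives([tuple(g) for g in config.grids], seed=config.seed)
    loss_cfg = config.loss_config()
    blend_cfg = config.blend_config()
    cmap = CanonicalMap(fixed.shape)
    state = OptState()
    state.reset_interval(prims.n)
    adam = _Adam({k: v.shape for k, v in _params_dict(prims).items()})
    fixed_flat = fixed.data
    trees = None

    for it in range(config.iterations):
        batch = sample_batch(fixed.shape, loss_cfg, rng)
        sim_pts = cmap.voxel_to_canonical(batch.sim_voxels)
        n_seeds = batch.tv_seeds.shape[0]
        tv_pts = cmap.voxel_to_canonical(
            np.concatenate([batch.tv_seeds, batch.tv_neighbors.reshape(-1, 3)])
        )
        pts = np.concatenate([sim_pts, tv_pts])

        # centres drift slowly; the KD-trees may be refreshed every few iters
        if trees is None or it % config.knn_refresh == 0:
            trees = build_trees(prims)
        result, caches = blend_forward(prims, pts, blend_cfg, trees)
        phi = result.displacement

        # similarity term
        B = sim_pts.shape[0]
        warped_pos = sim_pts + phi[:B]
        warped_vals, grad_pos = sample_with_grad(moving, warped_pos)
        fvals = fixed_flat[batch.sim_voxels[:, 0], batch.sim_voxels[:, 1], batch.sim_voxels[:, 2]]
        sim, g_warped = ncc_loss_grad(warped_vals, fvals)

        # regularization term
        phi_seed = phi[B : B + n_seeds]
        phi_nbr = phi[B + n_seeds :].reshape(n_seeds, 3, 3)
        reg, g_seed, g_nbr = tv_loss_grad(phi_seed, phi_nbr, config.tv_norm)

        loss = total_loss(sim, reg, loss_cfg)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at iteration {it}: {loss}")
        state.loss_history.append((loss, sim, reg))
        state.prim_count_history.append(prims.n)

        # upstream gradient at every evaluated displacement
        g_phi = np.concatenate([
            g_warped[:, None] * grad_pos,
            config.lambda_reg * g_seed,
            config.lambda_reg * g_nbr.reshape(-1, 3),
        ])
        grads = blend_backward(prims, caches, g_phi)

        # density-control statistics
        state.grad_accum += np.linalg.norm(grads["mu"], axis=1)
        state.grad_count += 1
        for sc, w in result.weights.items():
            np.maximum.at(state.max_weight, result.neighbor_idx[sc].ravel(), w.ravel())

        mult = lr_at(it, config)
        lrs = {k: config.base_lr[k] * mult for k in PARAM_BLOCKS}
        params = _params_dict(prims)
        adam.step(params, grads, lrs)

        if (
            config.density_control
            and config.dc_start <= it <= config.dc_stop
            and it > 0
            and it % config.dc_interval == 0
        ):
            prims = density_control(prims, state, config, adam)
            state.reset_interval(prims.n)
            trees = None
        state.iteration = it + 1

    dvf = evaluate_dense_dvf(prims, fixed.shape, config)
    return prims, dvf, state
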