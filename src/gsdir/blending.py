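"""Per-voxel displacements by blending local rigid deformations of nearby primitives.

For a query point ``x_j`` the K nearest primitives (Euclidean distance to the
centres, per lattice scale) are found; each contributes its rigid-transform
offset

    T_jk = R_k (x_j - mu_k) + mu_k + t_k - x_j

weighted by its normalized anisotropic Gaussian density at ``x_j``:

    w_hat_jk = (2 pi)^{-3/2} |Sigma_k|^{-1/2} exp(-1/2 (x_j-mu_k)^T Sigma_k^{-1} (x_j-mu_k))
    w_jk     = w_hat_jk / sum_k w_hat_jk

The per-scale blend is ``phi_j = sum_k w_jk T_jk``; with two lattice scales the
final displacement is the unweighted mean of the per-scale blends.

Everything is differentiable w.r.t. the five parameter blocks (mu, log_s, q,
r, t); the KNN index selection is treated as non-differentiable, mirroring the
truncated-kernel reading. The module provides both the forward evaluation and
the hand-derived reverse pass used by the optimizer (this package carries its
own gradients rather than relying on an autodiff framework).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core_model import GaussianPrimitiveSet, quat_to_rotmat, rotmat_quat_jacobian

__all__ = [
    "BlendConfig",
    "BlendResult",
    "knn",
    "blend_weights",
    "local_transform",
    "blend_displacements",
    "blend_forward",
    "blend_backward",
]

logger = logging.getLogger(__name__)

_LOG_NORM_3D = -1.5 * np.log(2.0 * np.pi)


@dataclass
class BlendConfig:
    """K: neighbours per scale; eps: floor added to the weight normalizer."""

    K: int = 8
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0.0 < self.eps <= 1e-6):
            raise ValueError("eps must lie in (0, 1e-6]")


@dataclass
class BlendResult:
    """Per-point blend: neighbour indices, weights and displacement.

    ``neighbor_idx``/``weights``/``raw_weights`` are dicts keyed by scale tag
    (each (M, K)); ``displacement`` is the (M, 3) scale-mean displacement.
    """

    neighbor_idx: dict[int, np.ndarray]
    weights: dict[int, np.ndarray]
    raw_weights: dict[int, np.ndarray]
    displacement: np.ndarray


def build_trees(prims: GaussianPrimitiveSet) -> dict[int, tuple[cKDTree, np.ndarray]]:
    """One KD-tree per lattice scale over the current centres."""
    return {
        int(sc): (cKDTree(prims.mu[prims.scale_indices(int(sc))]),
                  prims.scale_indices(int(sc)))
        for sc in prims.scales_present()
    }


def knn(
    prims: GaussianPrimitiveSet,
    points: np.ndarray,
    K: int,
    scale: int,
    tree: tuple[cKDTree, np.ndarray] | None = None,
) -> np.ndarray:
    """Indices (into the full set) of the K nearest same-scale centres.

    Distance is Euclidean to mu. Ties are broken toward the lower primitive
    index (cKDTree's ordering, with stable index mapping). ``tree`` optionally
    reuses a prebuilt KD-tree from :func:`build_trees` (the optimizer may
    refresh trees only every few iterations while centres drift slowly).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if tree is None:
        idx_scale = prims.scale_indices(scale)
        kdt = cKDTree(prims.mu[idx_scale])
    else:
        kdt, idx_scale = tree
    if K > idx_scale.size:
        raise ValueError(
            f"K={K} exceeds the {idx_scale.size} primitives at scale {scale}"
        )
    _, nbr = kdt.query(points, k=K)
    nbr = np.atleast_2d(nbr)
    if K == 1:
        nbr = nbr.reshape(-1, 1)
    return idx_scale[nbr]


def blend_weights(
    prims: GaussianPrimitiveSet,
    points: np.ndarray,
    neighbor_idx: np.ndarray,
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized and raw Gaussian-density weights of each point's neighbours.

    Returns ``(weights, raw_weights)`` with shapes (M, K). The densities
    include the full (2 pi)^{3/2} |Sigma|^{1/2} normalizer, which matters for
    anisotropic mixtures. Normalization runs in log space; if a point's
    densities are all non-finite the weights fall back to uniform 1/K.
    """
    cache = _weights_forward(prims, np.atleast_2d(points), np.atleast_2d(neighbor_idx), eps)
    return cache["w"], np.exp(cache["log_what"])


def _weights_forward(
    prims: GaussianPrimitiveSet,
    points: np.ndarray,
    nbr: np.ndarray,
    eps: float,
) -> dict:
    """Forward pass of the weight computation, retaining the backward cache."""
    s = prims.s[nbr]                                  # (M, K, 3)
    Q = quat_to_rotmat(prims.q)[nbr]                  # (M, K, 3, 3)
    d = points[:, None, :] - prims.mu[nbr]            # (M, K, 3)
    u = np.einsum("mkab,mka->mkb", Q, d)              # Q^T d, principal frame
    z = u / s
    log_what = _LOG_NORM_3D - np.log(s).sum(-1) - 0.5 * (z * z).sum(-1)
    finite = np.isfinite(log_what)
    bad = ~finite.any(axis=1)
    if bad.any():
        logger.warning(
            "all raw blending weights degenerate for %d point(s); using uniform", bad.sum()
        )
        log_what = np.where(finite, log_what, -np.inf)
        log_what[bad] = 0.0
    shift = log_what.max(axis=1, keepdims=True)
    e = np.exp(log_what - shift)
    denom = e.sum(axis=1, keepdims=True) + eps
    w = e / denom
    return {
        "points": points, "nbr": nbr, "s": s, "Q": Q, "d": d, "u": u, "z": z,
        "log_what": log_what, "w": w,
    }


def local_transform(
    prims: GaussianPrimitiveSet,
    k: int,
    points: np.ndarray,
) -> np.ndarray:
    """Rigid transform of primitive k applied about its own centre:
    ``x_hat = R_k (x - mu_k) + mu_k + t_k``."""
    if not 0 <= k < prims.n:
        raise IndexError(f"primitive index {k} out of range")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    R = quat_to_rotmat(prims.r[k])
    return (points - prims.mu[k]) @ R.T + prims.mu[k] + prims.t[k]


def _scale_forward(
    prims: GaussianPrimitiveSet,
    points: np.ndarray,
    config: BlendConfig,
    scale: int,
    tree: tuple | None = None,
) -> dict:
    nbr = knn(prims, points, config.K, scale, tree=tree)
    cache = _weights_forward(prims, points, nbr, config.eps)
    R = quat_to_rotmat(prims.r)[nbr]                   # (M, K, 3, 3)
    d = cache["d"]
    # T_jk = R_k d + t_k - d  with d = x - mu_k
    T = np.einsum("mkab,mkb->mka", R, d) - d + prims.t[nbr]
    phi = np.einsum("mk,mka->ma", cache["w"], T)
    cache.update({"R": R, "T": T, "phi": phi, "scale": scale})
    return cache


def blend_forward(
    prims: GaussianPrimitiveSet,
    points: np.ndarray,
    config: BlendConfig,
    trees: dict[int, tuple] | None = None,
) -> tuple[BlendResult, list[dict]]:
    """Blend displacements at ``points`` and keep the caches for the reverse pass.

    ``trees`` optionally reuses prebuilt per-scale KD-trees.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    scales = prims.scales_present()
    caches = [
        _scale_forward(
            prims, points, config, int(sc),
            None if trees is None else trees[int(sc)],
        )
        for sc in scales
    ]
    phi = np.mean([c["phi"] for c in caches], axis=0)
    result = BlendResult(
        neighbor_idx={c["scale"]: c["nbr"] for c in caches},
        weights={c["scale"]: c["w"] for c in caches},
        raw_weights={c["scale"]: np.exp(c["log_what"]) for c in caches},
        displacement=phi,
    )
    return result, caches


def blend_displacements(
    prims: GaussianPrimitiveSet,
    points: np.ndarray,
    config: BlendConfig | None = None,
) -> BlendResult:
    """Displacement at each point: per-scale density-weighted blends, averaged
    over the lattice scales present."""
    result, _ = blend_forward(prims, points, config or BlendConfig())
    return result


def blend_backward(
    prims: GaussianPrimitiveSet,
    caches: list[dict],
    g_phi: np.ndarray,
) -> dict[str, np.ndarray]:
    """Reverse pass: gradients of ``sum(g_phi * phi)`` w.r.t. all parameter blocks.

    ``g_phi`` is (M, 3), the upstream gradient at the blended (scale-mean)
    displacements. Returns dict with arrays shaped like mu, log_s, q, r, t.
    KNN indices are constants of the pass.
    """
    n = prims.n
    grads = {
        "mu": np.zeros((n, 3)),
        "log_s": np.zeros((n, 3)),
        "q": np.zeros((n, 4)),
        "r": np.zeros((n, 4)),
        "t": np.zeros((n, 3)),
    }
    n_scales = len(caches)
    Jq = rotmat_quat_jacobian(prims.q)  # (N, 4, 3, 3)
    Jr = rotmat_quat_jacobian(prims.r)
    for cache in caches:
        g = g_phi / n_scales                                  # (M, 3)
        nbr, w, T, R = cache["nbr"], cache["w"], cache["T"], cache["R"]
        d, z, s, Q = cache["d"], cache["z"], cache["s"], cache["Q"]
        flat = nbr.ravel()

        # --- transform path: phi = sum_k w_k T_k
        gT = w[..., None] * g[:, None, :]                     # (M, K, 3)
        np.add.at(grads["t"], flat, gT.reshape(-1, 3))
        # dT/dR: T = R d - d + t  ->  dL/dR_k += gT outer d
        gR = gT[..., :, None] * d[..., None, :]               # (M, K, 3, 3)
        gR_acc = np.zeros((n, 3, 3))
        np.add.at(gR_acc, flat, gR.reshape(-1, 3, 3))
        grads["r"] += np.einsum("nbij,nij->nb", Jr, gR_acc)
        # dT/dd = R - I, d = x - mu  ->  grad mu -= (R - I)^T gT
        g_d = np.einsum("mkab,mka->mkb", R, gT) - gT          # (R-I)^T gT
        np.add.at(grads["mu"], flat, -g_d.reshape(-1, 3))

        # --- weight path: softmax over log-densities a_k
        gw = np.einsum("ma,mka->mk", g, T)                    # dL/dw_k
        inner = (w * gw).sum(axis=1, keepdims=True)
        ga = w * (gw - inner)                                 # dL/d log_what_k
        # a = const - sum log s - 1/2 |z|^2, z = (Q^T d)/s
        # d a/d mu_k = Sigma^{-1} d = Q (z/s)
        Sinv_d = np.einsum("mkab,mkb->mka", Q, z / s)
        np.add.at(grads["mu"], flat, (ga[..., None] * Sinv_d).reshape(-1, 3))
        # d a/d log s = z^2 - 1
        np.add.at(grads["log_s"], flat, (ga[..., None] * (z * z - 1.0)).reshape(-1, 3))
        # d a/d Q[a, b] = -d_a z_b / s_b   (through u = Q^T d)
        gQ = -(ga[..., None, None]) * d[..., :, None] * (z / s)[..., None, :]
        gQ_acc = np.zeros((n, 3, 3))
        np.add.at(gQ_acc, flat, gQ.reshape(-1, 3, 3))
        grads["q"] += np.einsum("nbij,nij->nb", Jq, gQ_acc)
    return grads
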