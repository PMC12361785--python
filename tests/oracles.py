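"""Independent reference implementations used as test oracles.

Deliberately naive: per-point Python loops, scipy's quaternion conversion
(instead of the package's own), explicit covariance inverses and densities.
They share no code path with the vectorized implementation they check.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def rotmat(q_wxyz: np.ndarray) -> np.ndarray:
    """Quaternion (scalar-first) to rotation matrix via scipy (scalar-last)."""
    w, x, y, z = q_wxyz
    return Rotation.from_quat([x, y, z, w]).as_matrix()


def naive_covariance(s: np.ndarray, q_wxyz: np.ndarray) -> np.ndarray:
    Q = rotmat(q_wxyz)
    return Q @ np.diag(np.asarray(s) ** 2) @ Q.T


def naive_knn(mu: np.ndarray, point: np.ndarray, K: int) -> list[int]:
    d = [(float(np.linalg.norm(point - m)), i) for i, m in enumerate(mu)]
    d.sort()  # ties broken by index
    return [i for _, i in d[:K]]


def naive_blend_point(prims, point: np.ndarray, K: int) -> np.ndarray:
    """Scalar re-implementation of the density-weighted rigid blend at one point."""
    per_scale = []
    for sc in np.unique(prims.scale_id):
        idx = np.flatnonzero(prims.scale_id == sc)
        nbr = [idx[i] for i in naive_knn(prims.mu[idx], point, K)]
        what = []
        for k in nbr:
            sigma = naive_covariance(np.exp(prims.log_s[k]), prims.q[k] / np.linalg.norm(prims.q[k]))
            diff = point - prims.mu[k]
            dens = (
                (2 * np.pi) ** -1.5
                * np.linalg.det(sigma) ** -0.5
                * np.exp(-0.5 * diff @ np.linalg.inv(sigma) @ diff)
            )
            what.append(dens)
        wsum = sum(what)
        phi = np.zeros(3)
        for k, wk in zip(nbr, what):
            R = rotmat(prims.r[k] / np.linalg.norm(prims.r[k]))
            xhat = R @ (point - prims.mu[k]) + prims.mu[k] + prims.t[k]
            phi += (wk / wsum) * (xhat - point)
        per_scale.append(phi)
    return np.mean(per_scale, axis=0)


def naive_hd95(mask_a: np.ndarray, mask_b: np.ndarray, spacing) -> float:
    """Brute-force symmetric 95th-percentile surface distance."""
    spacing = np.asarray(spacing, dtype=float)

    def surface(mask):
        pts = []
        for p in np.argwhere(mask):
            for d in range(3):
                for off in (-1, 1):
                    q = p.copy()
                    q[d] += off
                    if (q < 0).any() or (q >= np.array(mask.shape)).any() or not mask[tuple(q)]:
                        pts.append(p)
                        break
                else:
                    continue
                break
        return np.array(pts, dtype=float)

    sa, sb = surface(mask_a), surface(mask_b)

    def directed(src, dst):
        dists = [np.linalg.norm((p - dst) * spacing, axis=1).min() for p in src]
        return np.percentile(dists, 95)

    return max(directed(sa, sb), directed(sb, sa))


def random_prims(rng: np.random.Generator, n: int, n_scales: int = 1, spread: float = 1.0):
    """Random anisotropic primitive set for property tests."""
    from gsdir.core_model import GaussianPrimitiveSet

    per = n // n_scales
    scale_id = np.repeat(np.arange(n_scales), per)
    n = scale_id.size
    q = rng.standard_normal((n, 4))
    r = np.tile([1.0, 0, 0, 0], (n, 1)) + 0.25 * rng.standard_normal((n, 4))
    return GaussianPrimitiveSet(
        mu=rng.uniform(-spread, spread, (n, 3)),
        log_s=rng.uniform(-1.5, 0.0, (n, 3)),
        q=q,
        r=r,
        t=rng.uniform(-0.2, 0.2, (n, 3)),
        scale_id=scale_id,
        lattice_spacing=np.full(n_scales, 0.5),
    )
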