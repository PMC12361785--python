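"""Gaussian-primitive deformation model: parameterization and coordinate conventions.

The displacement field is represented by a sparse set of mobile anisotropic 3D
Gaussian kernels. Each primitive ``G_i`` carries geometric parameters — a centre
``mu_i`` in the canonical cube [-1, 1]^3, per-axis scales ``s_i`` and an
orientation quaternion ``q_i`` that together build the covariance
``Sigma_i = Q_i S_i S_i^T Q_i^T`` — plus a local rigid deformation: a rotation
quaternion ``r_i`` and a translation ``t_i``. A voxel's displacement is the
Gaussian-density-weighted blend of its neighbours' rigid-transform offsets
(see :mod:`gsdir.blending`).

All model computations happen in canonical coordinates: the fixed image's voxel
grid is mapped per-axis onto [-1, 1] (index 0 -> -1, index n-1 -> +1).
Anisotropic voxel spacing enters only when converting displacements to
millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Volume",
    "CanonicalMap",
    "GaussianPrimitiveSet",
    "DisplacementField",
    "init_grid_primitives",
    "covariance",
    "quat_normalize",
    "quat_to_rotmat",
    "rotmat_quat_jacobian",
    "IDENTITY_QUAT",
]

IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])


class InvalidConfigurationError(ValueError):
    """Raised when a model is constructed with inconsistent settings."""


# ---------------------------------------------------------------------------
# quaternion utilities (scalar-first convention: (w, x, y, z))
# ---------------------------------------------------------------------------

def quat_normalize(q: np.ndarray) -> np.ndarray:
    """Return unit quaternions; input (..., 4), scalar-first."""
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("zero quaternion cannot be normalized")
    return q / norm


def quat_to_rotmat(q: np.ndarray) -> np.ndarray:
    """Proper rotation matrices from (possibly unnormalized) quaternions.

    Parameters
    ----------
    q : (..., 4) array, scalar-first. Normalized internally, so the map is
        invariant to positive rescaling of the raw parameter.

    Returns
    -------
    (..., 3, 3) rotation matrices with det = +1.
    """
    q = quat_normalize(q)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def _rotmat_jacobian_unit(q: np.ndarray) -> np.ndarray:
    """d(R)/d(q) for a UNIT quaternion q, treating the four entries as free.

    Returns (..., 4, 3, 3): derivative of each matrix entry w.r.t. each
    quaternion component.
    """
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    zero = np.zeros_like(w)
    J = np.empty(q.shape[:-1] + (4, 3, 3))
    # dR/dw
    J[..., 0, :, :] = 2 * np.stack(
        [
            np.stack([zero, -z, y], axis=-1),
            np.stack([z, zero, -x], axis=-1),
            np.stack([-y, x, zero], axis=-1),
        ],
        axis=-2,
    )
    # dR/dx
    J[..., 1, :, :] = 2 * np.stack(
        [
            np.stack([zero, y, z], axis=-1),
            np.stack([y, -2 * x, -w], axis=-1),
            np.stack([z, w, -2 * x], axis=-1),
        ],
        axis=-2,
    )
    # dR/dy
    J[..., 2, :, :] = 2 * np.stack(
        [
            np.stack([-2 * y, x, w], axis=-1),
            np.stack([x, zero, z], axis=-1),
            np.stack([-w, z, -2 * y], axis=-1),
        ],
        axis=-2,
    )
    # dR/dz
    J[..., 3, :, :] = 2 * np.stack(
        [
            np.stack([-2 * z, -w, x], axis=-1),
            np.stack([w, -2 * z, y], axis=-1),
            np.stack([x, y, zero], axis=-1),
        ],
        axis=-2,
    )
    return J


def rotmat_quat_jacobian(q_raw: np.ndarray) -> np.ndarray:
    """d(R)/d(q_raw) for the raw (unnormalized) quaternion parameter.

    Chains the unit-quaternion Jacobian through the normalization
    ``u = q/|q|``; returns (..., 4, 3, 3).
    """
    q_raw = np.asarray(q_raw, dtype=float)
    norm = np.linalg.norm(q_raw, axis=-1, keepdims=True)
    u = q_raw / norm
    Ju = _rotmat_jacobian_unit(u)  # (..., 4, 3, 3) w.r.t. unit components
    # du_a/dq_b = (delta_ab - u_a u_b)/|q|
    eye = np.eye(4)
    P = (eye - u[..., :, None] * u[..., None, :]) / norm[..., None]
    # J_raw[b] = sum_a du_a/dq_b * Ju[a]
    return np.einsum("...ab,...aij->...bij", P, Ju)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and origin metadata.

    ``data`` axes follow index order (axis 0, 1, 2); ``spacing``/``origin``
    entries align with those axes, in mm.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"volume shape must be positive, got {self.data.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if np.isnan(self.data).any():
            raise ValueError("volume data contains NaN")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class CanonicalMap:
    """Affine map between a voxel grid and the canonical cube [-1, 1]^3.

    Index 0 maps to -1 and index n-1 to +1 independently per axis. The
    Jacobian of voxel -> canonical is diag(2/(n-1)); mm conversion additionally
    multiplies by voxel spacing.
    """

    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)  # type: ignore[assignment]
        if len(self.shape) != 3:
            raise ValueError("canonical map requires a 3-axis shape")
        if any(n < 2 for n in self.shape):
            raise ValueError(f"degenerate canonical map: axis of length < 2 in {self.shape}")

    @property
    def half_extent(self) -> np.ndarray:
        """(n-1)/2 per axis: voxels per canonical unit."""
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    def voxel_to_canonical(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx / self.half_extent - 1.0

    def canonical_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts + 1.0) * self.half_extent

    def canonical_vec_to_voxel(self, vec: np.ndarray) -> np.ndarray:
        """Convert displacement vectors from canonical units to voxel units."""
        return np.asarray(vec, dtype=float) * self.half_extent

    def voxel_vec_to_canonical(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec, dtype=float) / self.half_extent

    def canonical_vec_to_mm(self, vec: np.ndarray, spacing: np.ndarray) -> np.ndarray:
        """Displacement vectors canonical -> mm: scale by (n-1)/2 then spacing."""
        return self.canonical_vec_to_voxel(vec) * np.asarray(spacing, dtype=float)


def voxel_to_canonical(cmap: CanonicalMap, idx: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`CanonicalMap.voxel_to_canonical`."""
    return cmap.voxel_to_canonical(idx)


def canonical_to_mm(cmap: CanonicalMap, spacing: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`CanonicalMap.canonical_vec_to_mm`."""
    return cmap.canonical_vec_to_mm(vec, spacing)


@dataclass
class GaussianPrimitiveSet:
    """Learnable primitives: centres, scales, orientations, local rigid motions.

    Fields (leading dimension N):
      mu      : (N, 3) centres, canonical coordinates
      log_s   : (N, 3) log-scales; s = exp(log_s) keeps Sigma positive definite
      q       : (N, 4) orientation quaternion (builds covariance rotation Q)
      r       : (N, 4) local-rotation quaternion (builds rigid rotation R)
      t       : (N, 3) local translation, canonical units
      scale_id: (N,) integer tag assigning each primitive to one of the
                (at most two) lattice scales
      lattice_spacing: per-scale canonical node spacing recorded at init;
                used by density control's split rule
    """

    mu: np.ndarray
    log_s: np.ndarray
    q: np.ndarray
    r: np.ndarray
    t: np.ndarray
    scale_id: np.ndarray
    lattice_spacing: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.log_s = np.atleast_2d(np.asarray(self.log_s, dtype=float))
        self.q = np.atleast_2d(np.asarray(self.q, dtype=float))
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        self.t = np.atleast_2d(np.asarray(self.t, dtype=float))
        self.scale_id = np.atleast_1d(np.asarray(self.scale_id, dtype=int))
        self.lattice_spacing = np.atleast_1d(np.asarray(self.lattice_spacing, dtype=float))
        n = self.mu.shape[0]
        if n < 1:
            raise ValueError("primitive set must contain at least one primitive")
        for name, arr, cols in (
            ("mu", self.mu, 3),
            ("log_s", self.log_s, 3),
            ("q", self.q, 4),
            ("r", self.r, 4),
            ("t", self.t, 3),
        ):
            if arr.shape != (n, cols):
                raise ValueError(f"{name} must have shape ({n}, {cols}), got {arr.shape}")
        if self.scale_id.shape != (n,):
            raise ValueError("scale_id must align with the primitive count")

    @property
    def n(self) -> int:
        return self.mu.shape[0]

    @property
    def s(self) -> np.ndarray:
        return np.exp(self.log_s)

    def scales_present(self) -> np.ndarray:
        return np.unique(self.scale_id)

    def scale_indices(self, scale: int) -> np.ndarray:
        return np.flatnonzero(self.scale_id == scale)

    def orientation_matrices(self) -> np.ndarray:
        """(N, 3, 3) covariance rotations Q_i."""
        return quat_to_rotmat(self.q)

    def rigid_rotations(self) -> np.ndarray:
        """(N, 3, 3) local rigid rotations R_i."""
        return quat_to_rotmat(self.r)

    def copy(self) -> "GaussianPrimitiveSet":
        return GaussianPrimitiveSet(
            self.mu.copy(), self.log_s.copy(), self.q.copy(), self.r.copy(),
            self.t.copy(), self.scale_id.copy(), self.lattice_spacing.copy(),
        )

    # -- serialization (one JSON record per primitive) ----------------------
    def to_json(self) -> str:
        rows = [
            {
                "mu": self.mu[i].tolist(),
                "s": self.s[i].tolist(),
                "q": quat_normalize(self.q[i]).tolist(),
                "r": quat_normalize(self.r[i]).tolist(),
                "t": self.t[i].tolist(),
                "scale_id": int(self.scale_id[i]),
            }
            for i in range(self.n)
        ]
        return json.dumps(
            {"lattice_spacing": self.lattice_spacing.tolist(), "primitives": rows},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GaussianPrimitiveSet":
        obj = json.loads(text)
        rows = obj["primitives"]
        return cls(
            mu=np.array([p["mu"] for p in rows]),
            log_s=np.log(np.array([p["s"] for p in rows])),
            q=np.array([p["q"] for p in rows]),
            r=np.array([p["r"] for p in rows]),
            t=np.array([p["t"] for p in rows]),
            scale_id=np.array([p["scale_id"] for p in rows]),
            lattice_spacing=np.array(obj.get("lattice_spacing", [])),
        )


@dataclass
class DisplacementField:
    """Dense per-voxel displacement on the fixed image's grid, canonical units.

    The moving image is sampled at ``x + phi(x)``; ``values`` has shape
    fixed-shape + (3,).
    """

    values: np.ndarray
    frame: str = "fixed"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[-1] != 3:
            raise ValueError(f"DVF must have shape (nx, ny, nz, 3), got {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]  # type: ignore[return-value]

    def canonical_map(self) -> CanonicalMap:
        return CanonicalMap(self.shape)

    def to_voxel_units(self) -> np.ndarray:
        return self.canonical_map().canonical_vec_to_voxel(self.values)

    def to_mm(self, spacing: np.ndarray) -> np.ndarray:
        return self.canonical_map().canonical_vec_to_mm(self.values, spacing)

    @classmethod
    def from_mm(cls, values_mm: np.ndarray, spacing: np.ndarray) -> "DisplacementField":
        cmap = CanonicalMap(values_mm.shape[:3])
        vox = np.asarray(values_mm, dtype=float) / np.asarray(spacing, dtype=float)
        return cls(cmap.voxel_vec_to_canonical(vox))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def init_grid_primitives(
    shape_per_scale: list[tuple[int, int, int]],
    seed: int = 0,
) -> GaussianPrimitiveSet:
    """Place identity-initialized primitives on lattices spanning [-1, 1]^3.

    One lattice per scale (at most two). Centres are exactly the grid nodes;
    local deformations start at the identity (r = (1,0,0,0), t = 0) so the
    fresh set produces a zero displacement field. Initial per-axis scale is
    the same-scale node spacing, giving neighbouring kernels overlap at init.

    ``seed`` is accepted for interface stability; initialization is
    deterministic and does not consume randomness.
    """
    del seed
    if not shape_per_scale:
        raise InvalidConfigurationError("at least one lattice scale is required")
    if len(shape_per_scale) > 2:
        raise InvalidConfigurationError("at most two lattice scales are supported")
    mus, log_ss, scale_ids, spacings = [], [], [], []
    for sid, grid in enumerate(shape_per_scale):
        grid = tuple(int(g) for g in grid)
        if len(grid) != 3 or any(g < 2 for g in grid):
            raise InvalidConfigurationError(
                f"grid size must be >= 2 on every axis, got {grid}"
            )
        axes = [np.linspace(-1.0, 1.0, g) for g in grid]
        nodes = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        spacing = np.array([2.0 / (g - 1) for g in grid])
        mus.append(nodes)
        log_ss.append(np.tile(np.log(spacing), (nodes.shape[0], 1)))
        scale_ids.append(np.full(nodes.shape[0], sid, dtype=int))
        spacings.append(spacing.max())
    n = sum(m.shape[0] for m in mus)
    return GaussianPrimitiveSet(
        mu=np.concatenate(mus),
        log_s=np.concatenate(log_ss),
        q=np.tile(IDENTITY_QUAT, (n, 1)),
        r=np.tile(IDENTITY_QUAT, (n, 1)),
        t=np.zeros((n, 3)),
        scale_id=np.concatenate(scale_ids),
        lattice_spacing=np.array(spacings),
    )


def covariance(prims: GaussianPrimitiveSet, index: int) -> np.ndarray:
    """Covariance Sigma = Q S S^T Q^T of one primitive (3x3, symmetric PD)."""
    if not 0 <= index < prims.n:
        raise IndexError(f"primitive index {index} out of range [0, {prims.n})")
    Q = quat_to_rotmat(prims.q[index])
    S = np.diag(prims.s[index])
    sigma = Q @ S @ S.T @ Q.T
    return 0.5 * (sigma + sigma.T)  # enforce exact symmetry against round-off
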