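"""Volume, landmark and displacement-field I/O plus intensity sampling/warping.

Volumes are read and written with SimpleITK (NIfTI ``.nii``/``.nii.gz`` and
MetaImage ``.mha``/``.mhd``). In-memory arrays use index order (axis 0, 1, 2)
matching the ``spacing`` entries; SimpleITK's (x, y, z) metadata order is
reversed at the boundary.

Intensity sampling is trilinear with border clamping, in the volume's own
canonical [-1, 1]^3 coordinates, and exposes the analytic derivative with
respect to the sample position — the optimizer backpropagates the similarity
loss through it into the displacement model.

Displacement fields are stored as 3-component vector NIfTI images holding
millimetre displacements in the fixed-image frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core_model import CanonicalMap, DisplacementField, Volume

__all__ = [
    "VolumeFormatError",
    "LandmarkParseError",
    "LandmarkSet",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "sample",
    "sample_with_grad",
    "warp",
    "write_dvf",
    "read_dvf",
]

_KNOWN_EXTS = (".nii", ".nii.gz", ".mha", ".mhd")


class VolumeFormatError(ValueError):
    pass


class LandmarkParseError(ValueError):
    pass


@dataclass
class LandmarkSet:
    """Point landmarks in 0-based voxel coordinates (fractions allowed)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("landmarks must be an (M, 3) array")

    @property
    def m(self) -> int:
        return self.points.shape[0]


@dataclass
class LabelVolume:
    """Integer segmentation sharing its companion image's grid."""

    data: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must hold integers")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.data)


def _check_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in _KNOWN_EXTS):
        raise VolumeFormatError(
            f"unsupported volume format {path.name!r}; expected one of {_KNOWN_EXTS}"
        )


def read_volume(path: str | Path) -> Volume:
    """Read a 3D scalar NIfTI/MetaImage volume, preserving spacing and origin."""
    path = Path(path)
    _check_ext(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # corrupt header etc.
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise VolumeFormatError(
            f"{path} is not a 3D scalar volume "
            f"(dim={img.GetDimension()}, components={img.GetNumberOfComponentsPerPixel()})"
        )
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.nan_to_num(data, nan=0.0) if np.isnan(data).any() else data
    return Volume(
        data=np.asarray(data, dtype=float),
        spacing=np.asarray(img.GetSpacing())[::-1],
        origin=np.asarray(img.GetOrigin())[::-1],
    )


def write_volume(vol: Volume, path: str | Path) -> None:
    path = Path(path)
    _check_ext(path)
    img = sitk.GetImageFromArray(vol.data)
    img.SetSpacing(tuple(vol.spacing[::-1]))
    img.SetOrigin(tuple(vol.origin[::-1]))
    sitk.WriteImage(img, str(path))


def read_landmarks(path: str | Path, one_based: bool = True) -> LandmarkSet:
    """Parse whitespace-separated coordinate triples, one landmark per line.

    DIR-Lab convention stores 1-based voxel indices; set ``one_based=False``
    for files already 0-based. Blank lines are ignored; an empty file is an
    error.
    """
    path = Path(path)
    pts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 3:
                raise LandmarkParseError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(tokens)}"
                )
            try:
                pts.append([float(t) for t in tokens])
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: non-numeric token") from exc
    if not pts:
        raise LandmarkParseError(f"{path}: no landmarks found")
    points = np.asarray(pts, dtype=float)
    if one_based:
        points -= 1.0
    return LandmarkSet(points)


def write_landmarks(lms: LandmarkSet, path: str | Path, one_based: bool = True) -> None:
    pts = lms.points + 1.0 if one_based else lms.points
    np.savetxt(path, pts, fmt="%.6f")


# ---------------------------------------------------------------------------
# trilinear sampling
# ---------------------------------------------------------------------------

def sample_with_grad(
    vol: Volume, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear intensities and their derivative w.r.t. canonical position.

    ``points`` are (M, 3) coordinates in the volume's own canonical cube;
    out-of-cube queries are clamped to the border (the gradient is zero in a
    clamped direction). Returns ``(values (M,), grad (M, 3))`` where grad is
    d(value)/d(canonical coordinate).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.isfinite(points).all():
        raise ValueError("sample points must be finite")
    shape = np.asarray(vol.shape)
    cmap = CanonicalMap(vol.shape)
    v = cmap.canonical_to_voxel(points)
    v = np.clip(v, 0.0, shape - 1.0)
    i0 = np.floor(v).astype(int)
    i0 = np.minimum(i0, shape - 2)  # keep the 8-corner cell in bounds
    f = v - i0

    data = vol.data
    c = np.empty(points.shape[:1] + (2, 2, 2))
    for a in (0, 1):
        for b in (0, 1):
            for cc in (0, 1):
                c[:, a, b, cc] = data[i0[:, 0] + a, i0[:, 1] + b, i0[:, 2] + cc]

    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]
    # interpolate along axis 2, then 1, then 0
    c2 = c[..., 0] * (1 - fz)[:, None, None] + c[..., 1] * fz[:, None, None]
    c1 = c2[:, :, 0] * (1 - fy)[:, None] + c2[:, :, 1] * fy[:, None]
    vals = c1[:, 0] * (1 - fx) + c1[:, 1] * fx

    # derivative w.r.t. fractional voxel coordinate, per axis
    dx = c1[:, 1] - c1[:, 0]
    c1x = c2[:, 0] * (1 - fx)[:, None] + c2[:, 1] * fx[:, None]  # (M, 2) over y
    dy = c1x[:, 1] - c1x[:, 0]
    cxy = (
        c[:, 0] * (1 - fx)[:, None, None] + c[:, 1] * fx[:, None, None]
    )  # (M, 2, 2) over (y, z)
    cz = cxy[:, 0] * (1 - fy)[:, None] + cxy[:, 1] * fy[:, None]  # (M, 2) over z
    dz = cz[:, 1] - cz[:, 0]
    grad_vox = np.stack([dx, dy, dz], axis=1)

    # clamped queries: value constant, derivative zero along the clamped axis
    unclamped = (cmap.canonical_to_voxel(points) >= 0.0) & (
        cmap.canonical_to_voxel(points) <= (shape - 1.0)
    )
    grad_vox = np.where(unclamped, grad_vox, 0.0)
    return vals, grad_vox * cmap.half_extent  # chain voxel -> canonical


def sample(vol: Volume, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at canonical coordinates with border clamping."""
    vals, _ = sample_with_grad(vol, points)
    return vals


def warp(moving: Volume, dvf: DisplacementField) -> Volume:
    """Resample the moving image at ``x + phi(x)`` over the fixed grid.

    The zero field reproduces the moving image on a matching grid exactly
    (sampling at voxel centres is exact).
    """
    shape = dvf.shape
    cmap = CanonicalMap(shape)
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = cmap.voxel_to_canonical(idx) + dvf.values.reshape(-1, 3)
    vals = sample(moving, pts)
    return Volume(vals.reshape(shape), spacing=moving.spacing, origin=moving.origin)


def warp_labels(labels: LabelVolume, dvf: DisplacementField) -> LabelVolume:
    """Nearest-neighbour warp for categorical maps."""
    shape = dvf.shape
    cmap = CanonicalMap(shape)
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    v = cmap.canonical_to_voxel(cmap.voxel_to_canonical(idx) + dvf.values.reshape(-1, 3))
    v = np.rint(np.clip(v, 0, np.asarray(shape) - 1)).astype(int)
    out = labels.data[v[:, 0], v[:, 1], v[:, 2]].reshape(shape)
    return LabelVolume(out, spacing=labels.spacing)


def write_dvf(dvf: DisplacementField, spacing: np.ndarray, path: str | Path) -> None:
    """Write a DVF as a 3-component vector image, displacements in mm
    (fixed-image frame, component order matching the image's voxel axes)."""
    path = Path(path)
    _check_ext(path)
    mm = dvf.to_mm(spacing)
    img = sitk.GetImageFromArray(mm, isVector=True)
    img.SetSpacing(tuple(np.asarray(spacing, dtype=float)[::-1]))
    sitk.WriteImage(img, str(path))


def read_dvf(path: str | Path) -> tuple[DisplacementField, np.ndarray]:
    """Read a vector-image DVF; returns the field (canonical units) and spacing."""
    path = Path(path)
    _check_ext(path)
    img = sitk.ReadImage(str(path))
    if img.GetNumberOfComponentsPerPixel() != 3:
        raise VolumeFormatError(f"{path} is not a 3-component displacement field")
    mm = sitk.GetArrayFromImage(img)
    spacing = np.asarray(img.GetSpacing())[::-1]
    return DisplacementField.from_mm(mm, spacing), spacing
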