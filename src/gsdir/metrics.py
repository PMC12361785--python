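"""Registration quality metrics: TRE, DSC, HD95 and folding percentage (NJD).

TRE measures landmark alignment in mm; DSC and HD95 measure segmentation
overlap and boundary agreement; NJD is the percentage of voxels whose
deformation Jacobian determinant is non-positive, i.e. where the map folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_model import CanonicalMap, DisplacementField
from .image_io import LabelVolume, LandmarkSet

__all__ = ["MetricReport", "tre", "dice", "hd95", "njd", "interp_dvf_at"]

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    tre_mean: float | None = None
    tre_sd: float | None = None
    dsc_mean: float | None = None
    dsc_sd: float | None = None
    hd95_mean: float | None = None
    hd95_sd: float | None = None
    njd_pct: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def interp_dvf_at(dvf: DisplacementField, voxel_points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the field at fractional voxel positions,
    returned in canonical units (one call per component via map_coordinates)."""
    pts = np.atleast_2d(np.asarray(voxel_points, dtype=float)).T  # (3, M)
    comps = [
        ndimage.map_coordinates(dvf.values[..., c], pts, order=1, mode="nearest")
        for c in range(3)
    ]
    return np.stack(comps, axis=1)


def tre(
    fixed_lms: LandmarkSet,
    moving_lms: LandmarkSet,
    dvf: DisplacementField,
    spacing: np.ndarray,
) -> np.ndarray:
    """Per-landmark target registration errors in mm.

    Landmark i of the fixed set is displaced by the (trilinearly interpolated)
    field and compared against its moving-set correspondence:
    ``error_i = || (p_f,i + phi(p_f,i)) - p_m,i ||`` with all quantities in mm.
    """
    if fixed_lms.m != moving_lms.m:
        raise ValueError(
            f"landmark counts differ: {fixed_lms.m} vs {moving_lms.m}"
        )
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    cmap = dvf.canonical_map()
    phi_vox = cmap.canonical_vec_to_voxel(interp_dvf_at(dvf, fixed_lms.points))
    delta_vox = fixed_lms.points + phi_vox - moving_lms.points
    return np.linalg.norm(delta_vox * spacing, axis=1)


def dice(a: LabelVolume, b: LabelVolume) -> tuple[dict[int, float], float]:
    """Per-label and macro-mean Dice overlap, background (0) excluded.

    Labels present in either volume contribute; a label absent from both is
    skipped. DSC per label = 2|A n B| / (|A| + |B|).
    """
    if a.data.shape != b.data.shape:
        raise ValueError("label volumes must share a shape")
    labels = np.union1d(a.labels, b.labels)
    labels = labels[labels != 0]
    per_label: dict[int, float] = {}
    for lab in labels:
        ma = a.data == lab
        mb = b.data == lab
        denom = ma.sum() + mb.sum()
        if denom == 0:
            continue
        per_label[int(lab)] = 2.0 * np.logical_and(ma, mb).sum() / denom
    mean = float(np.mean(list(per_label.values()))) if per_label else float("nan")
    return per_label, mean


def _surface(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: in the mask with at least one 6-neighbour outside."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def _directed_p95(src_surf: np.ndarray, dst_surf: np.ndarray, spacing) -> float:
    dist_to_dst = ndimage.distance_transform_edt(~dst_surf, sampling=spacing)
    return float(np.percentile(dist_to_dst[src_surf], 95))


def hd95(
    a: LabelVolume, b: LabelVolume, spacing: np.ndarray, label: int | None = None
) -> float:
    """Symmetric 95th-percentile surface distance in mm.

    Surfaces are 6-connectivity boundary voxels; distances come from the exact
    Euclidean distance transform with voxel spacing. When ``label`` is None the
    result is the mean over labels present in both volumes; a label empty on
    either side is excluded (and logged).
    """
    if a.data.shape != b.data.shape:
        raise ValueError("label volumes must share a shape")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    labels = (
        [label]
        if label is not None
        else [int(l) for l in np.union1d(a.labels, b.labels) if l != 0]
    )
    vals = []
    for lab in labels:
        ma = a.data == lab
        mb = b.data == lab
        if not ma.any() or not mb.any():
            logger.warning("label %d empty on one side; HD95 undefined, skipped", lab)
            continue
        sa, sb = _surface(ma), _surface(mb)
        vals.append(max(_directed_p95(sa, sb, spacing), _directed_p95(sb, sa, spacing)))
    if not vals:
        raise ValueError("no label with non-empty masks on both sides")
    return float(np.mean(vals))


def njd(dvf: DisplacementField, threshold: float = 0.0) -> float:
    """Percentage of interior voxels where det(J) <= threshold (folding).

    The Jacobian of the map ``x -> x + phi(x)`` is formed in voxel units with
    central differences on interior voxels; the boundary is excluded.
    """
    shape = dvf.shape
    if any(n < 3 for n in shape):
        raise ValueError("NJD needs at least 3 voxels per axis")
    phi_vox = dvf.to_voxel_units()
    J = np.empty(tuple(n - 2 for n in shape) + (3, 3))
    inner = tuple(slice(1, -1) for _ in range(3))
    for axis in range(3):
        hi = [slice(1, -1)] * 3
        lo = [slice(1, -1)] * 3
        hi[axis] = slice(2, None)
        lo[axis] = slice(None, -2)
        dphi = 0.5 * (phi_vox[tuple(hi)] - phi_vox[tuple(lo)])
        J[..., :, axis] = dphi
        J[..., axis, axis] += 1.0
    det = np.linalg.det(J)
    return float(100.0 * np.count_nonzero(det <= threshold) / det.size)
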