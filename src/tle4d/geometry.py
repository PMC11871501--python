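"""Target-volume geometry: mask shifting, unions, margin expansion, and the
union-vs-margin comparison metrics.

Two candidate tracking targets are compared per study:

* ``gtv_union_shift`` — the union of the per-phase GTVs after each phase is
  translated so its marker centroid coincides with the reference phase's
  (the construction a clinic performs on shifted CT images);
* ``gtv_tle_ref`` — the reference-phase GTV expanded anisotropically by the
  per-axis TLE margins, the cheap recipe the TLE statistic justifies.

``ptv_tle_ref`` adds a further isotropic setup margin (default 5 mm).  The
dosimetric V100% endpoint is replaced by a purely geometric coverage
fraction: the fraction of ``gtv_union_shift`` volume contained in the PTV
(``coverage_fraction_geometric`` in outputs).

Shifts are voxel-snapped (round half away from zero, per axis) so binary
masks never acquire interpolation pseudo-volume; the sub-voxel remainder is
returned for auditing and is bounded by half a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .study_io import mask_centroid
from .tle import MarkerCombination, alignment_shift
from .types import FourDStudy, Point3D, VoxelMask

__all__ = [
    "MarginSpec",
    "TargetSet",
    "TargetComparison",
    "snap_shift",
    "shift_mask",
    "union_masks",
    "pad_mask",
    "embed_common",
    "build_gtv_union_shift",
    "expand_mask",
    "build_target_set",
    "compare_targets",
]


@dataclass(frozen=True)
class MarginSpec:
    """Per-axis expansion distances in mm (LR, AP, SI)."""

    lr_mm: float
    ap_mm: float
    si_mm: float

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.as_array()):
            raise ValueError(f"margins must be non-negative: {self}")

    @classmethod
    def isotropic(cls, mm: float) -> "MarginSpec":
        return cls(mm, mm, mm)

    def as_array(self) -> np.ndarray:
        return np.array([self.lr_mm, self.ap_mm, self.si_mm], dtype=float)

    @property
    def is_isotropic(self) -> bool:
        a = self.as_array()
        return bool(np.all(a == a[0]))


def snap_shift(shift: Point3D, spacing: tuple[float, float, float]
               ) -> tuple[np.ndarray, np.ndarray]:
    """Split a mm shift into a whole-voxel offset and a sub-voxel remainder.

    Rounding is half away from zero per axis; the remainder (mm) satisfies
    ``offset * spacing + remainder == shift`` and |remainder| <= spacing/2.
    """
    s = shift.as_array()
    sp = np.asarray(spacing, dtype=float)
    frac = s / sp
    offset = (np.sign(frac) * np.floor(np.abs(frac) + 0.5)).astype(int)
    remainder = s - offset * sp
    return offset, remainder


def _int_shift(occ: np.ndarray, offset: np.ndarray) -> tuple[np.ndarray, int]:
    """Shift occupancy by whole voxels; returns (shifted, n_lost_off_grid)."""
    out = np.zeros_like(occ)
    src, dst = [], []
    for o, n in zip(offset, occ.shape):
        o = int(o)
        if abs(o) >= n:
            return out, int(occ.sum())
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    out[tuple(dst)] = occ[tuple(src)]
    return out, int(occ.sum()) - int(out.sum())


def pad_mask(mask: VoxelMask, before: np.ndarray, after: np.ndarray) -> VoxelMask:
    """Grow the grid by whole voxels on each side; occupancy is preserved."""
    before = np.asarray(before, dtype=int)
    after = np.asarray(after, dtype=int)
    if np.any(before < 0) or np.any(after < 0):
        raise ValueError("padding must be non-negative")
    occ = np.pad(mask.occupancy, list(zip(before, after)))
    origin = mask.origin.as_array() - before * mask.spacing_array()
    return VoxelMask(Point3D.from_array(origin), mask.spacing, occ)


def shift_mask(mask: VoxelMask, shift: Point3D, pad: bool = False) -> VoxelMask:
    """Translate a mask by the nearest whole-voxel offset to ``shift``.

    Volume is preserved exactly.  If occupied voxels would leave the grid,
    either the grid is grown first (``pad=True``) or an error advising grid
    padding is raised.
    """
    offset, _ = snap_shift(shift, mask.spacing)
    if pad:
        mask = pad_mask(mask, np.maximum(-offset, 0), np.maximum(offset, 0))
    shifted, lost = _int_shift(mask.occupancy, offset)
    if lost > 0:
        raise ValueError(
            f"shift {shift} pushes {lost} occupied voxels off the grid; "
            "pad the grid first (shift_mask(..., pad=True))"
        )
    return mask.with_occupancy(shifted)


def union_masks(masks: list[VoxelMask] | tuple[VoxelMask, ...]) -> VoxelMask:
    """Voxelwise OR of masks sharing one grid."""
    if not masks:
        raise ValueError("union of zero masks is undefined")
    first = masks[0]
    occ = first.occupancy.copy()
    for m in masks[1:]:
        if not first.same_grid(m):
            raise ValueError("union_masks requires all masks on one shared grid")
        occ |= m.occupancy
    return first.with_occupancy(occ)


def embed_common(masks: list[VoxelMask]) -> list[VoxelMask]:
    """Embed masks (same spacing, origins offset by whole voxels) onto one
    common bounding grid."""
    if not masks:
        return []
    sp = masks[0].spacing_array()
    for m in masks[1:]:
        if not np.allclose(sp, m.spacing_array()):
            raise ValueError("embed_common requires identical spacing")
    origins = np.array([m.origin.as_array() for m in masks])
    lo = origins.min(axis=0)
    offsets = (origins - lo) / sp
    if not np.allclose(offsets, np.round(offsets), atol=1e-6):
        raise ValueError("mask origins are not whole-voxel commensurate")
    offsets = np.round(offsets).astype(int)
    ends = offsets + np.array([m.shape for m in masks])
    shape = tuple(ends.max(axis=0))
    out = []
    for m, off in zip(masks, offsets):
        occ = np.zeros(shape, dtype=bool)
        sl = tuple(slice(o, o + n) for o, n in zip(off, m.shape))
        occ[sl] = m.occupancy
        out.append(VoxelMask(Point3D.from_array(lo), masks[0].spacing, occ))
    return out


def build_gtv_union_shift(
    study: FourDStudy, combination: MarkerCombination | None = None
) -> VoxelMask:
    """Union of the per-phase GTVs after marker-centroid alignment.

    Each phase-p mask is translated by s_p = M_ref - M_p (the reference
    phase stays put, s_ref = 0) and the union is taken over all phases.
    By default the combination uses every implanted marker.
    """
    if combination is None:
        combination = MarkerCombination(study.patient_id, study.marker_ids)
    shifted = []
    for p in range(study.phases.n_phases):
        s_p = alignment_shift(study, combination, p)
        shifted.append(shift_mask(study.gtv_masks[p], s_p, pad=True))
    return union_masks(embed_common(shifted))


def _ellipsoid_element(margins: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Structuring element: voxel offsets within the mm-ellipsoid of
    semi-axes ``margins``; axes with zero margin admit only zero offset."""
    radii = np.where(margins > 0, np.ceil(margins / spacing).astype(int), 0)
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
    d2 = np.zeros(tuple(2 * r + 1 for r in radii))
    for k in range(3):
        step = grids[k] * spacing[k]
        if margins[k] > 0:
            d2 = d2 + (step / margins[k]) ** 2
        # zero-margin axes contribute a single zero plane by construction
    return d2 <= 1.0 + 1e-9


def expand_mask(mask: VoxelMask, margins: MarginSpec, pad: bool = True) -> VoxelMask:
    """Morphological dilation by an ellipsoid of semi-axes (lr, ap, si) mm.

    A voxel of the result is occupied iff its center lies within the
    axis-scaled distance 1 of some occupied source voxel center.  With
    ``pad=True`` (default) the grid grows so nothing is clipped; with
    ``pad=False`` the expansion is truncated at the grid boundary.
    """
    m = margins.as_array()
    if np.all(m == 0):
        return mask
    sp = mask.spacing_array()
    elem = _ellipsoid_element(m, sp)
    if pad:
        r = np.array([(s - 1) // 2 for s in elem.shape])
        mask = pad_mask(mask, r, r)
    occ = ndimage.binary_dilation(mask.occupancy, structure=elem)
    return mask.with_occupancy(occ)


@dataclass(frozen=True)
class TargetSet:
    """The four masks of one study's margin validation, on one shared grid."""

    gtv_ref: VoxelMask
    gtv_union_shift: VoxelMask
    gtv_tle_ref: VoxelMask
    ptv_tle_ref: VoxelMask
    tle_margins: MarginSpec
    ptv_margin_mm: float

    def __post_init__(self) -> None:
        masks = (self.gtv_ref, self.gtv_union_shift, self.gtv_tle_ref, self.ptv_tle_ref)
        for m in masks[1:]:
            if not masks[0].same_grid(m):
                raise ValueError("TargetSet masks must share one grid")
        if np.any(self.gtv_ref.occupancy & ~self.gtv_tle_ref.occupancy):
            raise ValueError("gtv_ref must be contained in gtv_tle_ref")
        if np.any(self.gtv_tle_ref.occupancy & ~self.ptv_tle_ref.occupancy):
            raise ValueError("gtv_tle_ref must be contained in ptv_tle_ref")


@dataclass(frozen=True)
class TargetComparison:
    """Geometric comparison of the margin-based target to the union target.

    coverage_fraction_geometric proxies dosimetric V100%: the prescription
    isodose is assumed to cover the PTV, so coverage of the union by the
    PTV stands in for its dose coverage.
    """

    r_v_union_ref: float
    centroid_distance_mm: float
    coverage_fraction_geometric: float

    @property
    def fully_covered(self) -> bool:
        return self.coverage_fraction_geometric >= 1.0


def build_target_set(
    study: FourDStudy,
    tle_margins: MarginSpec,
    ptv_margin_mm: float = 5.0,
    combination: MarkerCombination | None = None,
) -> TargetSet:
    """Construct gtv_ref, gtv_union_shift, gtv_tle_ref and ptv_tle_ref for
    one study, embedded on one common grid."""
    union = build_gtv_union_shift(study, combination)
    gtv_tle_ref = expand_mask(study.reference_mask, tle_margins, pad=True)
    ptv = expand_mask(gtv_tle_ref, MarginSpec.isotropic(ptv_margin_mm), pad=True)
    gtv_ref_e, union_e, gtv_tle_e, ptv_e = embed_common(
        [study.reference_mask, union, gtv_tle_ref, ptv]
    )
    return TargetSet(gtv_ref_e, union_e, gtv_tle_e, ptv_e, tle_margins,
                     float(ptv_margin_mm))


def compare_targets(ts: TargetSet) -> TargetComparison:
    """Volume ratio, centroid distance and geometric coverage for a TargetSet."""
    if ts.gtv_union_shift.n_occupied == 0:
        raise ValueError("gtv_union_shift is empty; nothing to compare")
    ratio = ts.gtv_tle_ref.volume_mm3 / ts.gtv_union_shift.volume_mm3
    c1 = mask_centroid(ts.gtv_tle_ref).as_array()
    c2 = mask_centroid(ts.gtv_union_shift).as_array()
    dist = float(np.linalg.norm(c1 - c2))
    inter = int((ts.gtv_union_shift.occupancy & ts.ptv_tle_ref.occupancy).sum())
    coverage = inter / ts.gtv_union_shift.n_occupied
    return TargetComparison(float(ratio), dist, float(coverage))
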