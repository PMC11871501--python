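"""Target localization error (TLE): combination enumeration, marker-centroid
alignment, per-direction RMSE, and percentile pooling.

The statistic
-------------
For a chosen subset of fiducial markers, each respiratory phase p is rigidly
translated so that the subset's marker centroid M_p coincides with the
reference-phase marker centroid M_ref — exactly what a marker-based tracking
system does.  The residual tumor-position error at phase p is then

    r_p = (G_p + s_p) - G_ref,      s_p = M_ref - M_p,

with G_p the GTV centroid at phase p, which is algebraically the change in
the tumor-to-marker-centroid offset, (G_p - M_p) - (G_ref - M_ref).  The
per-direction RMSE pools r_p over the N non-reference phases (N = 9 for the
standard 10-phase binning):

    RMSE_axis = sqrt( (1/N) * sum_p r_{p,axis}^2 ).

The TLE for a cohort group is the 95th percentile of these per-combination
RMSE values; it is the margin needed (per axis) to cover tumor-marker
asynchrony in 95% of marker-subset choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _itercombs
from typing import Iterable, Mapping, Sequence

import numpy as np

from .study_io import mask_centroid
from .types import AXIS_NAMES, FourDStudy, MarkerTrack, Point3D, as_point_sequence

__all__ = [
    "MarkerCombination",
    "CombinationResult",
    "GroupStats",
    "TLEReport",
    "enumerate_combinations",
    "combination_centroid",
    "alignment_shift",
    "rmse_from_tracks",
    "rmse_per_direction",
    "pool_tle",
]

GROUP_ORDER = ("2", "3", "4", "5", "all")
GROUP_DISPLAY = {"2": "Two", "3": "Three", "4": "Four", "5": "Five", "all": "All"}


@dataclass(frozen=True)
class MarkerCombination:
    """One subset of a study's fiducial markers."""

    patient_id: str
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(self.marker_ids)
        object.__setattr__(self, "marker_ids", ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate marker ids in combination: {ids}")
        if not ids:
            raise ValueError("combination must contain at least one marker")

    @property
    def k(self) -> int:
        return len(self.marker_ids)


@dataclass(frozen=True)
class CombinationResult:
    """Per-direction RMSE (and covariates) for one marker combination."""

    combination: MarkerCombination
    rmse_mm: np.ndarray  # (3,) LR, AP, SI
    marker_gtv_distance_mm: np.ndarray | None = None  # (3,) per-direction
    respiratory_marker_motion_mm: np.ndarray | None = None  # (3,)

    def __post_init__(self) -> None:
        r = np.asarray(self.rmse_mm, dtype=float)
        object.__setattr__(self, "rmse_mm", r)
        if r.shape != (3,) or np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError(f"rmse_mm must be 3 finite non-negative values: {r}")


def enumerate_combinations(
    marker_ids: Sequence[str], min_size: int = 2, patient_id: str = ""
) -> list[MarkerCombination]:
    """All marker subsets of size >= ``min_size``, each exactly once.

    Order is deterministic: by subset size, then lexicographically by ids.
    For a 5-marker case this yields the 10 two-marker patterns plus the
    10 + 5 + 1 larger subsets (26 total at the default minimum of 2).
    """
    ids = sorted(set(marker_ids))
    if len(ids) != len(marker_ids):
        raise ValueError(f"marker ids must be distinct: {list(marker_ids)}")
    if len(ids) < min_size:
        raise ValueError(
            f"need at least {min_size} markers, got {len(ids)}: {ids}"
        )
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    out = []
    for k in range(min_size, len(ids) + 1):
        for subset in _itercombs(ids, k):
            out.append(MarkerCombination(patient_id, subset))
    return out


def _tracks_by_id(tracks: Iterable[MarkerTrack]) -> Mapping[str, MarkerTrack]:
    return {t.marker_id: t for t in tracks}


def combination_centroid(
    tracks: Sequence[MarkerTrack], marker_ids: Sequence[str], phase_index: int
) -> Point3D:
    """Unweighted mean of the member markers' positions at one phase."""
    by_id = _tracks_by_id(tracks)
    missing = [m for m in marker_ids if m not in by_id]
    if missing:
        raise KeyError(f"markers {missing} not present in tracks {sorted(by_id)}")
    pts = np.array([by_id[m].positions[phase_index].as_array() for m in marker_ids])
    return Point3D.from_array(pts.mean(axis=0))


def alignment_shift(
    study: FourDStudy, combination: MarkerCombination, phase_index: int
) -> Point3D:
    """Translation s_p = M_ref - M_p applied to phase-p structures.

    Applying s_p to the phase-p marker centroid lands it exactly on the
    reference-phase marker centroid; s_ref is zero by construction.
    """
    m_p = combination_centroid(study.markers, combination.marker_ids, phase_index)
    m_ref = combination_centroid(
        study.markers, combination.marker_ids, study.phases.reference_index
    )
    return m_ref - m_p


def rmse_from_tracks(
    target_positions: Sequence[Point3D] | np.ndarray,
    marker_centroids: Sequence[Point3D] | np.ndarray,
    reference_index: int,
) -> np.ndarray:
    """Per-direction RMSE of the aligned target positions, from point tracks.

    ``target_positions`` and ``marker_centroids`` are per-phase positions
    (same length n >= 2); the residual at each non-reference phase is
    (G_p - M_p) - (G_ref - M_ref) and the mean square runs over the n - 1
    non-reference phases.
    """
    g = as_point_sequence(target_positions)
    m = as_point_sequence(marker_centroids)
    if g.shape != m.shape:
        raise ValueError(f"track shapes differ: {g.shape} vs {m.shape}")
    n = g.shape[0]
    if not 0 <= reference_index < n:
        raise ValueError(f"reference_index {reference_index} out of range for {n} phases")
    if n < 2:
        raise ValueError("need at least 2 phases")
    rel = g - m
    resid = rel - rel[reference_index]
    non_ref = [i for i in range(n) if i != reference_index]
    return np.sqrt(np.mean(resid[non_ref] ** 2, axis=0))


def rmse_per_direction(
    study: FourDStudy, combination: MarkerCombination, mode: str = "centroid"
) -> np.ndarray:
    """Per-direction (LR, AP, SI) RMSE for one marker combination.

    mode="centroid" (default) evaluates the algebraic shortcut on GTV mask
    centroids: shifting a rigid structure shifts its centroid by exactly the
    shift vector, so aligning masks and recomputing centroids is equivalent
    and slower.  mode="mask-shift" performs the literal construction —
    voxel-snapped shift of each phase mask, then centroid — for end-to-end
    validation; it differs from the shortcut only by the sub-voxel snap
    remainder.
    """
    from .geometry import shift_mask  # local import; geometry depends on tle

    ref_idx = study.phases.reference_index
    centroids_m = [
        combination_centroid(study.markers, combination.marker_ids, p).as_array()
        for p in range(study.phases.n_phases)
    ]
    if mode == "centroid":
        centroids_g = [mask_centroid(m).as_array() for m in study.gtv_masks]
        return rmse_from_tracks(np.array(centroids_g), np.array(centroids_m), ref_idx)
    if mode == "mask-shift":
        g_ref = mask_centroid(study.gtv_masks[ref_idx]).as_array()
        resid = []
        for p in study.phases.non_reference_indices():
            s_p = alignment_shift(study, combination, p)
            shifted = shift_mask(study.gtv_masks[p], s_p, pad=True)
            resid.append(mask_centroid(shifted).as_array() - g_ref)
        return np.sqrt(np.mean(np.array(resid) ** 2, axis=0))
    raise ValueError(f"unknown mode {mode!r}; use 'centroid' or 'mask-shift'")


@dataclass(frozen=True)
class GroupStats:
    """Pooled RMSE summary for one marker-count group, per direction."""

    n_combinations: int
    rmse_min_mm: np.ndarray  # (3,)
    rmse_max_mm: np.ndarray
    rmse_sd_mm: np.ndarray
    tle_mm: np.ndarray  # P95 of pooled RMSE values


@dataclass(frozen=True)
class TLEReport:
    """Per-group (k = 2..5 and 'all') pooled RMSE range, SD, and TLE."""

    groups: dict[str, GroupStats] = field(default_factory=dict)
    percentile: float = 95.0

    def tle(self, group: str = "all") -> np.ndarray:
        return self.groups[group].tle_mm

    def to_records(self) -> list[dict]:
        recs = []
        for group in GROUP_ORDER:
            if group not in self.groups:
                continue
            g = self.groups[group]
            for d, axis in enumerate(AXIS_NAMES):
                recs.append(
                    {
                        "group": GROUP_DISPLAY[group],
                        "n": g.n_combinations,
                        "direction": axis,
                        "rmse_min_mm": float(g.rmse_min_mm[d]),
                        "rmse_max_mm": float(g.rmse_max_mm[d]),
                        "rmse_sd_mm": float(g.rmse_sd_mm[d]),
                        "tle_mm": float(g.tle_mm[d]),
                    }
                )
        return recs


def pool_tle(
    results: Sequence[CombinationResult],
    percentile: float = 95.0,
    interpolation: str = "linear",
    sd_ddof: int = 0,
) -> TLEReport:
    """Pool per-combination RMSEs into group TLEs (P95 by default).

    Combinations are grouped by subset size k across all patients, plus an
    'all' group pooling every combination; per group and direction the min,
    max, SD (population SD by default) and the percentile (TLE) of the
    pooled RMSE values are reported.  The percentile uses linear
    interpolation between closest order statistics (rank 0.95*(n-1),
    zero-based) unless another numpy method is requested.
    """
    if not results:
        raise ValueError("no combination results to pool")
    by_group: dict[str, list[np.ndarray]] = {}
    for res in results:
        by_group.setdefault(str(res.combination.k), []).append(res.rmse_mm)
        by_group.setdefault("all", []).append(res.rmse_mm)
    groups = {}
    for key, values in by_group.items():
        arr = np.array(values)  # (n, 3)
        groups[key] = GroupStats(
            n_combinations=arr.shape[0],
            rmse_min_mm=arr.min(axis=0),
            rmse_max_mm=arr.max(axis=0),
            rmse_sd_mm=arr.std(axis=0, ddof=sd_ddof),
            tle_mm=np.percentile(arr, percentile, axis=0, method=interpolation),
        )
    return TLEReport(groups=groups, percentile=percentile)
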