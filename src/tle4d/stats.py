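"""Covariates of tumor-marker asynchrony and their correlation with the
per-combination residual error.

Two geometric covariates are attached to each marker combination:

* marker-GTV distance — per-axis absolute offset of the marker-subset
  centroid from the GTV centroid, both in the reference phase;
* respiratory marker motion — per-axis maximum displacement of the subset
  centroid from its reference-phase position across all phases (peak-to-peak
  available via ``mode="peak_to_peak"``).

The dependent variable in the correlations is the per-combination RMSE
(the quantity whose 95th percentile defines the TLE): the TLE itself is a
single pooled number per group, so only the combination-level error admits
a correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .study_io import mask_centroid
from .tle import CombinationResult, combination_centroid
from .types import AXIS_NAMES, FourDStudy

__all__ = [
    "CorrelationResult",
    "marker_gtv_distance",
    "respiratory_marker_motion",
    "pearson_correlation",
    "correlate_tle",
]

COVARIATES = ("marker_gtv_distance", "respiratory_marker_motion")


@dataclass(frozen=True)
class CorrelationResult:
    group: str  # marker count ("2".."5") or "all"
    direction: str  # LR / AP / SI
    covariate: str
    pearson_r: float
    n: int
    two_sided_p: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError(f"|r| must be <= 1: {self.pearson_r}")


def marker_gtv_distance(study: FourDStudy, marker_ids: Sequence[str]) -> np.ndarray:
    """Per-axis |marker-subset centroid - GTV centroid| in the reference
    phase (mm); index with AXIS_NAMES. Use np.linalg.norm for the 3D value."""
    ref = study.phases.reference_index
    m = combination_centroid(study.markers, marker_ids, ref).as_array()
    g = mask_centroid(study.gtv_masks[ref]).as_array()
    return np.abs(m - g)


def respiratory_marker_motion(
    study: FourDStudy, marker_ids: Sequence[str], mode: str = "from_reference"
) -> np.ndarray:
    """Per-axis breathing excursion of the marker-subset centroid (mm).

    "from_reference" (default): max over phases of the absolute displacement
    from the reference phase.  "peak_to_peak": max minus min over phases.
    """
    pos = np.array(
        [
            combination_centroid(study.markers, marker_ids, p).as_array()
            for p in range(study.phases.n_phases)
        ]
    )
    if mode == "from_reference":
        return np.abs(pos - pos[study.phases.reference_index]).max(axis=0)
    if mode == "peak_to_peak":
        return pos.max(axis=0) - pos.min(axis=0)
    raise ValueError(f"unknown mode {mode!r}; use 'from_reference' or 'peak_to_peak'")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment r with its two-sided p (t-transform, n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need n >= 3 for a correlation, got n = {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_tle(
    results: Sequence[CombinationResult],
    min_group_size: int = 3,
) -> list[CorrelationResult]:
    """Correlate per-combination RMSE against both covariates, per
    marker-count group (and 'all') and per direction.

    Groups smaller than ``min_group_size`` and zero-variance covariates are
    skipped.  Results require covariates to have been attached to each
    CombinationResult.
    """
    by_group: dict[str, list[CombinationResult]] = {}
    for res in results:
        if res.marker_gtv_distance_mm is None or res.respiratory_marker_motion_mm is None:
            raise ValueError(
                f"combination {res.combination.marker_ids} lacks covariates"
            )
        by_group.setdefault(str(res.combination.k), []).append(res)
        by_group.setdefault("all", []).append(res)
    out: list[CorrelationResult] = []
    for group in sorted(by_group):
        members = by_group[group]
        if len(members) < min_group_size:
            continue
        rmse = np.array([m.rmse_mm for m in members])  # (n, 3)
        covs = {
            "marker_gtv_distance": np.array(
                [m.marker_gtv_distance_mm for m in members]
            ),
            "respiratory_marker_motion": np.array(
                [m.respiratory_marker_motion_mm for m in members]
            ),
        }
        for d, axis in enumerate(AXIS_NAMES):
            for name, cov in covs.items():
                if np.ptp(cov[:, d]) == 0 or np.ptp(rmse[:, d]) == 0:
                    continue
                r, p = pearson_correlation(cov[:, d], rmse[:, d])
                out.append(
                    CorrelationResult(group, axis, name, r, len(members), p)
                )
    return out
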