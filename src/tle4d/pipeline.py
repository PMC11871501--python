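"""End-to-end orchestration: simulate -> compute TLE -> build targets ->
correlate -> report.

The default cohort layout mirrors a realistic marker-count census for a
fiducial-tracked lung-SBRT service: 11 error-estimation studies with
2/3/4/5 markers in 1/2/4/4 patients (which yields 71 + 58 + 24 + 4 = 157
marker combinations at the default minimum subset size of 2) and 10
validation studies with 2/3/4 markers in 2/5/3 patients.  All randomness
flows from a single seed; per-study generators are derived from
(seed, study index) so studies are independent and order-stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as _stats
from .geometry import MarginSpec, build_target_set, compare_targets
from .phantom import random_phantom_spec
from .phantom import build_phantom
from .tle import (
    GROUP_DISPLAY,
    GROUP_ORDER,
    CombinationResult,
    GroupStats,
    TLEReport,
    enumerate_combinations,
    pool_tle,
    rmse_per_direction,
)
from .types import AXIS_NAMES, FourDStudy

logger = logging.getLogger(__name__)

__all__ = [
    "TLE_COHORT_MARKER_COUNTS",
    "VALIDATION_COHORT_MARKER_COUNTS",
    "PipelineConfig",
    "simulate_cohort",
    "evaluate_study",
    "run_tle_stage",
    "run_validation_stage",
    "write_table2_report",
    "read_table2_report",
    "run_all",
]

# Marker-count census of the two cohorts (counts of patients with
# 2, 3, 4 and 5 implanted markers respectively).
TLE_COHORT_MARKER_COUNTS: tuple[int, ...] = (2, 3, 3, 4, 4, 4, 4, 5, 5, 5, 5)
VALIDATION_COHORT_MARKER_COUNTS: tuple[int, ...] = (2, 2, 3, 3, 3, 3, 3, 4, 4, 4)


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; every field has the study-condition default."""

    seed: int = 0
    marker_counts: tuple[int, ...] = TLE_COHORT_MARKER_COUNTS
    validation_marker_counts: tuple[int, ...] = VALIDATION_COHORT_MARKER_COUNTS
    min_combination_size: int = 2
    rmse_mode: str = "centroid"  # or "mask-shift"
    noise_sd_mm: float = 0.2
    percentile: float = 95.0
    margins_mode: str = "cohort"  # "cohort" | "explicit"
    explicit_margins_mm: tuple[float, float, float] | None = None
    ptv_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.margins_mode not in ("cohort", "explicit"):
            raise ValueError(f"unknown margins_mode {self.margins_mode!r}")
        if self.margins_mode == "explicit" and self.explicit_margins_mm is None:
            raise ValueError("explicit margins_mode needs explicit_margins_mm")


def simulate_cohort(
    seed: int,
    marker_counts: Sequence[int] = TLE_COHORT_MARKER_COUNTS,
    *,
    noise_sd_mm: float = 0.2,
    prefix: str = "P",
    spacing_mm: float = 2.0,
) -> list[FourDStudy]:
    """Simulate one phantom study per entry of ``marker_counts``."""
    studies = []
    for i, n_markers in enumerate(marker_counts):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, i])
        spec = random_phantom_spec(
            rng, n_markers, noise_sd_mm=noise_sd_mm, spacing_mm=spacing_mm
        )
        studies.append(build_phantom(spec, patient_id=f"{prefix}{i + 1:02d}"))
    return studies


def evaluate_study(
    study: FourDStudy, min_size: int = 2, mode: str = "centroid"
) -> list[CombinationResult]:
    """All combination results for one study, with covariates attached."""
    results = []
    for comb in enumerate_combinations(study.marker_ids, min_size, study.patient_id):
        rmse = rmse_per_direction(study, comb, mode=mode)
        results.append(
            CombinationResult(
                combination=comb,
                rmse_mm=rmse,
                marker_gtv_distance_mm=_stats.marker_gtv_distance(
                    study, comb.marker_ids
                ),
                respiratory_marker_motion_mm=_stats.respiratory_marker_motion(
                    study, comb.marker_ids
                ),
            )
        )
        logger.debug(
            "study %s combination %s rmse %s", study.patient_id, comb.marker_ids, rmse
        )
    return results


def _combination_frame(results: Sequence[CombinationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {
            "patient_id": res.combination.patient_id,
            "marker_ids": "+".join(res.combination.marker_ids),
            "k": res.combination.k,
        }
        for d, axis in enumerate(AXIS_NAMES):
            a = axis.lower()
            row[f"rmse_{a}_mm"] = res.rmse_mm[d]
            row[f"marker_gtv_distance_{a}_mm"] = res.marker_gtv_distance_mm[d]
            row[f"respiratory_marker_motion_{a}_mm"] = res.respiratory_marker_motion_mm[d]
        rows.append(row)
    return pd.DataFrame(rows)


def run_tle_stage(
    studies: Sequence[FourDStudy],
    min_size: int = 2,
    mode: str = "centroid",
    percentile: float = 95.0,
) -> tuple[TLEReport, pd.DataFrame]:
    """Per-combination RMSEs for every study, pooled into the group report."""
    if not studies:
        raise ValueError("no studies to evaluate")
    all_results: list[CombinationResult] = []
    for study in studies:
        try:
            all_results.extend(evaluate_study(study, min_size, mode))
        except Exception as exc:  # re-raise with the study id attached
            raise RuntimeError(f"study {study.patient_id!r} failed: {exc}") from exc
    report = pool_tle(all_results, percentile=percentile)
    return report, _combination_frame(all_results)


def run_validation_stage(
    studies: Sequence[FourDStudy],
    margins: MarginSpec,
    ptv_margin_mm: float = 5.0,
) -> pd.DataFrame:
    """One target-comparison row per validation study, using all implanted
    markers for the union target; rows with coverage < 1 are flagged."""
    rows = []
    for study in studies:
        try:
            ts = build_target_set(study, margins, ptv_margin_mm)
            cmp_ = compare_targets(ts)
        except Exception as exc:
            raise RuntimeError(f"study {study.patient_id!r} failed: {exc}") from exc
        rows.append(
            {
                "patient_id": study.patient_id,
                "gtv_union_shift_cm3": ts.gtv_union_shift.volume_mm3 / 1000.0,
                "gtv_tle_ref_cm3": ts.gtv_tle_ref.volume_mm3 / 1000.0,
                "r_v_union_ref": cmp_.r_v_union_ref,
                "centroid_distance_mm": cmp_.centroid_distance_mm,
                "coverage_fraction_geometric": cmp_.coverage_fraction_geometric,
                "fully_covered": cmp_.fully_covered,
            }
        )
    return pd.DataFrame(rows)


def write_table2_report(report: TLEReport, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the group report as CSV (display, 1 decimal) and JSON (full
    precision).  Returns (csv_path, json_path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(report.to_records())
    csv_path = out_dir / "tle_report.csv"
    display = frame.copy()
    for col in ("rmse_min_mm", "rmse_max_mm", "rmse_sd_mm", "tle_mm"):
        display[col] = display[col].round(1)
    display.to_csv(csv_path, index=False)
    json_path = out_dir / "tle_report.json"
    payload = {
        "percentile": report.percentile,
        "groups": {
            key: {
                "n_combinations": g.n_combinations,
                "rmse_min_mm": g.rmse_min_mm.tolist(),
                "rmse_max_mm": g.rmse_max_mm.tolist(),
                "rmse_sd_mm": g.rmse_sd_mm.tolist(),
                "tle_mm": g.tle_mm.tolist(),
            }
            for key, g in report.groups.items()
        },
    }
    json_path.write_text(json.dumps(payload, indent=2))
    return csv_path, json_path


def read_table2_report(json_path: str | Path) -> TLEReport:
    payload = json.loads(Path(json_path).read_text())
    groups = {
        key: GroupStats(
            n_combinations=int(g["n_combinations"]),
            rmse_min_mm=np.array(g["rmse_min_mm"]),
            rmse_max_mm=np.array(g["rmse_max_mm"]),
            rmse_sd_mm=np.array(g["rmse_sd_mm"]),
            tle_mm=np.array(g["tle_mm"]),
        )
        for key, g in payload["groups"].items()
    }
    return TLEReport(groups=groups, percentile=float(payload["percentile"]))


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write all outputs under ``out_dir``.

    Returns a summary dict (also written as run_manifest.json) with the
    cohort TLE margins, validation aggregates and correlation rows.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tle_studies = simulate_cohort(
        config.seed, config.marker_counts, noise_sd_mm=config.noise_sd_mm, prefix="T"
    )
    report, combos = run_tle_stage(
        tle_studies,
        config.min_combination_size,
        config.rmse_mode,
        config.percentile,
    )
    combos.to_csv(out_dir / "combinations.csv", index=False)
    write_table2_report(report, out_dir)

    if config.margins_mode == "explicit":
        margins = MarginSpec(*config.explicit_margins_mm)
    else:
        margins = MarginSpec(*report.tle("all"))

    val_studies = simulate_cohort(
        config.seed + 101,
        config.validation_marker_counts,
        noise_sd_mm=config.noise_sd_mm,
        prefix="V",
    )
    validation = run_validation_stage(val_studies, margins, config.ptv_margin_mm)
    validation.to_csv(out_dir / "target_comparison.csv", index=False)

    corr_rows = _stats.correlate_tle(
        [
            res
            for study in tle_studies
            for res in evaluate_study(
                study, config.min_combination_size, config.rmse_mode
            )
        ]
    )
    corr_frame = pd.DataFrame(
        [
            {
                "group": GROUP_DISPLAY.get(c.group, c.group),
                "direction": c.direction,
                "covariate": c.covariate,
                "n": c.n,
                "pearson_r": c.pearson_r,
                "two_sided_p": c.two_sided_p,
            }
            for c in corr_rows
        ]
    )
    corr_frame.to_csv(out_dir / "correlations.csv", index=False)

    summary = {
        "seed": config.seed,
        "n_tle_studies": len(tle_studies),
        "n_validation_studies": len(val_studies),
        "n_combinations": {
            GROUP_DISPLAY[g]: report.groups[g].n_combinations
            for g in GROUP_ORDER
            if g in report.groups
        },
        "tle_margins_mm": {
            axis.lower(): float(v) for axis, v in zip(AXIS_NAMES, margins.as_array())
        },
        "ptv_margin_mm": config.ptv_margin_mm,
        "r_v_union_ref_mean": float(validation["r_v_union_ref"].mean()),
        "centroid_distance_mean_mm": float(validation["centroid_distance_mm"].mean()),
        "coverage_fraction_min": float(
            validation["coverage_fraction_geometric"].min()
        ),
        "n_under_covered": int((~validation["fully_covered"]).sum()),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(summary, indent=2))
    return summary
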