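"""Shared fixtures: small deterministic phantoms and hand-built studies."""

from __future__ import annotations

import numpy as np
import pytest

from tle4d.phantom import (
    MotionModelConfig,
    ObjectMotion,
    PhantomSpec,
    build_phantom,
)
from tle4d.types import FourDStudy, MarkerTrack, PhaseSet, Point3D, VoxelMask


@pytest.fixture
def phases() -> PhaseSet:
    return PhaseSet()  # 10 phases, reference = 30%


def make_static_spec(n_markers: int = 2, radius: float = 6.0) -> PhantomSpec:
    markers = {
        f"m{j + 1}": ObjectMotion(baseline=Point3D(5.0 * j, -4.0, 3.0))
        for j in range(n_markers)
    }
    motion = MotionModelConfig(tumor=ObjectMotion(), markers=markers, seed=0)
    return PhantomSpec(
        motion=motion,
        tumor_radius_mm=radius,
        grid_spacing_mm=(2.0, 2.0, 2.0),
        grid_shape=(16, 16, 16),
        grid_origin=Point3D(-15.0, -15.0, -15.0),
    )


def make_lagged_spec(
    amp_si: float = 10.0,
    lag: float = 0.05,
    n_markers: int = 2,
    spacing: float = 1.0,
    radius: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Tumor with SI sinusoid; markers share the tumor motion plus a lag."""
    amp = (0.0, 0.0, amp_si)
    markers = {
        f"m{j + 1}": ObjectMotion(
            amplitude_mm=amp, phase_lag=lag,
            baseline=Point3D(6.0 * j - 3.0, 5.0, -4.0),
        )
        for j in range(n_markers)
    }
    motion = MotionModelConfig(
        tumor=ObjectMotion(amplitude_mm=amp),
        markers=markers,
        noise_sd_mm=(noise_sd,) * 3,
        seed=seed,
    )
    reach = radius + amp_si + 3.0
    n_si = int(np.ceil(2 * reach / spacing)) + 1
    n_tr = int(np.ceil(2 * (radius + 3.0) / spacing)) + 1
    return PhantomSpec(
        motion=motion,
        tumor_radius_mm=radius,
        grid_spacing_mm=(spacing,) * 3,
        grid_shape=(n_tr, n_tr, n_si),
        grid_origin=Point3D(-(radius + 3.0), -(radius + 3.0), -reach),
    )


@pytest.fixture
def static_study() -> FourDStudy:
    return build_phantom(make_static_spec(), "static")


@pytest.fixture
def lagged_spec() -> PhantomSpec:
    return make_lagged_spec()


@pytest.fixture
def lagged_study(lagged_spec) -> FourDStudy:
    return build_phantom(lagged_spec, "lagged")


def make_track_study(
    tumor_positions: np.ndarray,
    marker_positions: dict[str, np.ndarray],
    phases: PhaseSet | None = None,
) -> FourDStudy:
    """Study whose GTV 'mask' is a single voxel placed exactly at each tumor
    position: the grid origin moves per phase, so mask centroids equal the
    given positions bit-exactly (masks intentionally not on one shared grid
    would violate invariants, so one shared one-voxel grid is simulated by a
    large sparse grid)."""
    phases = phases or PhaseSet()
    tumor_positions = np.asarray(tumor_positions, dtype=float)
    n = phases.n_phases
    assert tumor_positions.shape == (n, 3)
    # One shared fine grid covering all tumor positions; a single occupied
    # voxel per phase at the nearest grid node introduces zero error because
    # positions are chosen on-grid in the tests that use this helper.
    spacing = np.array([0.5, 0.5, 0.5])
    lo = tumor_positions.min(axis=0) - 2.0
    shape = tuple((np.ceil((tumor_positions.max(axis=0) + 2.0 - lo) / spacing)).astype(int) + 1)
    masks = []
    for p in range(n):
        occ = np.zeros(shape, dtype=bool)
        idx = np.round((tumor_positions[p] - lo) / spacing).astype(int)
        occ[tuple(idx)] = True
        masks.append(VoxelMask(Point3D.from_array(lo), tuple(spacing), occ))
    tracks = tuple(
        MarkerTrack(mid, tuple(Point3D.from_array(row) for row in pos))
        for mid, pos in marker_positions.items()
    )
    return FourDStudy("tracks", phases, tuple(masks), tracks)
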