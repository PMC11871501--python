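"""Mask shifting, unions, ellipsoidal margin expansion and target comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tle4d.geometry import (
    MarginSpec,
    TargetSet,
    build_gtv_union_shift,
    build_target_set,
    compare_targets,
    embed_common,
    expand_mask,
    pad_mask,
    shift_mask,
    snap_shift,
    union_masks,
)
from tle4d.phantom import analytic_residual_rmse, build_phantom
from tle4d.study_io import mask_centroid
from tle4d.types import Point3D, VoxelMask

from conftest import make_lagged_spec


def _ball(radius, spacing=1.0, pad=2, center=(0.0, 0.0, 0.0)):
    n = int(np.ceil((radius + pad) / spacing))
    ax = np.arange(-n, n + 1) * spacing
    occ = (
        (ax[:, None, None] - center[0]) ** 2
        + (ax[None, :, None] - center[1]) ** 2
        + (ax[None, None, :] - center[2]) ** 2
    ) <= radius**2
    return VoxelMask(Point3D(-n * spacing, -n * spacing, -n * spacing),
                     (spacing,) * 3, occ)


class TestSnapAndShift:
    def test_subvoxel_shift_keeps_mask_and_records_remainder(self):
        mask = _ball(3.0)
        offset, rem = snap_shift(Point3D(0.4, -0.4, 0.0), mask.spacing)
        assert list(offset) == [0, 0, 0]
        assert np.allclose(rem, [0.4, -0.4, 0.0])
        shifted = shift_mask(mask, Point3D(0.4, -0.4, 0.0))
        assert np.array_equal(shifted.occupancy, mask.occupancy)

    def test_half_voxel_rounds_away_from_zero(self):
        offset, rem = snap_shift(Point3D(0.5, -0.5, 1.5), (1.0, 1.0, 1.0))
        assert list(offset) == [1, -1, 2]
        assert np.allclose(rem, [-0.5, 0.5, -0.5])

    def test_whole_voxel_shift_moves_indices(self):
        mask = _ball(2.0, pad=4)
        shifted = shift_mask(mask, Point3D(2.0, 0.0, -1.0))
        assert shifted.n_occupied == mask.n_occupied
        assert np.array_equal(
            shifted.occupancy, np.roll(mask.occupancy, (2, 0, -1), axis=(0, 1, 2))
        )

    def test_zero_shift_is_identity(self):
        mask = _ball(2.5)
        out = shift_mask(mask, Point3D(0, 0, 0))
        assert out.same_grid(mask)
        assert np.array_equal(out.occupancy, mask.occupancy)

    def test_off_grid_shift_raises_with_padding_advice(self):
        mask = _ball(3.0, pad=0)
        with pytest.raises(ValueError, match="pad"):
            shift_mask(mask, Point3D(10.0, 0.0, 0.0))

    def test_pad_true_preserves_volume_for_any_shift(self):
        mask = _ball(3.0, pad=0)
        out = shift_mask(mask, Point3D(10.0, -7.0, 3.0), pad=True)
        assert out.n_occupied == mask.n_occupied
        delta = mask_centroid(out).as_array() - mask_centroid(mask).as_array()
        assert np.allclose(delta, [10.0, -7.0, 3.0])

    @given(
        sx=st.floats(-6, 6), sy=st.floats(-6, 6), sz=st.floats(-6, 6),
        seed=st.integers(0, 30),
    )
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_volume_conserved_under_padded_shift(self, sx, sy, sz, seed):
        rng = np.random.default_rng(seed)
        occ = rng.random((5, 5, 5)) > 0.4
        mask = VoxelMask(Point3D(0, 0, 0), (1.0, 2.0, 0.5), occ)
        out = shift_mask(mask, Point3D(sx, sy, sz), pad=True)
        assert out.n_occupied == mask.n_occupied


class TestUnion:
    def test_identical_inputs_unchanged(self):
        mask = _ball(3.0)
        out = union_masks([mask, mask, mask])
        assert np.array_equal(out.occupancy, mask.occupancy)

    def test_disjoint_blobs_add_volumes(self):
        a = _ball(2.0, pad=8)
        b = shift_mask(a, Point3D(7.0, 0.0, 0.0))
        out = union_masks([a, b])
        assert out.n_occupied == a.n_occupied + b.n_occupied

    def test_overlapping_spheres_match_voxelwise_or(self):
        a = _ball(4.0, pad=6)
        b = _ball(4.0, pad=6, center=(3.0, 1.0, 0.0))
        out = union_masks([a, b])
        # brute-force oracle: per-voxel OR over explicit loop
        count = 0
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                for k in range(a.shape[2]):
                    if a.occupancy[i, j, k] or b.occupancy[i, j, k]:
                        count += 1
        assert out.n_occupied == count

    def test_grid_mismatch_rejected(self):
        a = _ball(2.0)
        b = VoxelMask(Point3D(0.5, 0, 0), a.spacing, a.occupancy)
        with pytest.raises(ValueError, match="shared grid"):
            union_masks([a, b])

    def test_union_bounds_hold_on_phantom(self):
        study = build_phantom(make_lagged_spec(lag=0.08), "u")
        union = build_gtv_union_shift(study)
        per_phase = [m.n_occupied for m in study.gtv_masks]
        assert max(per_phase) <= union.n_occupied <= sum(per_phase)


class TestExpand:
    def test_zero_margins_identity(self):
        mask = _ball(3.0)
        assert expand_mask(mask, MarginSpec(0, 0, 0)) is mask

    def test_single_voxel_isotropic_expansion_is_digitized_ball(self):
        occ = np.zeros((1, 1, 1), dtype=bool)
        occ[0, 0, 0] = True
        mask = VoxelMask(Point3D(0, 0, 0), (1, 1, 1), occ)
        out = expand_mask(mask, MarginSpec.isotropic(5.0))
        # brute-force oracle: voxel centers within 5 mm of the origin
        centers = out.occupied_centers_mm()
        assert np.all(np.linalg.norm(centers, axis=1) <= 5.0 + 1e-9)
        ax = np.arange(-6, 7)
        d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
        assert out.n_occupied == int((d2 <= 25.0 + 1e-9).sum())

    def test_anisotropic_expansion_respects_zero_axis(self):
        occ = np.zeros((1, 1, 1), dtype=bool)
        occ[0, 0, 0] = True
        mask = VoxelMask(Point3D(0, 0, 0), (1, 1, 1), occ)
        out = expand_mask(mask, MarginSpec(0.0, 2.0, 4.0))
        centers = out.occupied_centers_mm()
        assert np.all(centers[:, 0] == 0.0)  # no LR growth
        assert centers[:, 1].max() == 2.0 and centers[:, 2].max() == 4.0

    def test_expanded_sphere_contains_larger_digitized_sphere(self):
        r, m, spacing = 5.0, 3.0, 1.0
        out = expand_mask(_ball(r, spacing), MarginSpec.isotropic(m))
        inner = _ball(r + m - spacing, spacing, pad=2 + int(m))
        out_e, inner_e = embed_common([out, inner])
        assert not np.any(inner_e.occupancy & ~out_e.occupancy)

    @pytest.mark.parametrize("margins_small,margins_big", [
        (MarginSpec(1, 1, 1), MarginSpec(2, 1, 1)),
        (MarginSpec(0, 2, 3), MarginSpec(1, 2, 3)),
        (MarginSpec(2, 2, 2), MarginSpec(3, 4, 5)),
    ])
    def test_monotone_in_every_margin_component(self, margins_small, margins_big):
        mask = _ball(3.0)
        small = expand_mask(mask, margins_small)
        big = expand_mask(mask, margins_big)
        small_e, big_e = embed_common([small, big])
        assert not np.any(small_e.occupancy & ~big_e.occupancy)


class TestTargets:
    def test_static_study_union_equals_reference(self, static_study):
        union = build_gtv_union_shift(static_study)
        ref = static_study.reference_mask
        union_e, ref_e = embed_common([union, ref])
        assert np.array_equal(union_e.occupancy, ref_e.occupancy)

    def test_synchronous_phantom_union_close_to_reference(self):
        spec = make_lagged_spec(amp_si=10.0, lag=0.0, spacing=1.0)
        study = build_phantom(spec, "sync")
        union = build_gtv_union_shift(study)
        ratio = union.volume_mm3 / study.reference_mask.volume_mm3
        assert 1.0 <= ratio < 1.15  # only rasterization-scale growth

    def test_si_residual_elongates_union_by_residual(self):
        spec = make_lagged_spec(amp_si=10.0, lag=0.1, spacing=1.0)
        study = build_phantom(spec, "lag")
        union = build_gtv_union_shift(study)
        t = np.arange(10) / 10
        rel = 10 * (np.sin(2 * np.pi * t) - np.sin(2 * np.pi * (t + 0.1)))
        rel -= rel[3]
        expected_growth = rel.max() - rel.min()  # peak-to-peak SI residual
        si_extent = lambda m: np.ptp(np.argwhere(m.occupancy)[:, 2]) * m.spacing[2]
        growth = si_extent(union) - si_extent(study.reference_mask)
        # one voxel of snap + digitization slack at each of the two extremes
        assert growth == pytest.approx(expected_growth, abs=2.0)

    def test_target_set_invariants_and_trivial_comparison(self, static_study):
        ts = build_target_set(static_study, MarginSpec(0, 0, 0), ptv_margin_mm=0.0)
        cmp_ = compare_targets(ts)
        assert cmp_.r_v_union_ref == pytest.approx(1.0)
        assert cmp_.centroid_distance_mm == pytest.approx(0.0, abs=1e-9)
        assert cmp_.coverage_fraction_geometric == 1.0

    def test_inclusion_violation_rejected(self):
        big = _ball(4.0)
        small = _ball(2.0)
        small_e, big_e = embed_common([small, big])
        with pytest.raises(ValueError, match="contained"):
            TargetSet(big_e, big_e, small_e, big_e, MarginSpec(0, 0, 0), 0.0)

    def test_exceedance_phantom_is_under_covered(self):
        """Asynchrony built to exceed the applied margins: part of the union
        must fall outside the PTV, and the exact uncovered voxel count comes
        from an explicit intersection loop."""
        spec = make_lagged_spec(amp_si=12.0, lag=0.25, spacing=1.0)
        study = build_phantom(spec, "exceed")
        ts = build_target_set(study, MarginSpec(2.0, 2.1, 3.2), ptv_margin_mm=5.0)
        cmp_ = compare_targets(ts)
        assert cmp_.coverage_fraction_geometric < 1.0
        assert not cmp_.fully_covered
        inside = int((ts.gtv_union_shift.occupancy & ts.ptv_tle_ref.occupancy).sum())
        assert cmp_.coverage_fraction_geometric == pytest.approx(
            inside / ts.gtv_union_shift.n_occupied
        )

    def test_coverage_complete_when_margins_exceed_residual(self):
        spec = make_lagged_spec(amp_si=10.0, lag=0.05, spacing=1.0)
        study = build_phantom(spec, "cover")
        resid = analytic_residual_rmse(spec, ["m1", "m2"])  # noise-free oracle
        assert resid[2] < 3.2 + 5.0 - 1.0  # residual below margin budget
        ts = build_target_set(study, MarginSpec(2.0, 2.1, 3.2), ptv_margin_mm=5.0)
        assert compare_targets(ts).coverage_fraction_geometric == 1.0
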