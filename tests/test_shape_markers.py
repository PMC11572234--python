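"""Shape markers: surface area, hulls, solidity/convexity/CI, FD, eccentricity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmhshape.mask_model import connected_components
from wmhshape.shape_markers import (
    box_counts,
    component_markers,
    concavity_index,
    convex_hull_metrics,
    convexity,
    eccentricity,
    fractal_dimension,
    participant_markers,
    solidity,
    surface_area,
    voxel_face_area,
)
from wmhshape.wmh_typing import type_wmh

from conftest import digitized_ball, make_mask


def cuboid(a, b, c, pad=2):
    arr = np.zeros((a + 2 * pad, b + 2 * pad, c + 2 * pad), dtype=bool)
    arr[pad : pad + a, pad : pad + b, pad : pad + c] = True
    return arr


class TestSurfaceArea:
    def test_ball_close_to_sphere_area(self, ball_r10):
        area = surface_area(ball_r10, (1, 1, 1))
        assert area == pytest.approx(4 * np.pi * 100, rel=0.03)

    def test_single_voxel_bounded_by_face_area(self):
        arr = np.zeros((3, 3, 3), dtype=bool)
        arr[1, 1, 1] = True
        area = surface_area(arr, (1, 1, 1))
        assert 0 < area <= 6.0

    def test_similarity_scaling(self, ball_r10):
        a1 = surface_area(ball_r10, (1, 1, 1))
        a2 = surface_area(ball_r10, (2, 2, 2))
        assert a2 == pytest.approx(4 * a1, rel=1e-6)

    def test_voxel_faces_overestimate_smooth_surface(self, ball_r10):
        mc = surface_area(ball_r10, (1, 1, 1))
        faces = voxel_face_area(ball_r10, (1, 1, 1))
        assert faces > 1.3 * mc

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            surface_area(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))


class TestConvexHull:
    def test_cuboid_exact(self):
        a, b, c = 5, 6, 7
        vh, sh = convex_hull_metrics(cuboid(a, b, c), (1, 1, 1))
        assert vh == pytest.approx(a * b * c)
        assert sh == pytest.approx(2 * (a * b + b * c + c * a))

    def test_cuboid_exact_anisotropic(self):
        # 4x3x2 voxels at 1x2x3 mm -> 4x6x6 mm box
        vh, sh = convex_hull_metrics(cuboid(4, 3, 2), (1.0, 2.0, 3.0))
        assert vh == pytest.approx(4 * 6 * 6)
        assert sh == pytest.approx(2 * (4 * 6 + 6 * 6 + 6 * 4))

    def test_ball_hull_volume_close_to_analytic(self, ball_r10):
        vh, _ = convex_hull_metrics(ball_r10, (1, 1, 1))
        assert vh == pytest.approx(4 / 3 * np.pi * 1000, rel=0.03)

    def test_single_voxel_positive_hull(self):
        arr = np.zeros((3, 3, 3), dtype=bool)
        arr[1, 1, 1] = True
        vh, sh = convex_hull_metrics(arr, (1, 1, 1))
        assert vh == pytest.approx(1.0)
        assert sh == pytest.approx(6.0)

    def test_two_separated_voxels_hull_spans_gap(self):
        arr = np.zeros((9, 3, 3), dtype=bool)
        arr[1, 1, 1] = arr[7, 1, 1] = True
        vh, _ = convex_hull_metrics(arr, (1, 1, 1))
        assert vh > 2.0  # more than the two voxel volumes

    def test_hull_dominates_volume(self, rng):
        for _ in range(10):
            arr = rng.random((9, 9, 9)) < 0.3
            if not arr.any():
                continue
            sub = connected_components(make_mask(arr), 26)
            comp = sub.labels == 1
            vh, _ = convex_hull_metrics(comp, (1, 1, 1))
            assert vh >= comp.sum() - 1e-9


class TestRatios:
    def test_solid_cuboid_solidity_one(self):
        arr = cuboid(5, 6, 7)
        vh, _ = convex_hull_metrics(arr, (1, 1, 1))
        assert solidity(float(arr.sum()), vh) == pytest.approx(1.0)

    def test_notched_cuboid_less_solid(self):
        arr = cuboid(8, 8, 8)
        notch = arr.copy()
        notch[5:9, 5:9, 2:10] = False  # corner bite
        vh_full, _ = convex_hull_metrics(arr, (1, 1, 1))
        vh_notch, _ = convex_hull_metrics(notch, (1, 1, 1))
        s = solidity(float(notch.sum()), vh_notch)
        assert s < 1.0

    def test_ball_convexity_near_one(self, ball_r10):
        m = component_markers(ball_r10, (1, 1, 1))
        assert 0.9 <= m["convexity"] <= 1.1

    def test_cratered_ball_lower_convexity(self, ball_r10):
        dented = ball_r10.copy()
        c = ball_r10.shape[0] // 2
        # carve deep 3x3 craters at the six poles: hull barely changes,
        # surface area grows, so convexity must drop
        for axis in range(3):
            for side in (slice(0, c - 4), slice(c + 5, None)):
                sl = [slice(c - 1, c + 2)] * 3
                sl[axis] = side
                dented[tuple(sl)] = False
        m_ball = component_markers(ball_r10, (1, 1, 1))
        m_dent = component_markers(dented, (1, 1, 1))
        assert m_dent["convexity"] < m_ball["convexity"]
        assert m_dent["solidity"] < m_ball["solidity"]
        assert m_dent["concavity_index"] > m_ball["concavity_index"]

    def test_concavity_index_plugin_values(self):
        assert concavity_index(1.0, 1.0) == pytest.approx(1.0)
        assert concavity_index(1.03, 0.19) == pytest.approx(1.78)

    def test_scale_invariance_of_all_markers(self, ball_r10):
        m1 = component_markers(ball_r10, (1, 1, 1))
        m2 = component_markers(ball_r10, (3.5, 3.5, 3.5))
        for key in ("solidity", "convexity", "concavity_index",
                    "fractal_dimension", "eccentricity"):
            assert m2[key] == pytest.approx(m1[key], rel=1e-6), key


class TestFractalDimension:
    @pytest.mark.parametrize(
        "shape,expected",
        [((8, 8, 8), 3.0), ((16, 16, 1), 2.0), ((16, 1, 1), 1.0)],
    )
    def test_closed_forms_exact(self, shape, expected):
        arr = np.ones(shape, dtype=bool)
        assert fractal_dimension(arr) == pytest.approx(expected, abs=1e-9)

    def test_padding_invariance(self):
        arr = np.ones((8, 8, 8), dtype=bool)
        padded = np.pad(arr, 7)
        assert fractal_dimension(padded) == pytest.approx(
            fractal_dimension(arr), abs=1e-12
        )

    def test_counts_follow_power_law_for_cube(self):
        counts = dict(box_counts(np.ones((8, 8, 8), dtype=bool)))
        assert counts == {1: 512, 2: 64, 4: 8}

    def test_single_voxel_rejected(self):
        arr = np.zeros((3, 3, 3), dtype=bool)
        arr[1, 1, 1] = True
        with pytest.raises(ValueError, match="scale"):
            fractal_dimension(arr)

    def test_clamped_to_three(self):
        # any occupancy slope is <= 3; the clamp guards numerics
        assert 0.0 <= fractal_dimension(np.ones((32, 32, 32), dtype=bool)) <= 3.0


class TestEccentricity:
    def test_ball_nearly_isotropic(self, ball_r10):
        assert eccentricity(ball_r10, (1, 1, 1)) < 0.2

    def test_rod_nearly_one(self):
        arr = np.ones((1, 1, 50), dtype=bool)
        e = eccentricity(arr, (1, 1, 1))
        assert 0.99 < e < 1.0

    def test_single_voxel_zero(self):
        arr = np.zeros((3, 3, 3), dtype=bool)
        arr[1, 1, 1] = True
        assert eccentricity(arr, (1, 1, 1)) == 0.0

    def test_axis_permutation_invariance(self, rng):
        arr = rng.random((7, 9, 11)) < 0.4
        arr[3, 4, 5] = True
        e1 = eccentricity(arr, (1, 1, 1))
        e2 = eccentricity(np.transpose(arr, (2, 0, 1)), (1, 1, 1))
        assert e2 == pytest.approx(e1, rel=1e-12)

    def test_elongated_ellipsoid_more_eccentric_than_ball(self):
        n = 25
        idx = np.indices((n, n, n)).astype(float) - n // 2
        rod_like = (idx[0] / 10) ** 2 + (idx[1] / 2) ** 2 + (idx[2] / 2) ** 2 <= 1
        ball = (idx**2).sum(0) <= 36
        assert eccentricity(rod_like, (1, 1, 1)) > eccentricity(ball, (1, 1, 1))

    @given(st.integers(2, 30))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_bounded_below_one(self, length):
        arr = np.ones((1, 1, length), dtype=bool)
        assert 0.0 <= eccentricity(arr, (1, 1, 1)) < 1.0


class TestParticipantAggregation:
    def _scene(self):
        shape = (40, 24, 24)
        vent = np.zeros(shape, dtype=bool)
        vent[0:2] = True
        wmh = np.zeros(shape, dtype=bool)
        wmh[3:6, 4:7, 4:7] = True      # periventricular
        wmh[25:29, 4:8, 4:8] = True    # deep
        wmh[25:31, 14:18, 14:18] = True  # deep
        return make_mask(wmh), make_mask(vent)

    def test_deep_markers_mean_over_components(self):
        wmh, vent = self._scene()
        labels, comps, typed = type_wmh(wmh, vent)
        ms = participant_markers(typed, labels)
        assert ms.n_deep == 2 and ms.n_pvc == 1
        per = [
            component_markers(labels.labels == c.component_id, (1.0, 1.0, 1.0))
            for c in typed.deep
        ]
        want_ecc = np.mean([p["eccentricity"] for p in per])
        assert ms.eccentricity == pytest.approx(want_ecc)
        want_fd = np.mean([p["fractal_dimension"] for p in per])
        assert ms.fd_deep == pytest.approx(want_fd)

    def test_single_pvc_component_identity(self):
        wmh, vent = self._scene()
        labels, comps, typed = type_wmh(wmh, vent)
        ms = participant_markers(typed, labels)
        only = component_markers(
            labels.labels == typed.pv_confluent[0].component_id, (1.0, 1.0, 1.0)
        )
        assert ms.solidity == pytest.approx(only["solidity"])
        assert ms.concavity_index == pytest.approx(only["concavity_index"])

    def test_absent_type_gives_nan_markers(self):
        shape = (40, 24, 24)
        vent = np.zeros(shape, dtype=bool)
        vent[0:2] = True
        wmh = np.zeros(shape, dtype=bool)
        wmh[3:6, 4:7, 4:7] = True  # periventricular only
        labels, comps, typed = type_wmh(make_mask(wmh), make_mask(vent))
        ms = participant_markers(typed, labels)
        assert ms.n_deep == 0
        assert math.isnan(ms.eccentricity) and math.isnan(ms.fd_deep)
        assert not math.isnan(ms.solidity)

    def test_subvoxel_components_skipped_and_counted(self):
        shape = (40, 24, 24)
        vent = np.zeros(shape, dtype=bool)
        vent[0:2] = True
        wmh = np.zeros(shape, dtype=bool)
        wmh[3:6, 4:7, 4:7] = True
        wmh[30, 20, 20] = True  # lone voxel, below scoring threshold
        labels, comps, typed = type_wmh(make_mask(wmh), make_mask(vent))
        ms = participant_markers(typed, labels)
        assert ms.n_skipped == 1
        assert ms.n_deep == 0
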