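"""Distance maps, ROI sampling/classification and the six measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulmolymph.core import (
    LABEL_INTERSTITIUM,
    LABEL_LYMPH,
    LABEL_PLEURA,
    LabelVolume,
)
from pulmolymph.morphometry import (
    ROI,
    classify_rois,
    fractal_dimension,
    measure_voi,
    measure_volume_surface,
    pleural_distance_map,
    sample_rois,
    skeleton_metrics,
    voi_covering,
)
from pulmolymph.synthetic import generate_validation_geometry


def _slab_volume(shape=(32, 32, 32), pitch=10.0, pleura_z=1):
    labels = np.full(shape, LABEL_INTERSTITIUM, dtype=np.uint8)
    labels[:pleura_z] = LABEL_PLEURA
    return LabelVolume(labels, pitch, pleural_direction="-z")


class TestPleuralDistance:
    def test_flat_plane_gives_linear_depth(self):
        vol = _slab_volume(pleura_z=1, pitch=10.0)
        dist = pleural_distance_map(vol)
        for z in range(1, 8):
            assert np.allclose(dist[z], (z - 0) * 10.0)
        assert np.all(dist[0] == 0.0)

    def test_face_adjacent_voxel_distance_is_one_pitch(self):
        vol = _slab_volume(pitch=13.2)
        assert np.allclose(pleural_distance_map(vol)[1], 13.2)

    def test_spherical_shell_distance_is_radial(self):
        n = 48
        zz, yy, xx = np.meshgrid(*([np.arange(n)] * 3), indexing="ij")
        rho = np.sqrt((zz - 24.0)**2 + (yy - 24.0)**2 + (xx - 24.0)**2)
        labels = np.full((n, n, n), LABEL_INTERSTITIUM, dtype=np.uint8)
        shell = (rho >= 20) & (rho < 21)
        labels[shell] = LABEL_PLEURA
        vol = LabelVolume(labels, 1.0, pleural_direction="-z")
        dist = pleural_distance_map(vol)
        interior = rho < 18
        assert np.all(np.abs(dist[interior] - (20 - rho[interior])) <= 1.5)

    def test_no_reference_raises(self):
        labels = np.full((8, 8, 8), LABEL_INTERSTITIUM, dtype=np.uint8)
        vol = LabelVolume(labels, 1.0)
        with pytest.raises(ValueError):
            pleural_distance_map(vol)


class TestSampler:
    def test_packing_bound_triggers_shortfall(self):
        vol = _slab_volume(shape=(4, 100, 100), pleura_z=0, pitch=1.0)
        vol = LabelVolume(vol.labels, 1.0, pleural_direction="-z")
        res = sample_rois(vol, z_plane=1, roi_side_um=50, n_target=5,
                          max_iter=500, seed=0)
        assert len(res.rois) <= 4
        assert res.shortfall

    def test_single_roi_in_bounds(self):
        vol = _slab_volume(shape=(8, 64, 64), pleura_z=0)
        res = sample_rois(vol, z_plane=2, roi_side_um=160, n_target=1, seed=1)
        assert len(res.rois) == 1
        roi = res.rois[0]
        assert 0 <= roi.origin[0] <= 64 - roi.side_vox
        assert 0 <= roi.origin[1] <= 64 - roi.side_vox

    def test_seed_reproducible_and_pairwise_disjoint(self):
        vol = _slab_volume(shape=(8, 96, 96), pleura_z=0)
        a = sample_rois(vol, 2, roi_side_um=100, n_target=10, seed=42)
        b = sample_rois(vol, 2, roi_side_um=100, n_target=10, seed=42)
        assert [r.origin for r in a.rois] == [r.origin for r in b.rois]
        for i, r in enumerate(a.rois):
            for s in a.rois[i + 1:]:
                assert not r.overlaps(s)

    def test_roi_larger_than_plane_rejected(self):
        vol = _slab_volume(shape=(8, 16, 16))
        with pytest.raises(ValueError):
            sample_rois(vol, 2, roi_side_um=1000, n_target=1, seed=0)


class TestClassification:
    @pytest.mark.parametrize("median_um,expected", [
        (0.0, "subpleural"),
        (829.9, "subpleural"),
        (830.0, "intralobular"),   # strict less-than threshold
        (5000.0, "intralobular"),
    ])
    def test_threshold_is_strict(self, median_um, expected):
        vol = _slab_volume(shape=(8, 32, 32), pleura_z=0, pitch=10.0)
        dist = np.full(vol.shape, median_um)
        recs = classify_rois([ROI(origin=(4, 4), side_vox=8, z0=2)], vol,
                             dist)
        assert recs[0].region_class == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=3000))
    def test_classification_is_pure_threshold_function(self, med):
        vol = _slab_volume(shape=(8, 32, 32), pleura_z=0, pitch=10.0)
        dist = np.full(vol.shape, med)
        rec = classify_rois([ROI(origin=(0, 0), side_vox=8, z0=1)], vol,
                            dist)[0]
        assert (rec.region_class == "subpleural") == (med < 830.0)


class TestVolumeSurface:
    def test_zero_lymph_voi(self):
        vol = _slab_volume()
        rec = measure_volume_surface(vol, voi_covering(vol))
        assert rec.volume_fraction == 0.0
        assert rec.surface_area == 0.0

    def test_all_lymph_gives_vf_one(self):
        labels = np.full((16, 16, 16), LABEL_LYMPH, dtype=np.uint8)
        vol = LabelVolume(labels, 1.0, pleural_direction="-z")
        rec = measure_volume_surface(vol, voi_covering(vol))
        assert rec.volume_fraction == 1.0

    def test_digital_sphere_surface_area_within_five_percent(self):
        n, r = 32, 10
        zz, yy, xx = np.meshgrid(*([np.arange(n)] * 3), indexing="ij")
        labels = np.full((n, n, n), LABEL_INTERSTITIUM, dtype=np.uint8)
        labels[(zz - 16.0)**2 + (yy - 16.0)**2 + (xx - 16.0)**2 <= r * r] = \
            LABEL_LYMPH
        vol = LabelVolume(labels, 1.0, pleural_direction="-z")
        rec = measure_volume_surface(vol, voi_covering(vol))
        assert abs(rec.surface_area - 4 * np.pi * r * r) <= 0.05 * 4 * np.pi * r * r

    def test_vf_identity_and_dilation_monotonicity(self, intralobular_voi):
        from scipy import ndimage
        vol, _ = intralobular_voi
        rec = measure_volume_surface(vol, voi_covering(vol))
        assert rec.volume_fraction == pytest.approx(
            rec.lymph_volume / rec.tissue_volume)
        assert 0.0 <= rec.volume_fraction <= 1.0
        grown = vol.labels.copy()
        grown[ndimage.binary_dilation(vol.labels == LABEL_LYMPH)] = LABEL_LYMPH
        vol2 = LabelVolume(grown, vol.voxel_pitch, vol.pleural_direction)
        rec2 = measure_volume_surface(vol2, voi_covering(vol2))
        assert rec2.lymph_volume >= rec.lymph_volume


class TestFractal:
    def test_space_filling_limits(self):
        full = np.ones((64, 64, 64), bool)
        d, ex = fractal_dimension(full)
        assert not ex and abs(d - 3.0) <= 0.1
        plane = np.zeros((64, 64, 64), bool)
        plane[32] = True
        d, ex = fractal_dimension(plane)
        assert not ex and abs(d - 2.0) <= 0.15
        line = np.zeros((64, 64, 64), bool)
        line[:, 32, 32] = True
        d, ex = fractal_dimension(line)
        assert not ex and abs(d - 1.0) <= 0.15

    def test_degenerate_masks_are_excluded_not_raised(self):
        empty = np.zeros((32, 32, 32), bool)
        assert fractal_dimension(empty) == (None, True)
        single = np.zeros((64, 64, 64), bool)
        single[3, 3, 3] = True
        assert fractal_dimension(single)[1] is True
        tiny = np.zeros((8, 8, 8), bool)   # < 3 usable box sizes
        tiny[2:4, 2:4, 2:4] = True
        assert fractal_dimension(tiny)[1] is True


class TestSkeleton:
    def test_straight_tube_one_branch_no_junction(self):
        vol = generate_validation_geometry("tube", radius=3, length=50,
                                           axis=0)
        _, branches, junctions, tort = skeleton_metrics(
            vol.labels == LABEL_LYMPH, 1.0)
        assert (branches, junctions) == (1, 0)
        assert tort == pytest.approx(1.0, abs=0.02)

    def test_symmetric_y_three_branches_one_junction(self):
        vol = generate_validation_geometry("y_tube", radius=3, size=64)
        _, branches, junctions, _ = skeleton_metrics(
            vol.labels == LABEL_LYMPH, 1.0)
        assert (branches, junctions) == (3, 1)

    def test_quarter_arc_tortuosity_matches_arc_over_chord(self):
        vol = generate_validation_geometry("arc_tube", arc_radius=40,
                                           radius=3)
        _, _, _, tort = skeleton_metrics(vol.labels == LABEL_LYMPH, 1.0)
        expected = (np.pi / 2) / np.sqrt(2)
        assert abs(tort - expected) / expected <= 0.05

    def test_skeleton_voxels_partition_into_nodes_and_edges(self):
        vol = generate_validation_geometry("y_tube", radius=3, size=48)
        graph, *_ = skeleton_metrics(vol.labels == LABEL_LYMPH, 1.0)
        seen = {}
        for i, node in enumerate(graph.node_voxels):
            for v in map(tuple, node):
                assert v not in seen
                seen[v] = ("node", i)
        interior = set()
        for e in graph.edges:
            for v in map(tuple, e["path"][1:-1]):
                assert v not in seen or seen[v][0] == "node"
                if seen.get(v, ("edge",))[0] != "node":
                    assert v not in interior
                    interior.add(v)
        assert len(seen) + len(interior) == graph.n_skeleton_voxels

    def test_empty_mask_gives_zeros(self):
        _, b, j, t = skeleton_metrics(np.zeros((8, 8, 8), bool), 1.0)
        assert (b, j, t) == (0, 0, None)

    def test_edge_tortuosity_at_least_one(self, intralobular_voi):
        vol, _ = intralobular_voi
        graph, *_ = skeleton_metrics(vol.labels == LABEL_LYMPH,
                                     vol.voxel_pitch)
        for e in graph.edges:
            if e["tortuosity"] is not None:
                assert e["tortuosity"] >= 1.0 - 1e-9


class TestMeasureVOI:
    def test_all_interstitium_record(self):
        vol = _slab_volume(pleura_z=0)
        vol = LabelVolume(vol.labels, vol.voxel_pitch, "-z")
        rec = measure_voi(vol, voi_covering(vol))
        assert rec.volume_fraction == 0.0
        assert rec.excluded_fractal
        assert rec.branch_count == 0

    def test_known_straight_lymphatic_length_recovered(self):
        vol = generate_validation_geometry("tube", radius=3, length=60,
                                           axis=0, voxel_pitch=10.0)
        graph, b, j, _ = skeleton_metrics(vol.labels == LABEL_LYMPH, 10.0)
        assert b == 1
        # thinning erodes roughly one voxel per open end
        measured = graph.edges[0]["length_um"]
        assert abs(measured - 600.0) / 600.0 <= 0.05
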