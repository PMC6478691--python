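"""Model-volume preparation and vessel-opening identification."""

import numpy as np
import pytest

from pulmolymph.core import (
    LABEL_BLOOD,
    LABEL_INTERSTITIUM,
    LABEL_LYMPH,
    LabelVolume,
)
from pulmolymph.model_prep import (
    distal_faces,
    identify_vessel_openings,
    model_from_labels,
    prepare_model_volume,
)
from pulmolymph.synthetic import generate_voi, intralobular_spec, subpleural_spec


def _cube(n=24, fill=LABEL_INTERSTITIUM):
    return np.full((n, n, n), fill, dtype=np.uint8)


def test_upsampling_preserves_volume_fractions_exactly():
    labels = _cube()
    labels[4:8, 4:8, 4:8] = LABEL_BLOOD
    labels[10:12, 10:20, 10:20] = LABEL_LYMPH
    vol = LabelVolume(labels, 13.2, "-z")
    base = prepare_model_volume(vol, voi=None, upsample=1, median_window=1)
    up = prepare_model_volume(vol, voi=None, upsample=3, median_window=1)
    for cls in ("blood", "lymph", "interstitium", "air"):
        f0 = base.class_mask(cls).mean()
        f3 = up.class_mask(cls).mean()
        assert f3 == pytest.approx(f0, abs=0)
    assert up.voxel_pitch == pytest.approx(13.2 / 3)


def test_isolated_island_removed_and_counted():
    labels = _cube()
    labels[12, 12, 12] = LABEL_BLOOD           # 1-voxel interior island
    labels[:, 2:5, 2:5] = LABEL_LYMPH          # face-connected column kept
    vol = LabelVolume(labels, 13.2, "-z")
    model = prepare_model_volume(vol, voi=None, upsample=3, median_window=1)
    assert model.provenance["removed_component_voxels"]["blood"] == 27
    assert not model.blood.any()
    assert model.lymph.any()


def test_overlap_precedence_lymph_over_blood():
    labels = _cube()
    # adjacent slabs that blur into each other under the median filter
    labels[:, 6:10, :] = LABEL_BLOOD
    labels[:, 10:14, :] = LABEL_LYMPH
    vol = LabelVolume(labels, 13.2, "-z")
    model = prepare_model_volume(vol, voi=None, upsample=1, median_window=3)
    assert not (model.blood & model.lymph).any()
    total = (model.blood.astype(int) + model.lymph.astype(int)
             + model.interstitium.astype(int) + model.air.astype(int))
    assert (total == 1).all()


def test_shrinkage_scale_doubles_pitch_not_counts():
    labels = _cube()
    labels[4:8, 4:8, 4:8] = LABEL_BLOOD
    vol = LabelVolume(labels, 13.2, "-z")
    a = prepare_model_volume(vol, voi=None, upsample=1, median_window=1,
                             shrinkage_scale=1.0)
    b = prepare_model_volume(vol, voi=None, upsample=1, median_window=1,
                             shrinkage_scale=2.0)
    assert b.voxel_pitch == pytest.approx(2 * a.voxel_pitch)
    assert b.blood.sum() == a.blood.sum()


def test_pruning_never_removes_face_connected_components():
    from scipy import ndimage
    vol, _ = generate_voi(intralobular_spec(shape=(48, 48, 48), seed=2))
    model = prepare_model_volume(vol, voi=None, upsample=1, median_window=1)
    for cls in ("blood", "lymph"):
        mask = model.class_mask(cls)
        before = vol.labels == (LABEL_BLOOD if cls == "blood" else LABEL_LYMPH)
        # independent flood fill from the faces
        border = np.zeros_like(before)
        border[0], border[-1] = True, True
        border[:, 0], border[:, -1] = True, True
        border[:, :, 0], border[:, :, -1] = True, True
        keep = ndimage.binary_propagation(border & before, mask=before,
                                          structure=np.ones((3, 3, 3)))
        assert (mask == keep).all()


def test_distal_faces_are_opposite_plus_two_laterals():
    faces = distal_faces((48, 48, 48), "-z")
    assert faces[0] == "+z"
    assert set(faces[1:]) <= {"-y", "+y", "-x", "+x"}
    assert len(set(faces)) == 3


@pytest.mark.parametrize("spec_fn,expected", [
    (intralobular_spec, (1, 4)),
    (subpleural_spec, (6, 3)),
])
def test_opening_identification_matches_generator(spec_fn, expected):
    vol, _ = generate_voi(spec_fn(shape=(48, 48, 48), seed=2))
    model = prepare_model_volume(vol, voi=None, upsample=1, median_window=1)
    bounds = identify_vessel_openings(model, "-z")
    n_lymph, n_blood = expected
    assert len(bounds.inlets["lymph"]) == n_lymph
    assert len(bounds.inlets["blood"]) == n_blood


def test_tube_spanning_pleural_to_distal_gets_one_inlet_one_outlet():
    labels = _cube()
    yy, xx = np.meshgrid(np.arange(24), np.arange(24), indexing="ij")
    labels[:, np.hypot(yy - 12, xx - 12) <= 3] = LABEL_BLOOD
    vol = LabelVolume(labels, 13.2, "-z")
    model = model_from_labels(vol)
    bounds = identify_vessel_openings(model, "-z")
    assert len(bounds.inlets["blood"]) == 1    # +z distal face
    assert len(bounds.outlets["blood"]) == 1   # -z pleural face


def test_missing_inlet_raises_named_error():
    labels = _cube()
    labels[0:10, 10:14, 10:14] = LABEL_BLOOD   # opens only on pleural face
    vol = LabelVolume(labels, 13.2, "-z")
    model = model_from_labels(vol)
    with pytest.raises(ValueError, match="blood"):
        identify_vessel_openings(model, "-z")


def test_opening_partition_covers_all_boundary_lumen_faces(intralobular_voi):
    vol, _ = intralobular_voi
    model = prepare_model_volume(vol, voi=None, upsample=1, median_window=1)
    bounds = identify_vessel_openings(model, "-z")
    for cls in ("blood", "lymph"):
        mask = model.class_mask(cls)
        boundary_count = int(mask[0].sum() + mask[-1].sum()
                             + mask[:, 0].sum() + mask[:, -1].sum()
                             + mask[:, :, 0].sum() + mask[:, :, -1].sum())
        patch_cells = [len(p) for p in bounds.inlets[cls]] + \
                      [len(p) for p in bounds.outlets[cls]]
        assert sum(patch_cells) == boundary_count


def test_non_cubic_whole_volume_rejected():
    labels = np.full((10, 24, 24), LABEL_INTERSTITIUM, dtype=np.uint8)
    vol = LabelVolume(labels, 13.2, "-z")
    with pytest.raises(ValueError, match="cubic"):
        prepare_model_volume(vol, voi=None)
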