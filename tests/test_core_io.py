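import json

import numpy as np
import pytest

from petref.core_io import (
    CohortTable,
    DynamicImage,
    FrameSchedule,
    LabelAtlas,
    StaticImage,
    SubjectRecord,
    default_frame_schedule,
    erode_mask,
    frames_in_window,
    read_atlas,
    read_cohort_table,
    read_dynamic_image,
    region_mean,
    time_weighted_mean_image,
    write_atlas,
    write_cohort_table,
    write_dynamic_image,
)
from petref.errors import FormatError, ValidationError

import pandas as pd


# ---------------------------------------------------------------------------
# FrameSchedule / default schedule
# ---------------------------------------------------------------------------

# the published 35-frame schedule, written out independently of the package
PRINTED_DURATIONS = [5.0] * 12 + [10.0] * 6 + [20.0] * 3 + [60.0] * 7 + [300.0] * 4 + [600.0] * 3


def test_default_schedule_has_35_frames_totalling_3600_s():
    s = default_frame_schedule()
    assert s.n_frames == 35
    assert s.total_s == 3600.0
    assert np.array_equal(s.duration_s, PRINTED_DURATIONS)


def test_default_schedule_first_and_last_frames():
    s = default_frame_schedule()
    assert s.start_s[0] == 0.0 and s.duration_s[0] == 5.0
    # frame 34 start: cumulative sum of the printed durations
    assert s.start_s[34] == sum(PRINTED_DURATIONS[:34]) == 3000.0
    assert s.duration_s[34] == 600.0


def test_default_schedule_midpoints_strictly_increasing():
    s = default_frame_schedule()
    assert np.all(np.diff(s.midpoint_s) > 0)


def test_schedule_rejects_gap():
    with pytest.raises(ValidationError):
        FrameSchedule([0.0, 6.0], [5.0, 5.0])


def test_schedule_rejects_nonzero_start():
    with pytest.raises(ValidationError):
        FrameSchedule([1.0, 6.0], [5.0, 5.0])


def test_schedule_rejects_nonpositive_duration():
    with pytest.raises(ValidationError):
        FrameSchedule([0.0, 5.0], [5.0, 0.0])


# ---------------------------------------------------------------------------
# frames_in_window
# ---------------------------------------------------------------------------


def test_frames_in_window_20_40_min_oracle():
    # independent oracle: enumerate all 35 midpoints from the printed durations
    starts = np.concatenate([[0.0], np.cumsum(PRINTED_DURATIONS)[:-1]])
    mids = starts + np.asarray(PRINTED_DURATIONS) / 2
    expected = np.nonzero((mids >= 1200) & (mids < 2400))[0]
    got = frames_in_window(default_frame_schedule(), 1200, 2400)
    assert np.array_equal(got, expected)
    # the selected midpoints are 1350, 1650 (300 s frames) and 2100 (600 s frame)
    assert np.array_equal(mids[got], [1350.0, 1650.0, 2100.0])


def test_frames_in_window_full_window_selects_all():
    got = frames_in_window(default_frame_schedule(), 0, 3600)
    assert np.array_equal(got, np.arange(35))


def test_frames_in_window_empty_raises():
    with pytest.raises(ValidationError):
        frames_in_window(default_frame_schedule(), 3600, 4000)


def test_frames_in_window_monotone_in_window():
    s = default_frame_schedule()
    prev = set()
    for t1 in [600, 1200, 2400, 3600]:
        cur = set(frames_in_window(s, 0, t1).tolist())
        assert prev <= cur
        prev = cur


# ---------------------------------------------------------------------------
# time_weighted_mean_image
# ---------------------------------------------------------------------------


def _img_from_frames(frame_values, durations):
    durations = np.asarray(durations, float)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    sched = FrameSchedule(starts, durations)
    vox = np.zeros((2, 2, 2, len(frame_values)))
    for i, v in enumerate(frame_values):
        vox[..., i] = v
    return DynamicImage(vox, (1, 1, 1), sched)


def test_time_weighted_mean_constant():
    img = _img_from_frames([4.2, 4.2, 4.2], [5, 10, 20])
    out = time_weighted_mean_image(img, [0, 1, 2])
    assert np.allclose(out.voxels, 4.2)


def test_time_weighted_mean_hand_computed():
    img = _img_from_frames([1.0, 3.0], [100, 300])
    out = time_weighted_mean_image(img, [0, 1])
    assert np.allclose(out.voxels, 2.5)


def test_time_weighted_mean_equal_durations_reduces_to_plain_mean():
    img = _img_from_frames([1.0, 2.0, 6.0], [60, 60, 60])
    out = time_weighted_mean_image(img, [0, 1, 2])
    assert np.allclose(out.voxels, 3.0)


def test_time_weighted_mean_is_linear(rng):
    durations = [5, 10, 20, 60]
    a = rng.normal(size=(3, 3, 3, 4))
    b = rng.normal(size=(3, 3, 3, 4))
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    sched = FrameSchedule(starts, durations)
    mk = lambda v: DynamicImage(v, (1, 1, 1), sched)
    frames = [1, 2, 3]
    lhs = time_weighted_mean_image(mk(2 * a + 3 * b), frames).voxels
    rhs = 2 * time_weighted_mean_image(mk(a), frames).voxels + 3 * time_weighted_mean_image(mk(b), frames).voxels
    assert np.allclose(lhs, rhs)


# ---------------------------------------------------------------------------
# erode_mask
# ---------------------------------------------------------------------------


def brute_force_erode(mask, radius_mm, spacing):
    """Exhaustive oracle: keep a voxel iff every in-radius offset is inside."""
    spacing = np.asarray(spacing, float)
    r = np.ceil(radius_mm / spacing).astype(int)
    offsets = [
        (dx, dy, dz)
        for dx in range(-r[0], r[0] + 1)
        for dy in range(-r[1], r[1] + 1)
        for dz in range(-r[2], r[2] + 1)
        if (dx * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 + (dz * spacing[2]) ** 2
        <= radius_mm**2 + 1e-9
    ]
    out = np.zeros_like(mask)
    for idx in np.argwhere(mask):
        ok = True
        for off in offsets:
            j = idx + off
            if np.any(j < 0) or np.any(j >= np.asarray(mask.shape)) or not mask[tuple(j)]:
                ok = False
                break
        out[tuple(idx)] = ok
    return out


def test_erode_radius_zero_is_identity(rng):
    mask = rng.random((6, 6, 6)) > 0.5
    assert np.array_equal(erode_mask(mask, 0.0, (1, 1, 1)), mask)


def test_erode_cube_matches_brute_force_oracle():
    mask = np.zeros((9, 9, 9), dtype=bool)
    mask[2:7, 2:7, 2:7] = True  # 5x5x5 solid cube
    got = erode_mask(mask, 2.0, (1.0, 1.0, 1.0))
    expected = brute_force_erode(mask, 2.0, (1.0, 1.0, 1.0))
    assert np.array_equal(got, expected)
    assert got.sum() == expected.sum() == 1  # only the cube centre survives r=2


def test_erode_matches_oracle_anisotropic(rng):
    mask = rng.random((8, 8, 8)) > 0.35
    got = erode_mask(mask, 2.0, (1.0, 2.0, 2.0))
    assert np.array_equal(got, brute_force_erode(mask, 2.0, (1.0, 2.0, 2.0)))


def test_erode_single_voxel_empties_with_warning():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    with pytest.warns(UserWarning, match="empty"):
        out = erode_mask(mask, 2.0, (1, 1, 1))
    assert not out.any()


def test_erode_output_subset_of_input(rng):
    mask = rng.random((7, 7, 7)) > 0.3
    out = erode_mask(mask, 1.0, (1, 1, 1))
    assert not np.any(out & ~mask)


def test_erode_commutes_with_translation():
    mask = np.zeros((12, 12, 12), dtype=bool)
    mask[3:7, 3:7, 3:7] = True
    shifted = np.roll(mask, (2, 1, 1), axis=(0, 1, 2))
    a = np.roll(erode_mask(mask, 1.5, (1, 1, 1)), (2, 1, 1), axis=(0, 1, 2))
    b = erode_mask(shifted, 1.5, (1, 1, 1))
    assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# region_mean
# ---------------------------------------------------------------------------


def _atlas_2regions():
    labels = np.zeros((4, 4, 4), dtype=np.int32)
    labels[0, 0, 0] = 1
    labels[0, 0, 1] = 1
    labels[1, 1, 1] = 2
    table = pd.DataFrame(
        {"label": [1, 2], "name": ["a", "b"], "role": ["target", "other"]}
    )
    return LabelAtlas(labels, table, (1, 1, 1))


def test_region_mean_uniform():
    atlas = _atlas_2regions()
    img = StaticImage(np.full((4, 4, 4), 7.0), (1, 1, 1))
    assert region_mean(img, atlas, 1) == 7.0


def test_region_mean_two_voxels():
    atlas = _atlas_2regions()
    vox = np.zeros((4, 4, 4))
    vox[0, 0, 0], vox[0, 0, 1] = 1.0, 3.0
    assert region_mean(StaticImage(vox, (1, 1, 1)), atlas, 1) == 2.0


def test_region_mean_absent_label_raises():
    atlas = _atlas_2regions()
    img = StaticImage(np.zeros((4, 4, 4)), (1, 1, 1))
    with pytest.raises(ValidationError):
        region_mean(img, atlas, 99)


# ---------------------------------------------------------------------------
# file round-trips
# ---------------------------------------------------------------------------


def test_dynamic_image_round_trip(tmp_path, rng):
    sched = default_frame_schedule()
    vox = rng.normal(size=(5, 4, 3, 35)).astype(np.float32)
    img = DynamicImage(vox, (2.0, 2.0, 2.0), sched)
    write_dynamic_image(img, tmp_path / "x.nii", tmp_path / "x.json")
    back = read_dynamic_image(tmp_path / "x.nii", tmp_path / "x.json")
    assert np.array_equal(back.voxels, vox)  # bit-identical
    assert back.spacing_mm == img.spacing_mm
    assert np.array_equal(back.schedule.start_s, sched.start_s)
    assert np.array_equal(back.schedule.duration_s, sched.duration_s)


def test_read_dynamic_image_paper_schedule_total(tmp_path, rng):
    img = DynamicImage(
        rng.normal(size=(3, 3, 3, 35)).astype(np.float32), (2, 2, 2), default_frame_schedule()
    )
    write_dynamic_image(img, tmp_path / "y.nii", tmp_path / "y.json")
    back = read_dynamic_image(tmp_path / "y.nii", tmp_path / "y.json")
    assert back.schedule.total_s == 3600.0
    assert back.schedule.n_frames == 35


def test_read_dynamic_image_sidecar_mismatch_raises(tmp_path, rng):
    img = DynamicImage(
        rng.normal(size=(3, 3, 3, 35)).astype(np.float32), (2, 2, 2), default_frame_schedule()
    )
    write_dynamic_image(img, tmp_path / "z.nii", tmp_path / "z.json")
    sidecar = json.loads((tmp_path / "z.json").read_text())
    sidecar["FrameDuration"] = sidecar["FrameDuration"][:34]  # 34 durations, 35 frames
    (tmp_path / "bad.json").write_text(json.dumps(sidecar))
    with pytest.raises(FormatError):
        read_dynamic_image(tmp_path / "z.nii", tmp_path / "bad.json")


def test_atlas_round_trip(tmp_path):
    atlas = _atlas_2regions()
    write_atlas(atlas, tmp_path / "atlas.nii", tmp_path / "atlas.tsv")
    back = read_atlas(tmp_path / "atlas.nii", tmp_path / "atlas.tsv")
    assert np.array_equal(back.labels, atlas.labels)
    assert list(back.table["name"]) == list(atlas.table["name"])
    assert back.labels_with_role("target") == [1]


def test_cohort_table_round_trip(tmp_path):
    records = [
        SubjectRecord("s1", "PSP-RS", 70.0, "m", 35.0, "discovery"),
        SubjectRecord("s2", "HC", 65.5, "f", None, "validation"),
    ]
    readouts = pd.DataFrame({"pallidum_suvr_wmref": [1.5, 1.1]}, index=["s1", "s2"])
    table = CohortTable(records, readouts)
    write_cohort_table(table, tmp_path / "subjects.tsv")
    back = read_cohort_table(tmp_path / "subjects.tsv")
    assert back.record("s1").severity == 35.0
    assert back.record("s2").severity is None  # empty field round-trips as missing
    assert back.record("s2").split == "validation"
    assert np.allclose(back.readouts["pallidum_suvr_wmref"], [1.5, 1.1])


def test_atlas_rejects_unknown_voxel_label():
    labels = np.zeros((3, 3, 3), dtype=np.int32)
    labels[0, 0, 0] = 5
    table = pd.DataFrame({"label": [1], "name": ["a"], "role": ["target"]})
    with pytest.raises(ValidationError):
        LabelAtlas(labels, table)


def test_subject_record_validation():
    with pytest.raises(ValidationError):
        SubjectRecord("s", "NOPE", 70, "m")
    with pytest.raises(ValidationError):
        SubjectRecord("s", "HC", -1, "m")
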