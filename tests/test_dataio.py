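import json

import numpy as np
import pytest

from iscsync import (
    AtlasTable,
    RoiTimeseriesDataset,
    SegmentEntry,
    SegmentSchedule,
    extract_roi_timeseries,
    extract_segments,
    read_atlas_table,
    read_schedule_json,
    read_timeseries_table,
    stack_subjects,
    write_atlas_table,
    write_schedule_json,
    write_timeseries_table,
)
from iscsync.exceptions import (
    AlignmentError,
    DataFormatError,
    DimensionError,
    EmptySelectionError,
    ScheduleError,
)


class TestTimeseriesTable:
    def test_shape_follows_table_layout(self, tmp_path):
        path = tmp_path / "sub.tsv"
        path.write_text("r1\tr2\tr3\n1\t2\t3\n4\t5\t6\n7\t8\t9\n10\t11\t12\n")
        ds = read_timeseries_table(path, tr_seconds=2.0)
        assert ds.data.shape == (1, 3, 4)
        assert ds.roi_ids == ("r1", "r2", "r3")
        # column order preserved
        np.testing.assert_array_equal(ds.data[0, 0], [1, 4, 7, 10])

    def test_empty_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(DataFormatError):
            read_timeseries_table(path, tr_seconds=2.0)

    def test_header_only_is_a_format_error(self, tmp_path):
        path = tmp_path / "hdr.tsv"
        path.write_text("r1\tr2\n")
        with pytest.raises(DataFormatError):
            read_timeseries_table(path, tr_seconds=2.0)

    def test_non_numeric_cell_reports_row_and_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("r1\tr2\n1\t2\n3\toops\n")
        with pytest.raises(DataFormatError, match=r"oops.*row 1.*'r2'"):
            read_timeseries_table(path, tr_seconds=2.0)

    def test_ragged_rows_are_a_format_error(self, tmp_path):
        path = tmp_path / "ragged.tsv"
        path.write_text("r1\tr2\n1\t2\n3\n")
        with pytest.raises(DataFormatError):
            read_timeseries_table(path, tr_seconds=2.0)

    def test_write_read_round_trip_is_value_exact(self, tmp_path, rng):
        ds = RoiTimeseriesDataset(
            data=rng.standard_normal((1, 5, 17)),
            tr_seconds=2.0,
            subject_ids=("s1",),
        )
        path = tmp_path / "s1.tsv"
        write_timeseries_table(ds, path)
        back = read_timeseries_table(path, tr_seconds=2.0, subject_id="s1")
        np.testing.assert_array_equal(back.data, ds.data)
        assert back.roi_ids == ds.roi_ids


class TestDatasetInvariants:
    def test_duplicate_roi_ids_rejected(self, rng):
        with pytest.raises(DataFormatError):
            RoiTimeseriesDataset(
                data=rng.standard_normal((2, 2, 5)),
                tr_seconds=2.0,
                roi_ids=("a", "a"),
            )

    def test_nonpositive_tr_rejected(self, rng):
        with pytest.raises(DataFormatError):
            RoiTimeseriesDataset(data=rng.standard_normal((2, 2, 5)), tr_seconds=0)

    def test_stack_requires_matching_rois_and_lengths(self, rng):
        a = RoiTimeseriesDataset(
            rng.standard_normal((1, 3, 10)), 2.0, ("s1",), ("x", "y", "z")
        )
        b = RoiTimeseriesDataset(
            rng.standard_normal((1, 3, 10)), 2.0, ("s2",), ("x", "y", "w")
        )
        with pytest.raises(AlignmentError):
            stack_subjects([a, b])
        c = RoiTimeseriesDataset(
            rng.standard_normal((1, 3, 11)), 2.0, ("s2",), ("x", "y", "z")
        )
        with pytest.raises(AlignmentError):
            stack_subjects([a, c])
        stacked = stack_subjects(
            [a, RoiTimeseriesDataset(b.data, 2.0, ("s2",), a.roi_ids)]
        )
        assert stacked.n_subjects == 2
        assert stacked.subject_ids == ("s1", "s2")


class TestSchedule:
    def test_overlapping_entries_rejected(self):
        with pytest.raises(ScheduleError):
            SegmentSchedule(
                [
                    SegmentEntry("j", "character", 1, 0, 10),
                    SegmentEntry("j", "action", 1, 5, 10),
                ]
            )

    def test_schedule_beyond_run_rejected(self, rng):
        schedule = SegmentSchedule([SegmentEntry("j", "action", 1, 0, 100)])
        with pytest.raises(ScheduleError):
            RoiTimeseriesDataset(
                rng.standard_normal((2, 2, 50)), 2.0, schedule=schedule
            )

    def test_json_round_trip(self, tmp_path):
        schedule = SegmentSchedule(
            [
                SegmentEntry("justified", "character", 1, 0, 45),
                SegmentEntry("justified", "action", 1, 48, 45),
            ]
        )
        path = tmp_path / "schedule.json"
        write_schedule_json(schedule, path)
        assert isinstance(json.loads(path.read_text()), list)
        assert read_schedule_json(path) == schedule


class TestExtractSegments:
    def test_whole_run_entry_is_identity(self, rng):
        data = rng.standard_normal((3, 2, 40))
        ds = RoiTimeseriesDataset(
            data, 2.0,
            schedule=SegmentSchedule([SegmentEntry("j", "action", 1, 0, 40)]),
        )
        out = extract_segments(ds, "j", "action")
        np.testing.assert_array_equal(out.data, data)

    def test_ninety_second_segment_at_tr2_has_45_samples(self, rng):
        length = int(90 / 2.0)
        ds = RoiTimeseriesDataset(
            rng.standard_normal((2, 2, 50)), 2.0,
            schedule=SegmentSchedule([SegmentEntry("j", "character", 1, 0, length)]),
        )
        assert extract_segments(ds, "j", "character").n_timepoints == 45

    def test_output_length_is_sum_of_matched_entries(self, scheduled_dataset):
        out = extract_segments(scheduled_dataset, "justified", "action")
        assert out.n_timepoints == 20  # two 10-sample action blocks
        assert out.n_rois == scheduled_dataset.n_rois
        full = extract_segments(scheduled_dataset, "justified")
        assert full.n_timepoints == 40

    def test_blocks_concatenated_in_clip_order(self, rng):
        data = rng.standard_normal((2, 2, 30))
        # clip 2 comes first in time; output must still be clip 1 then clip 2
        ds = RoiTimeseriesDataset(
            data, 2.0,
            schedule=SegmentSchedule(
                [
                    SegmentEntry("j", "action", 2, 0, 10),
                    SegmentEntry("j", "action", 1, 15, 10),
                ]
            ),
        )
        out = extract_segments(ds, "j", "action")
        np.testing.assert_array_equal(out.data[:, :, :10], data[:, :, 15:25])
        np.testing.assert_array_equal(out.data[:, :, 10:], data[:, :, 0:10])

    def test_single_clip_selection(self, scheduled_dataset):
        out = extract_segments(
            scheduled_dataset, "unjustified", "character", clip_index=2
        )
        assert out.n_timepoints == 10

    def test_no_match_raises(self, scheduled_dataset):
        with pytest.raises(EmptySelectionError):
            extract_segments(scheduled_dataset, "neutral", "action")

    def test_interludes_never_included(self, rng):
        # mark interlude samples with a sentinel; they must not appear
        data = np.zeros((1, 1, 24))
        data[:, :, 10:12] = 999.0
        ds = RoiTimeseriesDataset(
            data, 2.0,
            schedule=SegmentSchedule(
                [
                    SegmentEntry("j", "character", 1, 0, 10),
                    SegmentEntry("j", "action", 1, 12, 10),
                ]
            ),
        )
        out = extract_segments(ds, "j")
        assert not np.any(out.data == 999.0)


class TestVolumetricExtraction:
    def test_single_label_equals_whole_volume_mean(self, rng):
        vol = rng.standard_normal((3, 3, 3, 8))
        atlas = np.ones((3, 3, 3), dtype=int)
        ds = extract_roi_timeseries(vol, atlas, tr_seconds=2.0)
        np.testing.assert_allclose(ds.data[0, 0], vol.mean(axis=(0, 1, 2)))

    def test_constant_regions_recovered(self):
        t = np.arange(6, dtype=float)
        vol = np.empty((2, 1, 1, 6))
        vol[0, 0, 0] = t
        vol[1, 0, 0] = 2 * t
        atlas = np.array([[[1]], [[2]]])
        ds = extract_roi_timeseries(vol, atlas)
        np.testing.assert_array_equal(ds.data[0, 0], t)
        np.testing.assert_array_equal(ds.data[0, 1], 2 * t)
        assert ds.roi_ids == ("1", "2")

    def test_matches_voxel_loop_oracle(self, rng):
        vol = rng.standard_normal((4, 4, 4, 10))
        atlas = rng.integers(0, 4, size=(4, 4, 4))
        atlas.flat[:4] = [1, 2, 3, 0]  # ensure all labels present
        ds = extract_roi_timeseries(vol, atlas)
        for j, label in enumerate((1, 2, 3)):
            acc = np.zeros(10)
            count = 0
            for i in range(4):
                for jj in range(4):
                    for k in range(4):
                        if atlas[i, jj, k] == label:
                            acc += vol[i, jj, k]
                            count += 1
            np.testing.assert_allclose(ds.data[0, j], acc / count, rtol=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(DimensionError):
            extract_roi_timeseries(
                rng.standard_normal((4, 4, 4, 5)), np.ones((3, 3, 3), dtype=int)
            )

    def test_empty_label_excluded_with_warning(self, rng):
        vol = rng.standard_normal((2, 2, 2, 5))
        atlas = np.full((2, 2, 2), 3, dtype=int)
        atlas[0, 0, 0] = 1  # label 2 has no voxels
        with pytest.warns(UserWarning, match=r"\[2\]"):
            ds = extract_roi_timeseries(vol, atlas)
        assert ds.roi_ids == ("1", "3")

    def test_accepts_nibabel_images(self, rng):
        nib = pytest.importorskip("nibabel")
        vol = rng.standard_normal((3, 3, 3, 4))
        atlas = rng.integers(1, 3, size=(3, 3, 3))
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        atlas_img = nib.Nifti1Image(atlas.astype(np.int16), affine=np.eye(4))
        ds_img = extract_roi_timeseries(img, atlas_img)
        ds_arr = extract_roi_timeseries(vol, atlas)
        np.testing.assert_allclose(ds_img.data, ds_arr.data)


class TestAtlasTable:
    def _records(self):
        return [
            dict(roi_id="a", region_name="A", hemisphere="L",
                 mni_x=-10, mni_y=0, mni_z=5, lobe_label="frontal"),
            dict(roi_id="b", region_name="B", hemisphere="R",
                 mni_x=12, mni_y=-3, mni_z=7, lobe_label="occipital"),
        ]

    def test_round_trip(self, tmp_path):
        atlas = AtlasTable.from_records(self._records())
        path = tmp_path / "atlas.tsv"
        write_atlas_table(atlas, path)
        back = read_atlas_table(path)
        assert back.roi_ids == ("a", "b")
        assert back.mni("b") == (12.0, -3.0, 7.0)

    def test_duplicate_roi_id_rejected(self):
        records = self._records()
        records[1]["roi_id"] = "a"
        with pytest.raises(DataFormatError):
            AtlasTable.from_records(records)

    def test_bad_hemisphere_rejected(self):
        records = self._records()
        records[0]["hemisphere"] = "left"
        with pytest.raises(DataFormatError):
            AtlasTable.from_records(records)
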