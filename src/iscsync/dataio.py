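"""Reading, writing and slicing of ROI time-series data.

The central container is :class:`RoiTimeseriesDataset`, a dense
``subjects x ROIs x timepoints`` array with sampling metadata and an
optional :class:`SegmentSchedule` describing which stretches of the run
belong to which experimental condition (e.g. justified vs unjustified
movie clips) and segment type (character vs action blocks).

Time indices are 0-based and schedule intervals are half-open
``[onset, onset + length)``.  Inter-segment interludes and rest periods
are excluded simply by not being covered by any schedule entry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DataFormatError,
    DimensionError,
    EmptySelectionError,
    ScheduleError,
)

SEGMENT_TYPES = ("character", "action")
HEMISPHERES = ("L", "R", "L/R")

ATLAS_COLUMNS = [
    "roi_id",
    "region_name",
    "hemisphere",
    "mni_x",
    "mni_y",
    "mni_z",
    "lobe_label",
]


@dataclass(frozen=True)
class SegmentEntry:
    """One contiguous block of a run: a (condition, segment type, clip) triple."""

    condition: str
    segment_type: str
    clip_index: int
    onset_index: int
    length: int

    def __post_init__(self) -> None:
        if self.segment_type not in SEGMENT_TYPES:
            raise ScheduleError(
                f"segment_type must be one of {SEGMENT_TYPES}, got {self.segment_type!r}"
            )
        if self.clip_index < 1:
            raise ScheduleError(f"clip_index must be >= 1, got {self.clip_index}")
        if self.onset_index < 0:
            raise ScheduleError(f"onset_index must be >= 0, got {self.onset_index}")
        if self.length <= 0:
            raise ScheduleError(f"length must be > 0, got {self.length}")

    @property
    def stop_index(self) -> int:
        return self.onset_index + self.length


@dataclass(frozen=True)
class SegmentSchedule:
    """Non-overlapping segment entries covering (part of) a run."""

    entries: tuple[SegmentEntry, ...]

    def __init__(self, entries: Iterable[SegmentEntry | dict]) -> None:
        parsed = tuple(
            e if isinstance(e, SegmentEntry) else SegmentEntry(**e) for e in entries
        )
        ordered = sorted(parsed, key=lambda e: e.onset_index)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.onset_index < prev.stop_index:
                raise ScheduleError(
                    f"overlapping entries: {prev} and {nxt}"
                )
        object.__setattr__(self, "entries", parsed)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def total_length(self) -> int:
        """Number of timepoints covered by any entry."""
        return sum(e.length for e in self.entries)

    @property
    def end_index(self) -> int:
        """One past the last covered timepoint."""
        return max(e.stop_index for e in self.entries) if self.entries else 0

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.entries:
            if e.condition not in seen:
                seen.append(e.condition)
        return tuple(seen)

    def select(
        self,
        condition: str | None = None,
        segment_type: str | None = None,
        clip_index: int | None = None,
    ) -> tuple[SegmentEntry, ...]:
        """Entries matching the given keys, in clip order (then onset order)."""
        matched = [
            e
            for e in self.entries
            if (condition is None or e.condition == condition)
            and (segment_type is None or e.segment_type == segment_type)
            and (clip_index is None or e.clip_index == clip_index)
        ]
        return tuple(sorted(matched, key=lambda e: (e.clip_index, e.onset_index)))

    def to_records(self) -> list[dict]:
        return [
            {
                "condition": e.condition,
                "segment_type": e.segment_type,
                "clip_index": e.clip_index,
                "onset_index": e.onset_index,
                "length": e.length,
            }
            for e in self.entries
        ]


@dataclass
class RoiTimeseriesDataset:
    """Multi-subject ROI time-series array with sampling metadata.

    Parameters
    ----------
    data:
        Array of shape ``(n_subjects, n_rois, n_timepoints)``.
    tr_seconds:
        Sampling interval (repetition time) in seconds; must be positive.
    subject_ids, roi_ids:
        Unique labels for the first two axes.
    schedule:
        Optional :class:`SegmentSchedule` annotating the time axis.
    """

    data: np.ndarray
    tr_seconds: float
    subject_ids: tuple[str, ...] = ()
    roi_ids: tuple[str, ...] = ()
    schedule: SegmentSchedule | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 and self.data.ndim != 3:
            raise DimensionError(
                f"data must be 2-D (single subject) or 3-D, got ndim={self.data.ndim}"
            )
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        n_subj, n_roi, n_t = self.data.shape
        if not self.subject_ids:
            self.subject_ids = tuple(f"sub-{i + 1:02d}" for i in range(n_subj))
        if not self.roi_ids:
            self.roi_ids = tuple(f"roi-{i + 1:03d}" for i in range(n_roi))
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        self.roi_ids = tuple(str(r) for r in self.roi_ids)
        if len(self.subject_ids) != n_subj:
            raise DimensionError("subject_ids length does not match data")
        if len(self.roi_ids) != n_roi:
            raise DimensionError("roi_ids length does not match data")
        if len(set(self.roi_ids)) != n_roi:
            raise DataFormatError("duplicate ROI ids")
        if len(set(self.subject_ids)) != n_subj:
            raise DataFormatError("duplicate subject ids")
        if not (self.tr_seconds > 0):
            raise DataFormatError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        if self.schedule is not None and self.schedule.end_index > n_t:
            raise ScheduleError(
                f"schedule extends to index {self.schedule.end_index} "
                f"but run has only {n_t} timepoints"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, schedule: SegmentSchedule | None = None):
        """Copy of this dataset with new data (and optionally a new schedule)."""
        return replace(self, data=data, schedule=schedule)


# ---------------------------------------------------------------------------
# Tab-separated time-series tables (rows = timepoints, columns = ROIs)
# ---------------------------------------------------------------------------

def read_timeseries_table(
    path: str | Path,
    tr_seconds: float,
    subject_id: str | None = None,
) -> RoiTimeseriesDataset:
    """Read a single subject's ROI time series from a tab-separated table.

    The first row holds ROI ids; each subsequent row is one timepoint.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"{path}: malformed table ({exc})") from exc
    if frame.shape[0] == 0:
        raise DataFormatError(f"{path}: table has a header but no timepoints")
    if frame.isna().any().any():
        row, col = _first_bad_cell(frame, frame.isna())
        raise DataFormatError(
            f"{path}: ragged or missing cell at data row {row}, column {col!r}"
        )
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row, col = _first_bad_cell(frame, numeric.isna())
        raise DataFormatError(
            f"{path}: non-numeric value {frame.loc[row, col]!r} "
            f"at data row {row}, column {col!r}"
        )
    # numpy's str->float conversion is correctly rounded (exact round trip)
    data = frame.to_numpy(dtype=str).astype(float).T[np.newaxis]
    sid = subject_id if subject_id is not None else path.stem
    return RoiTimeseriesDataset(
        data=data,
        tr_seconds=tr_seconds,
        subject_ids=(sid,),
        roi_ids=tuple(frame.columns),
    )


def _first_bad_cell(frame: pd.DataFrame, mask: pd.DataFrame) -> tuple[int, str]:
    rows, cols = np.nonzero(mask.to_numpy())
    return int(frame.index[rows[0]]), str(frame.columns[cols[0]])


def write_timeseries_table(
    ds: RoiTimeseriesDataset, path: str | Path, subject: int | str = 0
) -> None:
    """Write one subject of a dataset as a tab-separated table (header = ROI ids)."""
    idx = ds.subject_ids.index(subject) if isinstance(subject, str) else int(subject)
    frame = pd.DataFrame(ds.data[idx].T, columns=list(ds.roi_ids))
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def stack_subjects(datasets: Sequence[RoiTimeseriesDataset]) -> RoiTimeseriesDataset:
    """Assemble single-subject datasets into one multi-subject dataset.

    ROI sets, run lengths and TR must match exactly; no resampling is
    attempted.  The schedule of the first dataset (if any) is carried over.
    """
    if not datasets:
        raise DataFormatError("no datasets to stack")
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.roi_ids != first.roi_ids:
            raise AlignmentError("ROI ids differ between subjects")
        if ds.n_timepoints != first.n_timepoints:
            raise AlignmentError("run lengths differ between subjects")
        if ds.tr_seconds != first.tr_seconds:
            raise AlignmentError("TR differs between subjects")
    data = np.concatenate([ds.data for ds in datasets], axis=0)
    subject_ids = tuple(sid for ds in datasets for sid in ds.subject_ids)
    return RoiTimeseriesDataset(
        data=data,
        tr_seconds=first.tr_seconds,
        subject_ids=subject_ids,
        roi_ids=first.roi_ids,
        schedule=first.schedule,
    )


# ---------------------------------------------------------------------------
# Atlas table
# ---------------------------------------------------------------------------

@dataclass
class AtlasTable:
    """ROI labels with anatomical metadata (name, hemisphere, MNI, lobe group)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ATLAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataFormatError(f"atlas table missing columns: {missing}")
        tab = self.table.loc[:, ATLAS_COLUMNS].copy()
        tab["roi_id"] = tab["roi_id"].astype(str)
        if tab["roi_id"].duplicated().any():
            dup = tab.loc[tab["roi_id"].duplicated(), "roi_id"].iloc[0]
            raise DataFormatError(f"duplicate roi_id in atlas table: {dup!r}")
        bad = ~tab["hemisphere"].isin(HEMISPHERES)
        if bad.any():
            raise DataFormatError(
                f"hemisphere must be one of {HEMISPHERES}, "
                f"got {tab.loc[bad, 'hemisphere'].iloc[0]!r}"
            )
        for c in ("mni_x", "mni_y", "mni_z"):
            tab[c] = pd.to_numeric(tab[c])
        self.table = tab.set_index("roi_id", drop=False)

    @property
    def roi_ids(self) -> tuple[str, ...]:
        return tuple(self.table["roi_id"])

    def mni(self, roi_id: str) -> tuple[float, float, float]:
        row = self.table.loc[str(roi_id)]
        return (float(row["mni_x"]), float(row["mni_y"]), float(row["mni_z"]))

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "AtlasTable":
        return cls(pd.DataFrame.from_records(list(records)))


def read_atlas_table(path: str | Path) -> AtlasTable:
    try:
        frame = pd.read_csv(path, sep="\t", header=0)
    except pd.errors.EmptyDataError as exc:
        raise DataFormatError(f"{path}: empty atlas table") from exc
    return AtlasTable(frame)


def write_atlas_table(atlas: AtlasTable, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Segment schedule (JSON)
# ---------------------------------------------------------------------------

def read_schedule_json(path: str | Path) -> SegmentSchedule:
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise DataFormatError(f"{path}: schedule JSON must be an array of entries")
    return SegmentSchedule(records)


def write_schedule_json(schedule: SegmentSchedule, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(schedule.to_records(), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Segment extraction
# ---------------------------------------------------------------------------

def extract_segments(
    ds: RoiTimeseriesDataset,
    condition: str,
    segment_type: str | None = None,
    clip_index: int | None = None,
) -> RoiTimeseriesDataset:
    """Concatenate the matching schedule blocks along time, in clip order.

    Interlude and rest samples are never included because the schedule does
    not cover them.  Restricting ``clip_index`` gives per-clip analyses.
    """
    if ds.schedule is None:
        raise ScheduleError("dataset has no segment schedule")
    entries = ds.schedule.select(condition, segment_type, clip_index)
    if not entries:
        raise EmptySelectionError(
            f"no schedule entries match condition={condition!r}, "
            f"segment_type={segment_type!r}, clip_index={clip_index!r}"
        )
    blocks = [ds.data[:, :, e.onset_index : e.stop_index] for e in entries]
    return RoiTimeseriesDataset(
        data=np.concatenate(blocks, axis=2),
        tr_seconds=ds.tr_seconds,
        subject_ids=ds.subject_ids,
        roi_ids=ds.roi_ids,
        schedule=None,
    )


# ---------------------------------------------------------------------------
# Volumetric extraction (optional NIfTI path)
# ---------------------------------------------------------------------------

def extract_roi_timeseries(
    volume_4d,
    atlas_volume,
    tr_seconds: float = 2.0,
    subject_id: str = "sub-01",
) -> RoiTimeseriesDataset:
    """Average a 4-D volume over each atlas label to get ROI time series.

    Accepts numpy arrays or nibabel spatial images.  Labels are non-negative
    integers with 0 = background; output ROIs are ordered by ascending label.
    Labels without any voxel are skipped with a warning.
    """
    vol = _as_array(volume_4d)
    atlas = _as_array(atlas_volume)
    if vol.ndim != 4:
        raise DimensionError(f"volume must be 4-D, got ndim={vol.ndim}")
    if atlas.shape != vol.shape[:3]:
        raise DimensionError(
            f"atlas shape {atlas.shape} does not match volume spatial "
            f"shape {vol.shape[:3]}"
        )
    labels_int = np.rint(atlas).astype(np.int64)
    if np.any(labels_int < 0):
        raise DataFormatError("atlas labels must be non-negative integers")
    flat_labels = labels_int.reshape(-1)
    flat_vol = vol.reshape(-1, vol.shape[3]).astype(float)
    present = np.unique(flat_labels)
    wanted = present[present > 0]
    if wanted.size == 0:
        raise DataFormatError("atlas volume contains no non-background labels")
    max_label = int(labels_int.max())
    counts = np.bincount(flat_labels, minlength=max_label + 1)
    missing = [
        lab for lab in range(1, max_label + 1) if counts[lab] == 0
    ]
    if missing:
        warnings.warn(
            f"atlas labels with zero voxels excluded: {missing}", stacklevel=2
        )
    sums = np.zeros((max_label + 1, vol.shape[3]))
    np.add.at(sums, flat_labels, flat_vol)
    series = sums[wanted] / counts[wanted, np.newaxis]
    return RoiTimeseriesDataset(
        data=series[np.newaxis],
        tr_seconds=tr_seconds,
        subject_ids=(subject_id,),
        roi_ids=tuple(str(lab) for lab in wanted),
    )


def _as_array(img) -> np.ndarray:
    if hasattr(img, "get_fdata"):  # nibabel spatial image
        return np.asarray(img.get_fdata())
    return np.asarray(img)
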