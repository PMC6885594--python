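"""Region tables summarizing significant ROIs per anatomical group.

At ROI resolution the analogue of a voxel cluster is the set of
significant ROIs sharing an anatomical group label and hemisphere; each
table row reports the count of such ROIs, the peak group-mean ISC among
them and the MNI coordinates of the peak ROI.  This is a deliberate
resolution change relative to voxelwise cluster tables, not an attempt
to replicate voxel clustering.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import AtlasTable
from .exceptions import AlignmentError, DimensionError

__all__ = ["RegionTableRow", "make_region_table", "region_table_to_frame",
           "write_region_table"]


@dataclass
class RegionTableRow:
    """One anatomical group x hemisphere of significant ROIs."""

    region_name: str
    hemisphere: str
    n_units: int
    peak_isc: float
    peak_mni: tuple[float, float, float]


def make_region_table(
    flags: np.ndarray,
    isc: np.ndarray,
    atlas: AtlasTable,
    roi_ids: Sequence[str],
) -> list[RegionTableRow]:
    """Group significant ROIs by (lobe label, hemisphere).

    ``flags`` and ``isc`` are aligned with ``roi_ids``, every one of which
    must appear in the atlas.  Rows are sorted by descending ROI count,
    then descending peak ISC, then name; the row's region name is the
    atlas lobe label (the grouping key).
    """
    flags = np.asarray(flags, dtype=bool)
    isc = np.asarray(isc, dtype=float)
    roi_ids = [str(r) for r in roi_ids]
    if not (flags.shape == isc.shape == (len(roi_ids),)):
        raise DimensionError("flags, isc and roi_ids must have equal length")
    missing = [r for r in roi_ids if r not in atlas.table.index]
    if missing:
        raise AlignmentError(f"ROI ids absent from atlas table: {missing}")

    groups: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for rid, flag, value in zip(roi_ids, flags, isc):
        if not flag:
            continue
        row = atlas.table.loc[rid]
        key = (str(row["lobe_label"]), str(row["hemisphere"]))
        groups.setdefault(key, []).append((rid, float(value)))

    rows = []
    for (lobe, hemi), members in groups.items():
        peak_id, peak_val = max(members, key=lambda m: m[1])
        rows.append(
            RegionTableRow(
                region_name=lobe,
                hemisphere=hemi,
                n_units=len(members),
                peak_isc=peak_val,
                peak_mni=atlas.mni(peak_id),
            )
        )
    rows.sort(key=lambda r: (-r.n_units, -r.peak_isc, r.region_name, r.hemisphere))
    return rows


def region_table_to_frame(rows: Sequence[RegionTableRow]) -> pd.DataFrame:
    """Region table as a DataFrame with MNI coordinates split into columns."""
    records = []
    for r in rows:
        rec = asdict(r)
        x, y, z = rec.pop("peak_mni")
        rec.update(mni_x=x, mni_y=y, mni_z=z)
        records.append(rec)
    columns = ["region_name", "hemisphere", "n_units", "peak_isc",
               "mni_x", "mni_y", "mni_z"]
    return pd.DataFrame.from_records(records, columns=columns)


def write_region_table(
    rows: Sequence[RegionTableRow], path: str | Path, fmt: str = "tsv"
) -> None:
    """Write a region table as tab-separated text or JSON."""
    path = Path(path)
    if fmt == "tsv":
        region_table_to_frame(rows).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump([asdict(r) for r in rows], fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
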