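"""Leave-one-out intersubject correlation (ISC) and derived summaries.

For subject *s* and region *r*, the leave-one-out ISC is the Pearson
correlation of subject *s*'s time series with the unweighted mean time
series of all remaining subjects, computed for every subject and region.
High ISC indicates that a region's activity is driven by the shared
stimulus rather than idiosyncratic noise.

Cells whose subject series or leave-one-out mean series has zero variance
are flagged invalid (NaN) and excluded from downstream summaries rather
than set to zero, which would bias group means toward the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import RoiTimeseriesDataset
from .exceptions import DegenerateInputError, DimensionError

__all__ = [
    "IscMatrix",
    "isc_loo",
    "group_mean_isc",
    "global_isc",
    "fisher_z",
    "fisher_z_inv",
]


@dataclass
class IscMatrix:
    """Subjects x ROIs matrix of leave-one-out ISC values.

    Invalid cells are NaN.  ``provenance`` records which condition, segment
    type and clip selection produced the matrix ("all" = no restriction).
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]
    roi_ids: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DimensionError("IscMatrix values must be 2-D")
        if self.values.shape != (len(self.subject_ids), len(self.roi_ids)):
            raise DimensionError("IscMatrix shape does not match id lists")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.max() > 1 + 1e-12 or finite.min() < -1 - 1e-12):
            raise ValueError("correlations outside [-1, 1]")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=list(self.roi_ids)
        )


def isc_loo(ds: RoiTimeseriesDataset, provenance: dict | None = None) -> IscMatrix:
    """Leave-one-out ISC for every subject x ROI cell.

    ``values[s, r]`` is the Pearson correlation of subject ``s``'s series
    for ROI ``r`` with the unweighted mean of all other subjects' series
    for the same ROI.
    """
    if ds.n_subjects < 2:
        raise DegenerateInputError("leave-one-out ISC needs at least 2 subjects")
    x = ds.data
    n = ds.n_subjects
    # Mean of the others = (total - own) / (n - 1); scaling does not affect
    # the correlation but is kept for clarity.
    others = (x.sum(axis=0, keepdims=True) - x) / (n - 1)
    xc = x - x.mean(axis=-1, keepdims=True)
    oc = others - others.mean(axis=-1, keepdims=True)
    sx = np.sqrt((xc * xc).sum(axis=-1))
    so = np.sqrt((oc * oc).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (xc * oc).sum(axis=-1) / (sx * so)
    degenerate = (sx == 0) | (so == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} subject x ROI cell(s) have zero variance; "
            "flagged invalid",
            stacklevel=2,
        )
        values = np.where(degenerate, np.nan, values)
    values = np.clip(values, -1.0, 1.0)  # NaN passes through unchanged
    return IscMatrix(
        values=values,
        subject_ids=ds.subject_ids,
        roi_ids=ds.roi_ids,
        provenance=provenance or {},
    )


def group_mean_isc(m: IscMatrix, method: str = "fisher") -> np.ndarray:
    """Per-ROI mean ISC over subjects.

    ``method="fisher"`` (default) averages on the Fisher-z scale and
    back-transforms, which is the variance-stabilized convention for
    averaging correlations; ``method="raw"`` averages the correlations
    directly.  Invalid (NaN) cells are excluded; an ROI with no valid
    cell yields NaN and a warning.
    """
    if method not in ("fisher", "raw"):
        raise ValueError(f"unknown averaging method {method!r}")
    vals = m.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "fisher":
            out = np.tanh(np.nanmean(np.arctanh(vals), axis=0))
        else:
            out = np.nanmean(vals, axis=0)
    n_missing = int(np.all(~np.isfinite(vals), axis=0).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} ROI(s) have no valid ISC cell; group mean is NaN",
            stacklevel=2,
        )
    return out


def global_isc(m: IscMatrix) -> np.ndarray:
    """Per-subject mean ISC over ROIs (whole-brain synchrony per subject)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(m.values, axis=1)


def fisher_z(r):
    """Fisher z-transform atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise DegenerateInputError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z):
    """Inverse Fisher transform tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out
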