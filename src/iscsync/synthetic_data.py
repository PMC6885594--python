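"""Synthetic multi-subject ROI BOLD time series.

The generator emulates the statistical structure the ISC analysis assumes:
within each scheduled segment, every subject's series for ROI *r* is

    x[s, r, t] = sqrt(a) * g[r, t] + sqrt(1 - a) * eps[s, r, t]

where ``g`` is one shared, standardized, stimulus-driven signal per ROI
per segment (band-limited Gaussian, optionally smoothed with a canonical
hemodynamic response), ``eps`` is per-subject AR(1) noise standardized
over the run, and ``a`` (the *shared-variance fraction*) is taken from
the segment the sample belongs to.  Samples not covered by any segment
(interludes, rest) are pure noise.  Under this model with white noise the
population leave-one-out ISC has the closed form of :func:`expected_isc`.

Design choices: the shared signal is band-limited to 0.05-0.1 Hz so that
the band-pass stage retains it while attenuating the broadband noise
(making the filter consequential and testable); segment boundaries
restart ``g`` but not ``eps``, approximating continuity of physiological
noise across cuts; AR(1) is the minimal noise model honoring the surrogate
method's premise of preserving the autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .dataio import (
    AtlasTable,
    RoiTimeseriesDataset,
    SegmentEntry,
    SegmentSchedule,
    write_atlas_table,
    write_schedule_json,
    write_timeseries_table,
)
from .exceptions import ConfigError

__all__ = [
    "RoiSpec",
    "SimulationScenario",
    "make_block_schedule",
    "simulate_dataset",
    "simulate_null_dataset",
    "expected_isc",
    "preset_paper_like",
    "atlas_for_scenario",
    "write_dataset_dir",
]

SHARED_BAND_HZ = (0.05, 0.1)


@dataclass(frozen=True)
class RoiSpec:
    """Metadata for one simulated ROI."""

    roi_id: str
    region_name: str
    hemisphere: str
    mni_xyz: tuple[float, float, float]
    lobe_label: str


@dataclass
class SimulationScenario:
    """Generative parameters for a simulated multi-subject run.

    ``shared_fraction`` maps ``(condition, segment_type)`` to the
    shared-variance fraction ``a`` — a scalar or a per-ROI array in [0, 1].
    Pairs not present default to 0 (no shared signal).
    """

    rois: Sequence[RoiSpec]
    schedule: SegmentSchedule
    n_subjects: int = 26
    tr_seconds: float = 2.0
    shared_fraction: Mapping[tuple[str, str], object] = field(default_factory=dict)
    noise_ar1_phi: float = 0.3
    hrf_smoothing: bool = False
    seed: int = 0
    n_timepoints: int | None = None

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("need at least 2 subjects")
        if not (self.tr_seconds > 0):
            raise ConfigError("tr_seconds must be positive")
        if not (-1 < self.noise_ar1_phi < 1):
            raise ConfigError("noise_ar1_phi must be in (-1, 1)")
        if not self.rois:
            raise ConfigError("scenario needs at least one ROI")
        n_t = self.total_timepoints
        if self.schedule.end_index > n_t:
            raise ConfigError(
                f"schedule needs {self.schedule.end_index} timepoints, "
                f"scenario provides {n_t}"
            )
        for key in self.shared_fraction:
            a = self.shared_for(*key)
            if np.any(a < 0) or np.any(a > 1):
                raise ConfigError(f"shared fraction for {key} outside [0, 1]")

    @property
    def total_timepoints(self) -> int:
        return (
            self.n_timepoints
            if self.n_timepoints is not None
            else self.schedule.end_index
        )

    @property
    def roi_ids(self) -> tuple[str, ...]:
        return tuple(r.roi_id for r in self.rois)

    def shared_for(self, condition: str, segment_type: str) -> np.ndarray:
        """Per-ROI shared-variance fractions for a condition x segment pair."""
        a = self.shared_fraction.get((condition, segment_type), 0.0)
        return np.broadcast_to(
            np.asarray(a, dtype=float), (len(self.rois),)
        ).copy()


def generic_rois(n_rois: int, lobe_label: str = "unspecified") -> list[RoiSpec]:
    """Placeholder ROI metadata for scenarios where anatomy is irrelevant."""
    return [
        RoiSpec(
            roi_id=f"roi-{i + 1:03d}",
            region_name=f"Region {i + 1}",
            hemisphere="L/R",
            mni_xyz=(0.0, 0.0, 0.0),
            lobe_label=lobe_label,
        )
        for i in range(n_rois)
    ]


def make_block_schedule(
    conditions: Sequence[str] = ("justified", "unjustified"),
    n_clips: int = 4,
    segment_length: int = 45,
    interlude_length: int = 3,
    inter_condition_gap: int = 15,
    start: int = 0,
) -> SegmentSchedule:
    """Block design: per condition, ``n_clips`` clips of a character segment
    followed by an action segment, separated by short interludes.

    Defaults encode 90-s segments at TR = 2 s (45 samples) with 5-s
    inter-segment interludes rounded up to whole samples (3).  Interlude
    and gap samples are simply not covered by any entry.
    """
    entries = []
    t = start
    for condition in conditions:
        for clip in range(1, n_clips + 1):
            for segment_type in ("character", "action"):
                entries.append(
                    SegmentEntry(
                        condition=condition,
                        segment_type=segment_type,
                        clip_index=clip,
                        onset_index=t,
                        length=segment_length,
                    )
                )
                t += segment_length + interlude_length
        t += inter_condition_gap
    return SegmentSchedule(entries)


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=-1, keepdims=True)
    std = x.std(axis=-1, keepdims=True)
    std = np.where(std == 0, 1.0, std)
    return (x - mean) / std


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], phi: float, burn_in: int = 50
) -> np.ndarray:
    """AR(1) innovations filtered to x_t = phi * x_{t-1} + w_t, with burn-in."""
    white = rng.standard_normal(shape[:-1] + (shape[-1] + burn_in,))
    series = _signal.lfilter([1.0], [1.0, -phi], white, axis=-1)
    return series[..., burn_in:]


def canonical_hrf(tr_seconds: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR."""
    t = np.arange(0, duration_s, tr_seconds)
    kernel = _stats.gamma.pdf(t, 6) - _stats.gamma.pdf(t, 16) / 6.0
    return kernel / np.abs(kernel).sum()


def _bandlimited_shared_signal(
    rng: np.random.Generator,
    n_rois: int,
    length: int,
    tr_seconds: float,
    hrf_smoothing: bool,
) -> np.ndarray:
    """One standardized shared signal per ROI, band-limited to 0.05-0.1 Hz."""
    freqs = np.fft.rfftfreq(length, d=tr_seconds)
    low, high = SHARED_BAND_HZ
    band = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not band.any():  # degenerate short segment: use the closest nonzero bin
        centre = 0.5 * (low + high)
        idx = int(np.argmin(np.abs(freqs[1:] - centre))) + 1
        band[idx] = True
    coeff = np.zeros((n_rois, freqs.size), dtype=complex)
    n_band = int(band.sum())
    coeff[:, band] = rng.standard_normal((n_rois, n_band)) + 1j * rng.standard_normal(
        (n_rois, n_band)
    )
    g = np.fft.irfft(coeff, n=length, axis=-1)
    if hrf_smoothing:
        kernel = canonical_hrf(tr_seconds)
        g = _signal.fftconvolve(g, kernel[np.newaxis, :], mode="full", axes=-1)
        g = g[..., :length]
    return _zscore(g)


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def simulate_dataset(sc: SimulationScenario) -> RoiTimeseriesDataset:
    """Draw one multi-subject dataset from the scenario's generative model.

    The random stream is fixed by ``sc.seed``: the noise array is drawn
    first, then one shared signal per schedule entry, in schedule order.
    Each output series is standardized over the full run (an affine map
    per series, which leaves all correlations unchanged).
    """
    sc.validate()
    rng = np.random.default_rng(sc.seed)
    n_s, n_r = sc.n_subjects, len(sc.rois)
    n_t = sc.total_timepoints
    eps = _zscore(_ar1_noise(rng, (n_s, n_r, n_t), sc.noise_ar1_phi))
    x = eps.copy()
    for entry in sc.schedule:
        g = _bandlimited_shared_signal(
            rng, n_r, entry.length, sc.tr_seconds, sc.hrf_smoothing
        )
        a = sc.shared_for(entry.condition, entry.segment_type)[:, np.newaxis]
        sl = slice(entry.onset_index, entry.stop_index)
        x[:, :, sl] = np.sqrt(a) * g[np.newaxis] + np.sqrt(1.0 - a) * eps[:, :, sl]
    return RoiTimeseriesDataset(
        data=_zscore(x),
        tr_seconds=sc.tr_seconds,
        subject_ids=tuple(f"sub-{i + 1:02d}" for i in range(n_s)),
        roi_ids=sc.roi_ids,
        schedule=sc.schedule,
    )


def simulate_null_dataset(
    n_subjects: int,
    n_rois: int,
    n_timepoints: int,
    ar1_phi: float = 0.3,
    tr_seconds: float = 2.0,
    seed=0,
) -> RoiTimeseriesDataset:
    """Global-null dataset: independent AR(1) noise, no shared signal.

    ``seed`` may be an int, a :class:`numpy.random.SeedSequence` or a
    generator.  Used for calibration of the inference procedure.
    """
    rng = np.random.default_rng(seed)
    data = _zscore(_ar1_noise(rng, (n_subjects, n_rois, n_timepoints), ar1_phi))
    return RoiTimeseriesDataset(data=data, tr_seconds=tr_seconds)


def expected_isc(a: float, n_subjects: int) -> float:
    """Population leave-one-out ISC under the generator with white noise.

    With ``x_i = sqrt(a) g + sqrt(1-a) e_i`` (unit-variance, independent),
    the correlation of ``x_i`` with the mean of the other ``n - 1``
    subjects is ``a / sqrt(a + (1 - a) / (n - 1))``.
    """
    if n_subjects < 2:
        raise ConfigError("expected_isc needs n_subjects >= 2")
    if not (0 <= a <= 1):
        raise ConfigError("shared fraction a must be in [0, 1]")
    return float(a / np.sqrt(a + (1.0 - a) / (n_subjects - 1)))


# ---------------------------------------------------------------------------
# Paper-like preset
# ---------------------------------------------------------------------------

def _roi(roi_id, name, hemi, xyz, lobe) -> RoiSpec:
    return RoiSpec(roi_id, name, hemi, xyz, lobe)


def preset_paper_like(seed: int = 2019) -> SimulationScenario:
    """Scenario encoding the qualitative dissociation under study.

    Occipital and temporal ROIs carry shared signal (a = 0.5) in every
    condition x segment; a vmPFC ROI is driven only during justified
    action; lOFC and insula ROIs only during unjustified action; the
    remaining frontal/parietal/subcortical ROIs are never driven.
    Twenty-six subjects view two conditions of four clips, each clip a
    45-sample character segment followed by a 45-sample action segment.
    """
    rois: list[RoiSpec] = [
        _roi("occ-calcarine-l", "Calcarine cortex", "L", (-8.0, -80.0, 6.0), "occipital"),
        _roi("occ-calcarine-r", "Calcarine cortex", "R", (10.0, -78.0, 8.0), "occipital"),
        _roi("occ-lingual-l", "Lingual gyrus", "L", (-14.0, -68.0, -6.0), "occipital"),
        _roi("occ-lingual-r", "Lingual gyrus", "R", (16.0, -66.0, -4.0), "occipital"),
        _roi("occ-mid-l", "Middle occipital gyrus", "L", (-30.0, -84.0, 14.0), "occipital"),
        _roi("occ-mid-r", "Middle occipital gyrus", "R", (32.0, -82.0, 16.0), "occipital"),
        _roi("tmp-sup-l", "Superior temporal gyrus", "L", (-50.0, -22.0, 2.0), "temporal"),
        _roi("tmp-sup-r", "Superior temporal gyrus", "R", (52.0, -20.0, 4.0), "temporal"),
        _roi("tmp-mid-l", "Middle temporal gyrus", "L", (-56.0, -34.0, -4.0), "temporal"),
        _roi("tmp-mid-r", "Middle temporal gyrus", "R", (58.0, -32.0, -2.0), "temporal"),
        _roi("tmp-heschl-l", "Heschl gyrus", "L", (-42.0, -20.0, 8.0), "temporal"),
        _roi("tmp-heschl-r", "Heschl gyrus", "R", (44.0, -18.0, 10.0), "temporal"),
        _roi("vmpfc", "Ventromedial prefrontal cortex", "L", (-14.0, 8.0, -20.0), "vmPFC"),
        _roi("lofc-l", "Lateral orbitofrontal cortex", "L", (-34.0, 42.0, -2.0), "lOFC"),
        _roi("lofc-r", "Lateral orbitofrontal cortex", "R", (36.0, 46.0, -2.0), "lOFC"),
        _roi("insula-l", "Insula", "L", (-36.0, 20.0, 8.0), "insula"),
        _roi("insula-r", "Insula", "R", (52.0, 12.0, -2.0), "insula"),
        _roi("acc", "Anterior cingulate cortex", "L/R", (0.0, 32.0, 12.0), "cingulate"),
        _roi("pcc", "Posterior cingulate cortex", "L/R", (-6.0, -32.0, 32.0), "cingulate"),
        _roi("sfg-l", "Superior frontal gyrus", "L", (-24.0, -6.0, 46.0), "frontal"),
        _roi("sfg-r", "Superior frontal gyrus", "R", (12.0, 16.0, 46.0), "frontal"),
        _roi("mfg-l", "Middle frontal gyrus", "L", (-48.0, 6.0, 22.0), "frontal"),
        _roi("mfg-r", "Middle frontal gyrus", "R", (50.0, 4.0, 20.0), "frontal"),
        _roi("precentral-l", "Precentral gyrus", "L", (-40.0, -6.0, 32.0), "frontal"),
        _roi("precentral-r", "Precentral gyrus", "R", (42.0, -4.0, 34.0), "frontal"),
        _roi("parietal-sup-l", "Superior parietal lobule", "L", (-26.0, -60.0, 52.0), "parietal"),
        _roi("parietal-sup-r", "Superior parietal lobule", "R", (28.0, -58.0, 54.0), "parietal"),
        _roi("precuneus", "Precuneus", "L/R", (2.0, -54.0, 48.0), "parietal"),
        _roi("caudate-l", "Caudate nucleus", "L", (-10.0, -4.0, 14.0), "subcortical"),
        _roi("caudate-r", "Caudate nucleus", "R", (14.0, 0.0, 12.0), "subcortical"),
    ]
    lobes = np.array([r.lobe_label for r in rois])
    sensory = (lobes == "occipital") | (lobes == "temporal")
    vmpfc = np.array([r.roi_id == "vmpfc" for r in rois])
    lofc_insula = (lobes == "lOFC") | (lobes == "insula")

    drive = 0.5
    shared: dict[tuple[str, str], np.ndarray] = {}
    for condition in ("justified", "unjustified"):
        for segment_type in ("character", "action"):
            a = np.where(sensory, drive, 0.0)
            if (condition, segment_type) == ("justified", "action"):
                a = np.where(vmpfc, drive, a)
            if (condition, segment_type) == ("unjustified", "action"):
                a = np.where(lofc_insula, drive, a)
            shared[(condition, segment_type)] = a

    return SimulationScenario(
        rois=rois,
        schedule=make_block_schedule(),
        n_subjects=26,
        tr_seconds=2.0,
        shared_fraction=shared,
        noise_ar1_phi=0.3,
        hrf_smoothing=False,
        seed=seed,
    )


def atlas_for_scenario(sc: SimulationScenario) -> AtlasTable:
    """Atlas label table matching the scenario's ROI metadata."""
    return AtlasTable.from_records(
        {
            "roi_id": r.roi_id,
            "region_name": r.region_name,
            "hemisphere": r.hemisphere,
            "mni_x": r.mni_xyz[0],
            "mni_y": r.mni_xyz[1],
            "mni_z": r.mni_xyz[2],
            "lobe_label": r.lobe_label,
        }
        for r in sc.rois
    )


def write_dataset_dir(
    ds: RoiTimeseriesDataset,
    out_dir: str | Path,
    atlas: AtlasTable | None = None,
) -> Path:
    """Write a dataset as per-subject TSV tables plus schedule/atlas files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid in ds.subject_ids:
        write_timeseries_table(ds, out / f"{sid}_timeseries.tsv", subject=sid)
    if ds.schedule is not None:
        write_schedule_json(ds.schedule, out / "schedule.json")
    if atlas is not None:
        write_atlas_table(atlas, out / "atlas.tsv")
    return out
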