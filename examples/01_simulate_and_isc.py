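"""Simulate a movie-viewing experiment and compute leave-one-out ISC.

Builds the paper-like scenario (26 subjects, two conditions of four clips,
each clip a 90-s character segment followed by a 90-s action segment at
TR = 2 s), band-pass filters the runs to 0.05-0.1 Hz, and prints the
group-mean ISC of a few regions during justified action segments.
"""

import numpy as np

from iscsync import (
    bandpass_filter,
    expected_isc,
    extract_segments,
    group_mean_isc,
    isc_loo,
    preset_paper_like,
    simulate_dataset,
)

scenario = preset_paper_like()
dataset = bandpass_filter(simulate_dataset(scenario))
block = extract_segments(dataset, "justified", "action")
matrix = isc_loo(block, provenance={"condition": "justified",
                                    "segment": "action"})
mean_isc = group_mean_isc(matrix)

print(f"dataset: {dataset.n_subjects} subjects x {dataset.n_rois} ROIs x "
      f"{dataset.n_timepoints} timepoints (TR {dataset.tr_seconds} s)")
print(f"justified-action block: {block.n_timepoints} timepoints "
      f"(4 clips x 45 samples)\n")
print("group-mean leave-one-out ISC (justified action):")
for roi in ("occ-calcarine-l", "tmp-sup-l", "vmpfc", "lofc-l", "precuneus"):
    value = mean_isc[block.roi_ids.index(roi)]
    print(f"  {roi:<16} {value:+.3f}")
print(
    "\nROIs simulated with shared fraction a = 0.5 should sit near the "
    f"analytic value {expected_isc(0.5, 26):.3f} (boosted by the band-pass,"
)
print("which removes broadband noise but keeps the band-limited shared "
      "signal); undriven ROIs fluctuate around zero.")
print(f"mean ISC over all cells: {np.nanmean(matrix.values):+.3f}")
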