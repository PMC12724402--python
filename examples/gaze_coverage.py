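"""Gaze dwell-density maps and cumulative image-coverage curves.

Simulates the initial free-viewing gaze of an NT-like and an ASD-like
observer, cleans the streams, builds the Gaussian kernel-density dwell map
(sigma = 10 px) with its 15x15 downsampled version, and prints percent image
coverage over cumulative 1-10 s windows.
"""

import numpy as np

from perceptseg import gaze, simulate

SEED = 0

for cohort in ("NT", "ASD"):
    preset = simulate.gaze_preset(cohort)
    stream = simulate.simulate_gaze(seed=SEED, **preset)
    cleaned, retention = gaze.clean_gaze(stream)
    density = gaze.gaze_density(cleaned, sigma=10.0)
    coarse = gaze.downsample_density(density)
    curve = gaze.coverage_curve(cleaned)
    full = gaze.coverage(cleaned, preset["duration_s"] + 0.1)
    print(f"{cohort}: {preset['duration_s']:.1f} s viewing, "
          f"retention {100 * retention:.0f}%, "
          f"total dwell {density.total_dwell:.2f} s "
          f"(conserved on the 15x15 grid: {coarse.total_dwell:.2f} s)")
    print(f"   coverage at 1/5 s and full epoch: {curve.coverage_pct[0]:.1f}% / "
          f"{curve.coverage_pct[4]:.1f}% / {full:.1f}%")
# The ASD-like preset views longer and scatters fixations more widely, so its
# full-epoch coverage exceeds the NT-like one for most seeds (single observers
# are noisy at short windows; cohort means order reliably).  Dwell time is
# conserved exactly through smoothing and downsampling.
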