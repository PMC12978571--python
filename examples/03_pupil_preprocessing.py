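"""Clean, downsample, baseline-correct and time-normalize one pupil
trace.

A raw 2,000 Hz-style trace with a blink gap is repaired (gap padded and
interpolated, +/-5 SD outliers removed), averaged into 10 ms bins,
baseline-corrected against the 0-300 ms fixation window, and finally
warped onto the unified [0, 1] time axis (stimulus epoch -> [0, 0.5],
imagination epoch -> [0.5, 1]) with cubic B-spline smoothing.
"""

import numpy as np

from loomdyn import preprocess as pp
from loomdyn.synth import PupilTrace
from loomdyn.trajectory import normalize_trace, warp_time

rng = np.random.default_rng(0)
keypress = 3_300.0  # jTTC of 3.0 s
t = np.arange(0.0, keypress, 0.5)  # 2,000 Hz
signal = 4.0 + 0.3 * np.sin(np.pi * np.clip((t - 300) / 3000, 0, 1))
d = signal + rng.normal(0, 0.02, len(t))
valid = ~((t >= 1500) & (t < 1700))  # 200 ms blink
d[~valid] = 0.0
raw = PupilTrace(trial_id="demo", t=t, d=d, valid=valid)

clean = pp.clean_trace(raw)
print(f"cleaned: {clean.meta['frac_interpolated']:.1%} of samples "
      "interpolated (blink + 100 ms padding each side)")

binned = pp.downsample(clean, bin_ms=10.0)
print(f"downsampled: {len(binned.t)} bins of 10 ms")

corrected = pp.baseline_correct(binned)
print(f"baseline mean {corrected.baseline_mean:.3f} mm subtracted; "
      f"corrected baseline now {corrected.d[corrected.t < 300].mean():.1e}")

means = pp.phase_means(corrected, jttc_s=3.0)
print("phase means (mm, baseline-corrected):",
      {k: round(v, 3) for k, v in means.items()})

traj = normalize_trace(corrected.t, corrected.d, keypress, trial_id="demo")
print(f"\nnormalized trajectory on {len(traj.grid)} grid points; "
      f"t = 800 ms maps to u = {warp_time(800.0, keypress):.2f} "
      "(mid-stimulus), smoothing penalty chosen by GCV: "
      f"lambda = {traj.gcv_lambda:.2g}")
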