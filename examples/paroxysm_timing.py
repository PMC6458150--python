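"""Detect per-pixel bursts of motion and quantify their synchrony.

Simulates a cube whose pixels switch from quiescence to large fluctuations
at prescribed frames (two spatial blocks, two frames apart), then recovers
the event timing per pixel at single-frame resolution, the onset histogram,
and the diffusion rate a molecular messenger would need to coordinate the
earliest onsets within one frame.
"""

import numpy as np

from ipws.paroxysm import event_timing_map, onset_histogram, synchrony_report
from ipws.phantom import simulate_paroxysm_cube

rng = np.random.default_rng(17)
shape = (32, 32)
onset = np.full(shape, 60)
onset[:, 16:] = 62                      # right half fires two frames later
cube = simulate_paroxysm_cube(201, onset, np.full(shape, 4.0),
                              mean_shift_map=np.full(shape, 1e-2), rng=rng)

tmap = event_timing_map(cube)
offsets, fractions, cumulative = onset_histogram(tmap)
print(f"event pixels            : {tmap.n_events} / {onset.size}")
print(f"onset offsets (frames)  : {[int(o) for o in offsets]}")
print(f"fraction per offset     : {np.round(fractions, 3).tolist()}")
print(f"cumulative within 35/70/105 ms: "
      f"{[round(float(cumulative[min(i, len(cumulative) - 1)]), 3) for i in (0, 1, 2)]}")

rep = synchrony_report(tmap, pixel_size_um=0.1)
print(f"first-frame extent      : {rep.max_distance_first_frame_um:.1f} um")
print(f"required regulator D    : {rep.required_regulator_D:.0f} um^2/s "
      f"({rep.msd_convention} convention)")
print("The two onset blocks, two frames apart, dominate the histogram "
      "(a handful of pixels localize one frame early, the detector's "
      "single-frame jitter).  For a cell-wide event spanning 30 um in one "
      "35 ms frame the same report yields D > 6400 um^2/s -- orders of "
      "magnitude beyond free protein diffusion (~20 um^2/s).")
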