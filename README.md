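# endotrack

Nanometre-scale particle tracking and first-passage-probability analysis of
intracellular organelle motility.

Early endosomes and other motor-driven cargo move along microtubules in
bursts: stochastic alternation between stationary *rests* and directed
*runs*, where a run is itself a chain of constant-speed segments whose speed
can change abruptly.  Characterizing this behaviour from high-speed
fluorescence movies (28 frames/s, ~85 nm pixels) requires subpixel
localization, careful track repair, and trajectory statistics that do not
presuppose a motion model.  `endotrack` implements that full chain for
cell biologists and biophysicists quantifying membrane-traffic dynamics:

- **Tracking** — spot detection on background-subtracted images, subpixel
  refinement by a polynomial-fit, Gaussian-weight (PFGW) scheme, shape-based
  rejection of non-vesicle extrema (eccentricity, radius, skewness), and
  frame-to-frame linking.
- **Track operations** — stitching of fragments broken by defocus (end and
  start within 5 px and 14 frames), spatially smoothed and coarsened contours
  (smoothing scale L<sub>pix</sub> ≈ 340 nm), and projection onto the contour
  to obtain the arc-length displacement series *x*(*T*).
- **Run/rest segmentation** — rests are stretches of more than 14 frames
  (0.5 s) moving less than one pixel (85 nm); runs displace ≥ 85 nm at
  ≥ 0.17 µm/s.  Population summaries report percent time running (± s.e.m.
  across movies) and the fraction of particles that never run, plus
  inward/outward classification relative to the cell centre.
- **First-passage probability (FPP)** — for each passage length *L*, the
  distribution of the smallest *t* with |**r**(*T*+*t*) − **r**(*T*)| ≥ *L*
  over every starting time point *T* of every track, normalized by the total
  number of time points; the speed form *F*(*u*, *L*) uses *u* = *L*/*t*.
  Fixed-cell (noise-only) tracks processed identically give the static-error
  floor.
- **Parsing** — decomposition of *x*(*T*) for long (> 2 µm) tracks into
  constant-speed segments by an exact penalized piecewise-linear change-point
  fit; survival curves of segment speeds, distance-per-speed-bin tables, and
  fast-run (> 5 µm/s) selection.
- **Synthetic data** — a ground-truthed simulator of run/rest motion
  (exponential durations, per-segment speeds up to 8 µm/s, segment distances
  ~1.4 µm on average, Gaussian localization noise) plus movie rendering and
  fixed-cell fixtures, so every stage is verifiable without raw movies.

## Worked example

```python
import numpy as np
from endotrack import (AcquisitionGeometry, build_contour, classify_runs_rests,
                       fpp_distribution, mean_passage_speed, parse_segments,
                       select_long_tracks, summarize_population)
from endotrack.synthetic import control_params, simulate_population

geom = AcquisitionGeometry(field_size=(80.0, 80.0), cell_centre=(40.0, 40.0))
pop = simulate_population(control_params(seed=0), geom, n_tracks=20, n_frames=1000)
tracks = [t for t, _ in pop]

contours, annotations = {}, []
for t in tracks:
    contours[t.track_id] = build_contour(t)
    annotations.append(classify_runs_rests(contours[t.track_id].arc_positions,
                                           geom, track_id=t.track_id))
summary = summarize_population(annotations)
print(f"time running: {summary.pct_time_running:.1f}%  "
      f"never running: {summary.pct_never_running:.1f}%")

results = fpp_distribution(tracks, geom, L_set=[0.5, 1.0, 3.0, 9.0])
print(mean_passage_speed(results).to_string(index=False))

long_tracks = select_long_tracks(tracks, 2.0)
segments = []
for t in long_tracks:
    segments += parse_segments(contours[t.track_id].arc_positions, geom,
                               frames=t.frames, track_id=t.track_id)
speeds = [s.speed for s in segments]
print(f"{len(long_tracks)} long tracks -> {len(segments)} constant-speed "
      f"segments, max speed {max(speeds):.1f} um/s")
```

prints

```
time running: 34.8%  never running: 0.0%
  L  n_passages  mean_speed
0.5       19158    1.361131
1.0       18995    1.505946
3.0       17706    1.658055
9.0       12743    1.677366
20 long tracks -> 943 constant-speed segments, max speed 8.3 um/s
```

The run-time percentage is the fraction of tracked frames inside runs, the
FPP table shows that mean passage speed rises with passage length (long
passages are completed only by fast, persistent translocations), and parsing
recovers segment speeds up to the generator's 8 µm/s ceiling.

A command-line interface wraps the same stages
(`endotrack simulate | track | stitch | segment | fpp | parse | report`);
`endotrack report` runs the whole pipeline and writes delimited tables, a
Table-style motility summary, and a plain-text report embedding the fully
resolved configuration.

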