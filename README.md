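# larvascape

Analysis pipeline for two-channel volumetric calcium imaging of
proprioceptors in crawling and exploring *Drosophila* larvae.

The six multidendritic proprioceptor types of the larval body wall (vpda,
ddaD, ddaE, dbd, vbd, dmd1) report segment deformation during behavior.
High-speed volumetric light-sheet imaging of larvae co-expressing a calcium
indicator (green, GCaMP-like) and a static fiducial (red, tdTomato-like) at
10 volumes/s yields movies from which this package extracts, per cell:

* a 3-D soma track on the static red channel (seeded manually, followed by
  iterated thresholded centroiding, with conflict resolution and manual
  correction hooks);
* ratiometrically corrected activity
  `ΔR/R₀ = (R − R₀)/R₀` with `R = (green − bg_g)/(red − bg_r)` and `R₀` the
  mean of the lowest 10% of ratio values — the ratio cancels intensity
  changes common to both channels (motion through the sheet);
* contraction events from the inter-cell distance `d(t)` to the homologous
  neuron in the adjacent segment: the event time axis is normalized by the
  excursion's full width at half maximum (1 A.U. = 1 FWHM, maximum
  contraction at 0), activity amplitudes optionally normalized to 1, with
  resting-phase ([−1.5, −1] A.U.) and contraction-phase ([−1, 1] A.U.)
  statistics and one-tailed paired t tests on half-maximum activation times;
* for exploration behavior, the two-bar decomposition: two rigid bars of
  length 2p separated by S(t), the anterior rotated by θ(t); the left/right
  inter-cell distances obey `r_R − r_L ≈ 2p·sin θ` (turning metric,
  retraction cancels) and `r_L + r_R ≈ 2S` (retraction metric, turning
  cancels), and the same difference/sum applied to left/right calcium
  signals.

Because the kind of imaging data this targets is not publicly deposited, the
package ships a first-class synthetic generator (`larvascape.synthlarva`)
producing ground-truthed two-channel movies — peristaltic crawl waves or
turning/retraction exploration, first-order calcium kinetics (~400 ms
decay), common intensity modulation, and read noise — which the test suite
uses to validate every stage against known truth.

## Worked example

```python
import numpy as np
from larvascape.synthlarva import SimulationConfig, run_simulation, truth_to_seeds
from larvascape import tracking, signals, events

cfg = SimulationConfig(mode="crawl", duration=6.0, noise_sd=10.0, seed=1)
truth, movie = run_simulation(cfg)          # (60, 2, 19, 185, 50) voxels, 2 um
tracks = tracking.track_movie(movie, truth_to_seeds(truth))
traces = signals.extract_traces(movie, tracks)

byid = {t.cell_id: t for t in tracks}
dtr = events.inter_cell_distance(byid["ddaE_s2_L"], byid["ddaE_s1_L"])
evs = events.apply_exclusion_rules(events.detect_contractions(dtr), dtr)
ev = [e for e in evs if e.included][0]
```

This prints (seed 1):

```
RMS tracking error: 0.169 um
resting length: 80.1 um
event: t_max = 3.00 s, FWHM = 0.97 s, depth = 27.7 um
baseline R0 = 0.931, peak dR/R0 = 0.99
half-max time: -0.24 A.U.
```

The tracked somata sit within 0.2 µm of the generator's ground truth at a
peak-signal-to-noise ratio of 10; the segment between the s1 and s2 ddaE
cells rests at ~80 µm and contracts by ~28 µm (35%) as the wave passes at
t = 3 s, with a 0.97 s FWHM; the cell's calcium activity reaches half of its
maximum about a quarter of a contraction-width before maximum contraction.

A command-line interface wraps the same pipeline:

```sh
larvascape simulate --mode crawl --out sim/ --seed 1
larvascape track   --movie sim/movie.h5 --seeds sim/seeds.csv --out tracks.csv
larvascape extract --movie sim/movie.h5 --tracks tracks.csv --out traces.csv
larvascape events  --tracks tracks.csv --traces traces.csv --pairs pairs.csv --out out/
larvascape explore --tracks tracks.csv --traces traces.csv --out out/
```

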