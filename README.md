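# hatchtrack

Identity-preserving tracking of *Drosophila melanogaster* developmental
stages in rearing vials, extraction of pupation/eclosion events, and
circadian rhythm analysis of eclosion timing — together with a synthetic
colony simulator so the full pipeline runs and is testable without any
imaging hardware.

## Who this is for

Chronobiology and developmental-biology labs monitor fly vials with
long-term imaging systems: a camera captures one frame every 10 minutes
for two weeks, and a detector emits per-frame bounding boxes classified
as wandering L3 *larva*, *full pupa*, *empty pupa*, *adult fly* or
*out-of-focus*. `hatchtrack` turns those per-frame detections into
per-specimen life histories and rhythm statistics:

1. **Tracking.** Detections of consecutive frames are linked by solving a
   maximum-weight bipartite matching (Hungarian algorithm) on a
   dummy-augmented IoU matrix. With boxes $b_i^t$ in frame $t$ and
   $b_j^{t+1}$ in frame $t{+}1$, the score matrix holds the Jaccard
   overlap $J(b_i, b_j) = |b_i \cap b_j| / |b_i \cup b_j|$, gated by the
   association rule: a pair is admissible only if $J > 0.6$ (strict) and
   the stage labels are the same or developmentally adjacent
   (larva ↔ full pupa, full ↔ empty pupa; an adult is always a new
   object). $n$ dummy rows and $m$ dummy columns allow objects to appear
   and disappear. Tracks last seen at $t{-}2 \dots t{-}4$ remain
   candidates, so occasionally missed detections do not break identities.
2. **Post-processing.** Per-track stage sequences are cleaned with a
   centered median filter (window 5) over the stage ordinals; tracks
   shorter than 30 frames (mostly untrackable flying adults) are
   discarded. A time point $t$ is marked as pupation/eclosion when the
   majority of the window $[t, \dots, t{+}\tau{-}1]$ (default
   $\tau = 7$) carries the full-/empty-pupa label.
3. **Rhythm analysis.** Eclosion events are aggregated into 2-hour bins
   and the free-running period is estimated as the peak of the classical
   normalized Lomb-Scargle periodogram over a 14–34 h grid — e.g. ~24 h
   for wild-type flies in constant darkness, ~19 h / ~28 h for
   short-/long-period clock mutants, no significant peak for arrhythmic
   mutants.
4. **Simulation.** A synthetic colony generator draws eclosion times from
   a raised-cosine inhomogeneous Poisson process
   $\lambda(t) = r\,(1 + A \cos 2\pi (t - \phi)/P)$, animates larvae,
   stationary pupae and teleporting adults inside up to three vial
   regions, and corrupts the ground truth with a detector noise model
   (class confusion, box jitter, spurious out-of-focus boxes) whose
   default confusion rates follow published per-class detector
   accuracies (full/empty pupae 95 %/97 %, adults 86 %, larvae 84 %).

Results are stored in HDF5 (per-track groups + a flat event table) and
CSV for downstream chronobiology tooling.

## Worked example

Simulate a noisy 14-day recording of 20 wild-type animals, track it, and
estimate the eclosion rhythm:

```sh
hatchtrack simulate --preset iso31 --seed 3 --n-animals 20 --out sim.jsonl
printf 'tracked_classes: [full_pupa, empty_pupa]\n' > cfg.yaml
hatchtrack run --detections sim.jsonl --config cfg.yaml --out results.h5
```

which prints

```json
{
  "n_frames": 2016,
  "n_tracks": 20,
  "n_pupation": 5,
  "n_eclosion": 20,
  "peak_period_h": 24.099999999999966,
  "peak_p_value": 0.013342460616816364
}
```

All 20 simulated specimens are recovered as pupal tracks despite
detector-level class noise, every eclosion is found, and the periodogram
peak (24.1 h, p ≈ 0.013) matches the simulated 24-hour rhythm.
(`n_pupation` counts only tracks whose larva→pupa transition was
observable; with pupae-only tracking most tracks begin as pupae.)

The same steps are available as library calls:

```python
from hatchtrack import (PRESETS, NoiseModel, simulate_colony,
                        corrupt_detections, track_sequence, TrackerConfig,
                        StageLabel, filter_short_tracks, smooth_stages,
                        collect_events, EventType, estimate_rhythm)

gt = simulate_colony(PRESETS["iso31"], rng_seed=3, n_animals=20)
frames = corrupt_detections(gt, NoiseModel.default(), rng_seed=4)
cfg = TrackerConfig(tracked_classes={StageLabel.FULL_PUPA, StageLabel.EMPTY_PUPA})
tracks = filter_short_tracks(track_sequence(frames, cfg), cfg.min_track_length)
for tr in tracks:
    smooth_stages(tr, cfg.median_window)
events = collect_events(tracks, cfg, event_type=EventType.ECLOSION)
print(estimate_rhythm(events).peak_period_h)
```

## HDF5 layout

```
/meta                         attrs: format_version, config (JSON), frame_interval_min
/tracks/<id>/frames           frame indices
/tracks/<id>/bboxes           (n, 4) pixel corners
/tracks/<id>/stages_raw       stage ordinals (larva=0, full pupa=1, empty pupa=2, adult=3)
/tracks/<id>/stages_smoothed  after median filtering
/tracks/<id>/observed         False for gap-bridged frames
/events                       track_id, event_type, frame_index, time_min
/sensors/<channel>            optional environmental time series
```

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
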