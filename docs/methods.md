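# Methods

## Tracking model

Tracking is detection-based: each frame arrives as a set of classified
bounding boxes, and identities are propagated by bipartite matching
between the active tracks and the new frame's detections.

**Association score.** The spatial score is the intersection-over-union
(Jaccard index) of axis-aligned boxes in continuous pixel coordinates
(origin top-left, closed intervals, area = product of side lengths).
A track–detection pair is *admissible* when its IoU strictly exceeds the
threshold (default 0.6 — an IoU of exactly 0.6 is rejected) **and** the
stage labels are the same or developmentally adjacent. The adjacency
graph is {larva↔larva, larva↔full pupa, full↔full, full↔empty pupa,
empty↔empty, adult↔adult}: a specimen can cross at most one
developmental boundary between 10-minute frames, and the adult emerging
at eclosion is a newly appearing free-moving object rather than a
continuation of the pupal identity. The relation is symmetric because a
single-frame misclassification can transiently "reverse" a stage; the
median filter repairs such flips later.

**Dummy augmentation.** With m candidate tracks and n detections the
score matrix is augmented to shape (m+n)×(n+m): the real block holds the
gated IoU, with inadmissible pairs set to a FORBIDDEN score of −1; all
dummy entries are 0, including the dummy–dummy block. Maximizing the
total score with the Hungarian algorithm (via
`scipy.optimize.linear_sum_assignment`) then yields exactly the intended
behavior: any admissible pair (score > 0.6) beats routing both members
through dummies (0), and a FORBIDDEN pair (−1) never beats it, so
unmatched detections found new tracks and unmatched tracks coast.
The solver is deterministic for fixed input, which makes the whole
pipeline reproducible; among matchings of exactly equal total weight the
particular one returned is an implementation detail of the solver.

**Gap bridging.** Candidate tracks are those last *observed* within the
previous `max_gap_frames` frames (default 4: t−1 … t−4). A candidate is
represented by its last observed box and raw stage — a "hold" model with
no motion extrapolation, appropriate because larvae are slow and pupae
strictly immobile at a 10-minute sampling interval. When a track
re-associates across a gap, the skipped frames are filled with the held
box/stage and flagged `observed=False`; track length counts these
covered frames. A track unobserved for `max_gap_frames` consecutive
frames is closed and never reopened.

**Birth policy.** Any unmatched detection of a tracked class founds a
track immediately (no birth delay). Spurious short tracks — mostly
flying adults, which cannot be followed at this frame rate — are removed
afterwards by the minimum-length filter (default 30 frames, strict:
length 29 is discarded, 30 kept).

## Stage smoothing and event extraction

Stage sequences are cleaned with a centered median filter (default
window 5) over the stage *ordinals* larva=0 < full pupa=1 < empty
pupa=2 < adult=3. The ordering places adult above empty pupa so that
pupal/adult confusions do not collapse into larva. The first/last
⌊window/2⌋ frames keep their raw labels (no window shrinking — a
simplest-defensible edge policy affecting ≤ 2 frames per end). Smoothing
runs after gap filling, so the filter sees a gapless sequence.

Events use a sliding majority window of τ frames (default 7, i.e.
70 minutes): the earliest time point t such that ≥ ⌈τ/2⌉ = 4 of the
labels in [t, …, t+τ−1] are full pupa (pupation) or empty pupa
(eclosion) is marked. Consequences of this literal rule, deliberately
kept:

- the marked frame *precedes* the visible transition by up to
  ⌊τ/2⌋ = 3 frames and can never trail it (verified as an invariant on
  noise-free simulations);
- windows truncated by the end of a track are not evaluated;
- pupation additionally requires an earlier non-full-pupa frame, so a
  track that is a pupa from its first frame (e.g. when only pupal
  classes are tracked) yields an eclosion but no pupation event.

## Rhythm analysis

Eclosion events are aggregated into half-open uniform bins (default 2 h)
and the classical normalized Lomb-Scargle periodogram is computed on the
(bin center, count) pairs after mean subtraction, with the standard
per-frequency phase offset and normalization by the series variance.
The periodogram is therefore invariant under adding a constant to all
counts and under positive rescaling. It is computed on binned counts —
matching how eclosion data are usually summarized — not on raw event
times. The default period grid is 14–34 h in 0.1 h steps, bracketing
wild-type (~24 h) and short-/long-period mutant rhythms (19 h, 28.3 h);
the grid must stay below the series span. Peak significance uses the
standard exponential null, p = 1 − (1 − e^(−z))^M with
M = span / min(period) independent frequencies — an approximation that
is adequate for ranking and for the arrhythmicity check, not an exact
test. A constant series returns zero power everywhere and p = 1.

The spectral resolution of a length-T recording near period P is about
P²/T; with T = 336 h this is ≈ 1.7 h at 24 h, 2.4 h at 28.3 h and
1.1 h at 19 h, which is the tolerance used for period-recovery checks.

## Synthetic colony generator

The generator defines the study conditions under which the pipeline is
validated.

**Eclosion process.** Times are drawn from an inhomogeneous Poisson
process with raised-cosine intensity
λ(t) = r·(1 + A·cos 2π(t−φ)/P) for t ≥ onset, sampled by thinning.
Defaults: baseline r = 0.5 events/h, amplitude A = 0.8, phase φ = 0,
duration 336 h (14 days), onset 96 h — eclosion begins around day 4
once the fastest animals complete development. Presets: `iso31`
(P = 24 h), `per_short` (19 h), `per_long` (28.3 h, onset 120 h — the
long-period mutant ecloses about a day later), `per0` (A = 0,
arrhythmic). When an exact colony size is requested, that many times are
drawn i.i.d. from the normalized intensity (the process conditioned on
its count).

**Scene.** Up to three 300 px-wide vial strips in a 1200×900 px frame.
Each specimen pupariates at a dedicated wall site (sites spaced so pupal
boxes never touch), is strictly stationary through the full- and
empty-pupa stages, and before that wanders as a larva for 24 h on a slow
Brownian bridge (step σ = 1.5 px/frame, start ~40 px from the site)
pinned to end at the pupariation site, so the larva→pupa handover
satisfies the IoU gate. Pupal duration defaults to 96 h. The emerging
adult is a separate object that jumps to a uniform random position in
its vial every frame for 24 h — deliberately untrackable at 10-minute
sampling, mirroring the scope of the real system. Box sizes: larva
10×22 px, pupa 12×26 px, adult 16×16 px.

**Noise model.** Per ground-truth box per frame: optional miss, class
resampling from a per-class confusion row over {four stages,
out-of-focus, background}, and Gaussian corner jitter; spurious
out-of-focus boxes are added at a Poisson rate per frame. The default
confusion rows encode published per-class detector accuracies — full
pupa 95 % (2 % empty pupa), empty pupa 97 % (1 % full pupa), adult 86 %
(12 % out-of-focus), larva 84 % (8 % full pupa); background false
negatives 1 % (3 % for larvae). Residual off-diagonal mass not printed
in that evaluation is assigned to the out-of-focus class. Default
corner jitter is σ = 0.5 px — sub-pixel localization, realistic for a
modern box regressor on stationary, high-contrast pupae — and spurious
rate 2 boxes/frame. Miss/jitter magnitudes are assumptions, exposed as
parameters.

**What the simulator does not emulate:** occlusions and clutter near
the food, gradual pupariation appearance (the larva→pupa switch is
instantaneous), out-of-focus *specimens* on the vial's far side,
illumination drift, and detector confidence structure (confidence is
constant). Passing tests therefore demonstrate the correctness of the
association, smoothing, event and rhythm machinery under controlled
noise — not detector performance on real imagery.

## Vial calibration

The original one-time calibration procedure is not published; the
functional contract (per-vial regions from backlit frames) is
implemented as: Otsu threshold of the mean frame → column-wise
foreground fraction → smoothing over ~2 % of the width → up to three
widest plateaus above half the peak density become full-height ROIs,
ordered left to right. A manual ROI override is always available, and a
detection whose center lies on a shared ROI boundary goes to the lower
vial id (arbitrary but deterministic).

## Numerical and design choices

- Stage labels are stored on disk as their ordinal codes; times as
  minutes since experiment start (frame index × capture interval).
- The event-count conservation, threshold monotonicity and
  matching-optimality properties are enforced by tests against
  brute-force oracles (exhaustive enumeration for m, n ≤ 6).
- Periodogram cross-checked against an independent reference
  implementation (`scipy.signal.lombscargle`) on random series.
- Problem sizes used in validation: 50-animal colonies over 2016 frames
  for identity preservation and event timing; 20 seeds per preset for
  period recovery; 100 seeds for the arrhythmicity rate. These sizes
  match the 14-day, three-vial experimental design the package targets.

## Known limitations

- **Localization noise sensitivity.** Because unmatched detections found
  tracks immediately, a single IoU-gate failure on a stationary pupa
  spawns a competing track that can permanently steal the identity; with
  corner jitter ≳ 1 px on pupa-sized boxes (~3 % gate failures/frame)
  long tracks fragment noticeably. The strict 0.6 gate assumes the
  detector localizes stationary objects to sub-pixel accuracy.
- The majority-window event rule is systematically early by up to
  ⌊τ/2⌋ frames; downstream binning at 2 h (12 frames) makes this bias
  negligible for rhythm estimation, but absolute event times inherit it.
- Pupation timing is intrinsically less sharp than eclosion (the
  larva→pupa transition is gradual in real imagery); the simulator's
  instantaneous switch does not probe this.
- The Lomb-Scargle significance is the approximate exponential null;
  for publication-grade p-values use a permutation test on the binned
  series.
- Adults are not tracked (frame rate far too low); only their presence
  as detections is modeled.
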