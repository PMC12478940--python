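"""Synthetic colony generator: ground-truth trajectories, rhythmic
eclosion times and noisy detection streams.

The generator emulates a 14-day recording of up to three backlit rearing
vials sampled every 10 minutes.  Eclosion times follow a raised-cosine
inhomogeneous Poisson process (rate lambda(t) = baseline * (1 +
amplitude * cos(2*pi*(t - phase)/period)) after a development onset
delay), the simplest process with a controllable circadian period and
rhythm strength.  Each specimen appears as a slowly wandering L3 larva,
pupariates at a fixed wall site, stays immobile through the full- and
empty-pupa stages, and spawns a fast-moving adult object at eclosion
that is effectively untrackable at the 10-minute interval.  Detection
noise (misses, class confusion, box jitter, spurious out-of-focus boxes)
reproduces published per-class detector accuracies by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .core import BBox, Detection, FrameDetections, StageLabel

__all__ = [
    "RhythmPreset",
    "PRESETS",
    "NoiseModel",
    "VialGeometry",
    "SpecimenTruth",
    "GroundTruth",
    "sample_eclosion_times",
    "simulate_colony",
    "corrupt_detections",
    "render_frame",
]

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class RhythmPreset:
    """Parameters of the rhythmic eclosion process.

    ``onset_h`` is the development offset: eclosion events only begin
    once the fastest animals have completed development (~day 4).
    """

    name: str
    period_h: float
    amplitude: float = 0.8
    phase_h: float = 0.0
    baseline_rate: float = 0.5  # events per hour
    n_animals: Optional[int] = None
    duration_h: float = 336.0  # 14 days
    onset_h: float = 96.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must be in [0, 1]")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.period_h <= 0:
            raise ValueError("period_h must be positive")

    def rate(self, t_h: float) -> float:
        """Instantaneous eclosion rate lambda(t) in events/h; zero before onset."""
        if t_h < self.onset_h:
            return 0.0
        return self.baseline_rate * (
            1.0 + self.amplitude * math.cos(2.0 * math.pi * (t_h - self.phase_h) / self.period_h)
        )


# Genotype presets: wild type free-runs at ~24 h; the short- and
# long-period clock mutants shift the eclosion rhythm to 19 h and 28.3 h
# (the long-period mutant additionally ecloses ~1 day later); the
# arrhythmic null keeps the average eclosion rate but no modulation.
PRESETS: dict[str, RhythmPreset] = {
    "iso31": RhythmPreset(name="iso31", period_h=24.0),
    "per_short": RhythmPreset(name="per_short", period_h=19.0),
    "per_long": RhythmPreset(name="per_long", period_h=28.3, onset_h=120.0),
    "per0": RhythmPreset(name="per0", period_h=24.0, amplitude=0.0),
}


def sample_eclosion_times(preset: RhythmPreset, rng_seed: RngLike = 0) -> list[float]:
    """Draw eclosion times (hours) from the inhomogeneous Poisson process
    by thinning against the rate ceiling; reproducible given the seed."""
    rng = _rng(rng_seed)
    if preset.baseline_rate == 0.0:
        return []
    lam_max = preset.baseline_rate * (1.0 + preset.amplitude)
    times: list[float] = []
    t = preset.onset_h
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= preset.duration_h:
            break
        if rng.random() * lam_max < preset.rate(t):
            times.append(t)
    return times


def _sample_n_eclosion_times(preset: RhythmPreset, n: int, rng: np.random.Generator) -> list[float]:
    """Draw exactly n i.i.d. times from the normalized rate density
    (the Poisson process conditioned on its count)."""
    lam_max = preset.baseline_rate * (1.0 + preset.amplitude)
    if lam_max == 0.0:
        raise ValueError("cannot place animals with zero eclosion rate")
    times: list[float] = []
    while len(times) < n:
        t = rng.uniform(preset.onset_h, preset.duration_h)
        if rng.random() * lam_max < preset.rate(t):
            times.append(t)
    return sorted(times)


@dataclass(frozen=True)
class VialGeometry:
    """Frame size and the vertical vial regions within it (pixels)."""

    frame_width: int = 1200
    frame_height: int = 900
    vial_rois: tuple[BBox, ...] = ()

    @classmethod
    def default(cls, n_vials: int = 3) -> "VialGeometry":
        if not 1 <= n_vials <= 3:
            raise ValueError("1..3 vials supported")
        width, height = 1200, 900
        strip_w, gap = 300, 100
        rois = tuple(
            BBox(gap + i * (strip_w + gap), 0.0, gap + i * (strip_w + gap) + strip_w, float(height))
            for i in range(n_vials)
        )
        return cls(frame_width=width, frame_height=height, vial_rois=rois)


# stage-dependent box sizes (w, h) in pixels
_LARVA_SIZE = (10.0, 22.0)
_PUPA_SIZE = (12.0, 26.0)
_ADULT_SIZE = (16.0, 16.0)


def _box_at(cx: float, cy: float, size: tuple[float, float]) -> BBox:
    w, h = size
    return BBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


@dataclass
class SpecimenTruth:
    """Ground-truth life history of one specimen (larva -> full pupa ->
    empty pupa); the emerging adult is a separate object."""

    specimen_id: int
    vial_id: int
    eclosion_time_h: float
    appear_frame: int
    pupation_frame: int
    eclosion_frame: int
    frames: dict[int, tuple[BBox, StageLabel]] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Complete synthetic scene: per-frame specimen and adult boxes,
    true event frames and the vial geometry."""

    specimens: list[SpecimenTruth]
    adults: list[dict[int, BBox]]  # one dict per emerged adult
    geometry: VialGeometry
    n_frames: int
    frame_interval_min: float

    @property
    def eclosion_times_h(self) -> list[float]:
        return [s.eclosion_time_h for s in self.specimens]

    def to_frame_detections(self, include_adults: bool = True) -> list[FrameDetections]:
        """Perfect (noise-free) detection stream for the whole recording."""
        frames = []
        for f in range(self.n_frames):
            dets = []
            for sp in self.specimens:
                if f in sp.frames:
                    bbox, stage = sp.frames[f]
                    dets.append(Detection(bbox=bbox, stage=stage, vial_id=sp.vial_id))
            if include_adults:
                for adult in self.adults:
                    if f in adult:
                        dets.append(Detection(bbox=adult[f], stage=StageLabel.ADULT))
            frames.append(
                FrameDetections(frame_index=f, time_min=f * self.frame_interval_min, detections=dets)
            )
        return frames


def _pupation_sites(geometry: VialGeometry, rng: np.random.Generator) -> list[list[tuple[float, float, int]]]:
    """Candidate pupariation sites (cx, cy, vial_id) along both walls of
    each vial, vertically spaced so neighboring pupal boxes never touch."""
    spacing = _PUPA_SIZE[1] + 6.0
    margin = 20.0
    per_vial: list[list[tuple[float, float, int]]] = []
    for vid, roi in enumerate(geometry.vial_rois):
        ys = np.arange(roi.y_min + margin, roi.y_max - margin, spacing)
        sites = [(roi.x_min + 12.0, float(y), vid) for y in ys]
        sites += [(roi.x_max - 12.0, float(y), vid) for y in ys]
        order = rng.permutation(len(sites))
        per_vial.append([sites[i] for i in order])
    return per_vial


def simulate_colony(
    preset: RhythmPreset,
    geometry: Optional[VialGeometry] = None,
    rng_seed: RngLike = 0,
    n_animals: Optional[int] = None,
    pupal_duration_h: float = 96.0,
    larval_duration_h: float = 24.0,
    adult_lifetime_h: float = 24.0,
    frame_interval_min: float = 10.0,
    larval_step_px: float = 1.5,
    larval_start_spread_px: float = 40.0,
) -> GroundTruth:
    """Simulate a colony with rhythmic eclosion.

    Each specimen gets an eclosion time from the preset's Poisson process
    (or exactly ``n_animals`` i.i.d. draws from its normalized density),
    pupariates ``pupal_duration_h`` earlier at a dedicated wall site, and
    wanders as a larva for ``larval_duration_h`` before that on a slow
    Brownian bridge ending at the site.  Pupal boxes are strictly
    stationary.  The emerging adult jumps to a uniformly random position
    in its vial every frame for ``adult_lifetime_h``.
    """
    rng = _rng(rng_seed)
    geometry = geometry or VialGeometry.default()
    n = n_animals if n_animals is not None else preset.n_animals
    if n is not None:
        if n < 1:
            raise ValueError("n_animals must be >= 1")
        times = _sample_n_eclosion_times(preset, n, rng)
    else:
        times = sample_eclosion_times(preset, rng)

    sites_per_vial = _pupation_sites(geometry, rng)
    n_vials = len(geometry.vial_rois)
    capacity = [len(s) for s in sites_per_vial]
    # round-robin vial assignment; overflow means the vials cannot hold the colony
    per_vial_counts = [len(range(v, len(times), n_vials)) for v in range(n_vials)]
    if any(c > cap for c, cap in zip(per_vial_counts, capacity)):
        raise ValueError(
            f"geometry too small for {len(times)} animals "
            f"(per-vial capacity {capacity})"
        )

    n_frames = int(round(preset.duration_h * 60.0 / frame_interval_min))
    pupal_frames = int(round(pupal_duration_h * 60.0 / frame_interval_min))
    larval_frames = int(round(larval_duration_h * 60.0 / frame_interval_min))
    adult_frames = int(round(adult_lifetime_h * 60.0 / frame_interval_min))

    specimens: list[SpecimenTruth] = []
    adults: list[dict[int, BBox]] = []
    vial_cursor = [0] * n_vials
    for sid, e_h in enumerate(times):
        vid = sid % n_vials
        roi = geometry.vial_rois[vid]
        site_x, site_y, _ = sites_per_vial[vid][vial_cursor[vid]]
        vial_cursor[vid] += 1

        ecl_frame = min(int(round(e_h * 60.0 / frame_interval_min)), n_frames - 1)
        pup_frame = max(ecl_frame - pupal_frames, 0)
        appear_frame = max(pup_frame - larval_frames, 0)

        sp = SpecimenTruth(
            specimen_id=sid,
            vial_id=vid,
            eclosion_time_h=e_h,
            appear_frame=appear_frame,
            pupation_frame=pup_frame,
            eclosion_frame=ecl_frame,
        )

        # larval wandering: slow Brownian bridge from a start point near the
        # site, pinned to land on the pupariation site
        k = pup_frame - appear_frame
        if k > 0:
            start = np.array([site_x, site_y]) + rng.normal(0.0, larval_start_spread_px, 2)
            walk = np.cumsum(rng.normal(0.0, larval_step_px, (k, 2)), axis=0)
            frac = (np.arange(1, k + 1) / k)[:, None]
            bridge = walk - frac * walk[-1]
            path = start + frac * (np.array([site_x, site_y]) - start) + bridge
            path[:, 0] = np.clip(path[:, 0], roi.x_min + 8, roi.x_max - 8)
            path[:, 1] = np.clip(path[:, 1], roi.y_min + 12, roi.y_max - 12)
            for i, f in enumerate(range(appear_frame, pup_frame)):
                sp.frames[f] = (_box_at(path[i, 0], path[i, 1], _LARVA_SIZE), StageLabel.LARVA)

        pupa_box = _box_at(site_x, site_y, _PUPA_SIZE)
        for f in range(pup_frame, ecl_frame):
            sp.frames[f] = (pupa_box, StageLabel.FULL_PUPA)
        for f in range(ecl_frame, n_frames):
            sp.frames[f] = (pupa_box, StageLabel.EMPTY_PUPA)
        specimens.append(sp)

        adult: dict[int, BBox] = {}
        for f in range(ecl_frame, min(ecl_frame + adult_frames, n_frames)):
            cx = rng.uniform(roi.x_min + 10, roi.x_max - 10)
            cy = rng.uniform(roi.y_min + 10, roi.y_max - 10)
            adult[f] = _box_at(cx, cy, _ADULT_SIZE)
        adults.append(adult)

    return GroundTruth(
        specimens=specimens,
        adults=adults,
        geometry=geometry,
        n_frames=n_frames,
        frame_interval_min=frame_interval_min,
    )


# ---------------------------------------------------------------------------
# detection noise

_BACKGROUND = "background"
_CONFUSION_OUTCOMES = [
    StageLabel.LARVA,
    StageLabel.FULL_PUPA,
    StageLabel.EMPTY_PUPA,
    StageLabel.ADULT,
    StageLabel.OUT_OF_FOCUS,
    _BACKGROUND,
]


@dataclass
class NoiseModel:
    """Detector noise: per-class miss probability, class confusion,
    bounding-box jitter and spurious out-of-focus detections.

    Confusion rows are over {larva, full pupa, empty pupa, adult,
    out-of-focus, background}; a ``background`` outcome drops the
    detection (false negative), ``out-of-focus`` emits the box with the
    OUT_OF_FOCUS label.
    """

    miss_prob: dict[StageLabel, float] = field(default_factory=dict)
    confusion: dict[StageLabel, dict] = field(default_factory=dict)
    bbox_jitter_px: float = 0.0
    spurious_rate: float = 0.0

    def __post_init__(self) -> None:
        for stage, row in self.confusion.items():
            total = sum(row.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"confusion row for {stage.name} sums to {total}, not 1")
            if any(p < 0 for p in row.values()):
                raise ValueError("confusion probabilities must be >= 0")
        for p in self.miss_prob.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("miss probabilities must be in [0, 1]")

    @classmethod
    def zero(cls) -> "NoiseModel":
        """Perfect detector: output equals ground truth."""
        return cls(
            miss_prob={s: 0.0 for s in _CONFUSION_OUTCOMES[:4]},
            confusion={s: {s: 1.0} for s in _CONFUSION_OUTCOMES[:4]},
        )

    @classmethod
    def default(cls) -> "NoiseModel":
        """Detector-like noise matching published per-class accuracies:
        full/empty pupae 95%/97% (occasionally confused with each other),
        adults 86% (12% out-of-focus), larvae 84% (8% full pupa);
        background false negatives 1% (3% for larvae).  Unprinted
        residual mass goes to the out-of-focus class."""
        L, FP, EP, A = (
            StageLabel.LARVA,
            StageLabel.FULL_PUPA,
            StageLabel.EMPTY_PUPA,
            StageLabel.ADULT,
        )
        OOF = StageLabel.OUT_OF_FOCUS
        return cls(
            miss_prob={s: 0.0 for s in (L, FP, EP, A)},
            confusion={
                L: {L: 0.84, FP: 0.08, OOF: 0.05, _BACKGROUND: 0.03},
                FP: {FP: 0.95, EP: 0.02, OOF: 0.02, _BACKGROUND: 0.01},
                EP: {EP: 0.97, FP: 0.01, OOF: 0.01, _BACKGROUND: 0.01},
                A: {A: 0.86, OOF: 0.13, _BACKGROUND: 0.01},
            },
            bbox_jitter_px=0.5,
            spurious_rate=2.0,
        )


def corrupt_detections(
    gt: GroundTruth, noise: NoiseModel, rng_seed: RngLike = 0
) -> list[FrameDetections]:
    """Apply the noise model to the ground-truth boxes.

    Per box per frame: drop with the class miss probability, else
    resample the class from its confusion row (a background outcome also
    drops the box), then jitter the corners with Gaussian noise of the
    stated scale.  Spurious out-of-focus boxes are added at the stated
    Poisson rate per frame.  Reproducible given the seed.
    """
    rng = _rng(rng_seed)
    cum = {
        stage: (
            np.cumsum([row.get(o, 0.0) for o in _CONFUSION_OUTCOMES]),
            _CONFUSION_OUTCOMES,
        )
        for stage, row in noise.confusion.items()
    }
    width, height = gt.geometry.frame_width, gt.geometry.frame_height
    clean = gt.to_frame_detections()
    out = []
    for fd in clean:
        dets = []
        for det in fd.detections:
            if rng.random() < noise.miss_prob.get(det.stage, 0.0):
                continue
            cumrow, outcomes = cum[det.stage]
            outcome = outcomes[int(np.searchsorted(cumrow, rng.random(), side="right"))]
            if outcome == _BACKGROUND:
                continue
            bbox = det.bbox
            if noise.bbox_jitter_px > 0:
                jit = rng.normal(0.0, noise.bbox_jitter_px, 4)
                x0, y0 = bbox.x_min + jit[0], bbox.y_min + jit[1]
                x1, y1 = bbox.x_max + jit[2], bbox.y_max + jit[3]
                if x1 <= x0:
                    x0, x1 = x1 - 0.5, x0 + 0.5
                if y1 <= y0:
                    y0, y1 = y1 - 0.5, y0 + 0.5
                bbox = BBox(x0, y0, x1, y1)
            dets.append(
                Detection(bbox=bbox, stage=outcome, confidence=det.confidence, vial_id=det.vial_id)
            )
        for _ in range(rng.poisson(noise.spurious_rate)):
            cx = rng.uniform(20, width - 20)
            cy = rng.uniform(20, height - 20)
            dets.append(
                Detection(bbox=_box_at(cx, cy, _PUPA_SIZE), stage=StageLabel.OUT_OF_FOCUS)
            )
        out.append(FrameDetections(frame_index=fd.frame_index, time_min=fd.time_min, detections=dets))
    return out


def render_frame(gt: GroundTruth, frame_index: int) -> np.ndarray:
    """Grayscale rendering of one frame for calibration tests: light
    background, darker vial strips, dark specimen blobs."""
    if not 0 <= frame_index < gt.n_frames:
        raise ValueError(f"frame_index {frame_index} outside recording")
    h, w = gt.geometry.frame_height, gt.geometry.frame_width
    img = np.full((h, w), 235, dtype=np.uint8)
    for roi in gt.geometry.vial_rois:
        img[:, int(roi.x_min) : int(roi.x_max)] = 140
    boxes = [
        sp.frames[frame_index][0] for sp in gt.specimens if frame_index in sp.frames
    ] + [adult[frame_index] for adult in gt.adults if frame_index in adult]
    for b in boxes:
        y0, y1 = max(int(b.y_min), 0), min(int(math.ceil(b.y_max)), h)
        x0, x1 = max(int(b.x_min), 0), min(int(math.ceil(b.x_max)), w)
        img[y0:y1, x0:x1] = 40
    return img
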