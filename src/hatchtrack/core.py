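"""Domain types shared by the whole pipeline.

The pipeline deals with per-frame object detections of *Drosophila
melanogaster* developmental stages in rearing vials (wandering L3 larvae,
full pupae, empty pupal cases and adult flies, plus a catch-all
out-of-focus class for blurred background objects), links them into
identity-preserving trajectories, and extracts pupation/eclosion events.
"""

from __future__ import annotations

import enum
import json
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator, Optional

import yaml

__all__ = [
    "StageLabel",
    "TRACKABLE_STAGES",
    "BBox",
    "Detection",
    "FrameDetections",
    "TrackerConfig",
    "TrackRecord",
    "Track",
    "SensorRecord",
    "stage_adjacent",
]


class StageLabel(enum.Enum):
    """Developmental stage classes produced by the detector.

    The four trackable classes carry an ordinal encoding the developmental
    order larva < full pupa < empty pupa < adult, used by median smoothing
    of stage sequences.  OUT_OF_FOCUS absorbs blurred background objects
    and is never tracked.
    """

    LARVA = "larva"
    FULL_PUPA = "full_pupa"
    EMPTY_PUPA = "empty_pupa"
    ADULT = "adult"
    OUT_OF_FOCUS = "out_of_focus"

    @property
    def ordinal(self) -> int:
        try:
            return _ORDINAL[self]
        except KeyError:
            raise ValueError(f"{self.name} has no developmental ordinal") from None

    @classmethod
    def from_ordinal(cls, code: int) -> "StageLabel":
        try:
            return _FROM_ORDINAL[code]
        except KeyError:
            raise ValueError(f"no trackable stage with ordinal {code}") from None

    @property
    def trackable(self) -> bool:
        return self is not StageLabel.OUT_OF_FOCUS


_ORDINAL = {
    StageLabel.LARVA: 0,
    StageLabel.FULL_PUPA: 1,
    StageLabel.EMPTY_PUPA: 2,
    StageLabel.ADULT: 3,
}
_FROM_ORDINAL = {v: k for k, v in _ORDINAL.items()}

TRACKABLE_STAGES = frozenset(_ORDINAL)

# Undirected stage-adjacency graph for temporal association: a specimen may
# stay in its stage or cross one developmental boundary between consecutive
# frames (larva <-> full pupa at pupariation, full <-> empty pupa at
# eclosion).  The adult emerging at eclosion is treated as a new object, so
# ADULT is adjacent only to itself.  The relation is kept symmetric because
# single-frame misclassifications can transiently "reverse" a stage.
_ADJACENT = frozenset(
    {
        frozenset({StageLabel.LARVA}),
        frozenset({StageLabel.FULL_PUPA}),
        frozenset({StageLabel.EMPTY_PUPA}),
        frozenset({StageLabel.ADULT}),
        frozenset({StageLabel.LARVA, StageLabel.FULL_PUPA}),
        frozenset({StageLabel.FULL_PUPA, StageLabel.EMPTY_PUPA}),
    }
)


def stage_adjacent(a: StageLabel, b: StageLabel) -> bool:
    """True iff stages *a* and *b* may belong to the same specimen in
    consecutive frames (same stage or one developmental transition apart)."""
    if not a.trackable or not b.trackable:
        raise ValueError("stage adjacency is defined only for trackable classes")
    return frozenset({a, b}) in _ADJACENT


@dataclass(frozen=True)
class BBox:
    """Axis-aligned bounding box in continuous pixel coordinates,
    origin at the top-left of the frame."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def intersects(self, other: "BBox") -> bool:
        return (
            self.x_min < other.x_max
            and other.x_min < self.x_max
            and self.y_min < other.y_max
            and other.y_min < self.y_max
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class Detection:
    """One detector output: a classified box with confidence, assigned to a vial."""

    bbox: BBox
    stage: StageLabel
    confidence: float = 1.0
    vial_id: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class FrameDetections:
    """All detections of one captured frame (one time point)."""

    frame_index: int
    time_min: float
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class TrackerConfig:
    """Tunable parameters of tracking and post-processing.

    Defaults encode the operating point of the monitoring system:
    10-minute capture interval, association requiring IoU strictly above
    0.6 and same-or-adjacent stages, a re-association window reaching back
    to t-4, trajectories below 30 frames discarded, stage sequences median
    filtered with window 5, and event extraction with a sliding majority
    window of 7 frames.
    """

    iou_threshold: float = 0.6
    max_gap_frames: int = 4
    min_track_length: int = 30
    median_window: int = 5
    event_window_tau: int = 7
    frame_interval_min: float = 10.0
    tracked_classes: frozenset[StageLabel] = TRACKABLE_STAGES

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_threshold < 1.0:
            raise ValueError("iou_threshold must be in (0, 1)")
        if self.median_window % 2 == 0 or self.median_window < 1:
            raise ValueError("median_window must be odd and >= 1")
        if self.event_window_tau % 2 == 0 or self.event_window_tau < 1:
            raise ValueError("event_window_tau must be odd and >= 1")
        if self.min_track_length < 1:
            raise ValueError("min_track_length must be >= 1")
        if self.max_gap_frames < 1:
            raise ValueError("max_gap_frames must be >= 1")
        self.tracked_classes = frozenset(self.tracked_classes)
        if not self.tracked_classes <= TRACKABLE_STAGES:
            raise ValueError("tracked_classes must be trackable stage labels")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["tracked_classes"] = sorted(s.value for s in self.tracked_classes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrackerConfig":
        d = dict(d)
        if "tracked_classes" in d:
            d["tracked_classes"] = frozenset(
                StageLabel(s) if not isinstance(s, StageLabel) else s
                for s in d["tracked_classes"]
            )
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "TrackerConfig":
        """Load a config from a TOML, YAML or JSON file mirroring the fields."""
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".toml":
            data = tomllib.loads(text)
        elif path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text) or {}
        elif path.suffix == ".json":
            data = json.loads(text)
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        return cls.from_dict(data)


@dataclass(frozen=True)
class TrackRecord:
    """State of one tracked specimen at one frame.

    ``observed`` is False for gap-bridged frames, whose box and stage are
    held from the last real detection.
    """

    bbox: BBox
    stage: StageLabel
    observed: bool = True


@dataclass
class Track:
    """One specimen's identity over time: per-frame boxes and stage labels.

    Records cover a contiguous frame range once gaps are bridged; the
    optional ``smoothed_stages`` map is filled by median smoothing.
    """

    track_id: int
    records: dict[int, TrackRecord] = field(default_factory=dict)
    smoothed_stages: Optional[dict[int, StageLabel]] = None

    @property
    def frames(self) -> list[int]:
        return sorted(self.records)

    @property
    def first_frame(self) -> int:
        return min(self.records)

    @property
    def last_frame(self) -> int:
        return max(self.records)

    @property
    def length(self) -> int:
        """Number of frames covered, inferred fills included."""
        return len(self.records)

    def stages(self, smoothed: bool = False) -> list[StageLabel]:
        if smoothed:
            if self.smoothed_stages is None:
                raise ValueError(f"track {self.track_id} has no smoothed stages")
            return [self.smoothed_stages[f] for f in self.frames]
        return [self.records[f].stage for f in self.frames]

    def __iter__(self) -> Iterator[tuple[int, TrackRecord]]:
        for f in self.frames:
            yield f, self.records[f]


@dataclass(frozen=True)
class SensorRecord:
    """Environmental sensor reading synchronized with a capture; all
    channels optional, pass-through storage only."""

    time_min: float
    temperature_c: Optional[float] = None
    humidity_rh: Optional[float] = None
    pressure_hpa: Optional[float] = None
    light_lux: Optional[float] = None
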