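"""Identity-preserving tracking by detection.

Detections of consecutive frames are associated by solving a maximum-
weight bipartite matching on a dummy-augmented IoU matrix.  A real pair
(track i, detection j) is admissible when its IoU strictly exceeds the
configured threshold (default 0.6) and the stages are the same or
developmentally adjacent; inadmissible pairs carry a FORBIDDEN score so
the solver routes them through dummy rows/columns instead, which realizes
track termination and birth.  Occasional missed detections are bridged by
keeping a track eligible for matching while it was last seen within the
previous ``max_gap_frames`` frames (t-1 ... t-4 by default), holding its
last observed box and stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import (
    BBox,
    Detection,
    FrameDetections,
    StageLabel,
    Track,
    TrackRecord,
    TrackerConfig,
    stage_adjacent,
)

__all__ = [
    "FORBIDDEN",
    "iou",
    "admissible",
    "AssociationMatrix",
    "build_association_matrix",
    "solve_matching",
    "TrackerState",
    "step",
    "track_sequence",
]

# Score assigned to inadmissible real pairs.  Under maximization any such
# pair is dominated by routing both members through dummies (score 0), so
# a FORBIDDEN pair is never part of an optimal matching.
FORBIDDEN = -1.0


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union (Jaccard index) of two boxes, in [0, 1]."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def admissible(
    track_box: BBox, track_stage: StageLabel, det: Detection, cfg: TrackerConfig
) -> bool:
    """Association gate: IoU strictly above threshold AND stages
    same-or-adjacent.  An IoU of exactly the threshold does not pass."""
    return (
        iou(track_box, det.bbox) > cfg.iou_threshold
        and stage_adjacent(track_stage, det.stage)
    )


@dataclass
class AssociationMatrix:
    """Dummy-augmented score matrix between m candidate tracks and n
    detections, shape (m+n) x (n+m).

    Real block [i < m, j < n] holds the gated IoU (FORBIDDEN when
    inadmissible); the dummy row/column blocks are 0 so every track and
    detection can remain unmatched; the dummy-dummy block is 0, which
    together with maximization prevents dummy-dummy pairs from mattering.
    """

    m: int
    n: int
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.shape != (self.m + self.n, self.n + self.m):
            raise ValueError(
                f"expected shape {(self.m + self.n, self.n + self.m)}, got {self.scores.shape}"
            )


def build_association_matrix(
    tracks: Sequence[tuple[BBox, StageLabel]],
    dets: Sequence[Detection],
    cfg: TrackerConfig,
) -> AssociationMatrix:
    m, n = len(tracks), len(dets)
    scores = np.zeros((m + n, n + m))
    for i, (tbox, tstage) in enumerate(tracks):
        for j, det in enumerate(dets):
            scores[i, j] = (
                iou(tbox, det.bbox) if admissible(tbox, tstage, det, cfg) else FORBIDDEN
            )
    return AssociationMatrix(m=m, n=n, scores=scores)


def solve_matching(matrix: AssociationMatrix) -> set[tuple[int, int]]:
    """Maximum-total-score perfect matching on the augmented matrix
    (Hungarian method); returns only real track-detection pairs with an
    admissible score."""
    if matrix.scores.size == 0:
        return set()
    rows, cols = linear_sum_assignment(matrix.scores, maximize=True)
    return {
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < matrix.m and j < matrix.n and matrix.scores[i, j] > FORBIDDEN
    }


@dataclass
class _ActiveTrack:
    track: Track
    last_observed_frame: int

    @property
    def last_record(self) -> TrackRecord:
        return self.track.records[self.last_observed_frame]


@dataclass
class TrackerState:
    """Mutable tracker state carried from frame to frame."""

    active: dict[int, _ActiveTrack] = field(default_factory=dict)
    closed: list[Track] = field(default_factory=list)
    next_id: int = 0
    last_frame: Optional[int] = None


def step(state: TrackerState, fd: FrameDetections, cfg: TrackerConfig) -> TrackerState:
    """Process one frame: close stale tracks, match candidates against the
    frame's detections, bridge gaps, and found new tracks.

    Candidates are active tracks last observed within the previous
    ``max_gap_frames`` frames, represented by their last observed box and
    (smoothing-free) stage.  A matched track is extended with the
    detection; skipped frames are filled with the held box/stage flagged
    as inferred.  Unmatched detections of tracked classes found new
    tracks in reading order; detections of other classes are dropped.
    """
    t = fd.frame_index
    if state.last_frame is not None and t <= state.last_frame:
        raise ValueError(f"out-of-order frame {t} after {state.last_frame}")

    # close tracks that fell out of the re-association window
    for tid in [tid for tid, at in state.active.items() if t - at.last_observed_frame > cfg.max_gap_frames]:
        state.closed.append(state.active.pop(tid).track)

    candidate_ids = sorted(state.active)
    candidates = [
        (state.active[tid].last_record.bbox, state.active[tid].last_record.stage)
        for tid in candidate_ids
    ]
    dets = [d for d in fd.detections if d.stage in cfg.tracked_classes]

    matches = solve_matching(build_association_matrix(candidates, dets, cfg))

    matched_dets = set()
    for i, j in sorted(matches):
        tid = candidate_ids[i]
        at = state.active[tid]
        held = at.last_record
        for gap_frame in range(at.last_observed_frame + 1, t):
            at.track.records[gap_frame] = TrackRecord(
                bbox=held.bbox, stage=held.stage, observed=False
            )
        det = dets[j]
        at.track.records[t] = TrackRecord(bbox=det.bbox, stage=det.stage, observed=True)
        at.last_observed_frame = t
        matched_dets.add(j)

    for j, det in enumerate(dets):
        if j in matched_dets:
            continue
        track = Track(track_id=state.next_id, records={t: TrackRecord(det.bbox, det.stage)})
        state.active[state.next_id] = _ActiveTrack(track=track, last_observed_frame=t)
        state.next_id += 1

    # a track unobserved for max_gap_frames consecutive frames is closed
    for tid in [tid for tid, at in state.active.items() if t - at.last_observed_frame >= cfg.max_gap_frames]:
        state.closed.append(state.active.pop(tid).track)

    state.last_frame = t
    return state


def track_sequence(
    frames: Sequence[FrameDetections], cfg: Optional[TrackerConfig] = None
) -> list[Track]:
    """Track a full recording; returns all tracks in first-appearance order.

    Deterministic for fixed input: ids are assigned by frame, then by
    reading order within each frame.
    """
    cfg = cfg or TrackerConfig()
    state = TrackerState()
    for fd in frames:
        step(state, fd, cfg)
    tracks = state.closed + [at.track for at in state.active.values()]
    tracks.sort(key=lambda tr: tr.track_id)
    return tracks
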