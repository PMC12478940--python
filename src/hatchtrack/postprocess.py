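"""Stage-sequence cleaning, trajectory filtering and event extraction.

After tracking, per-specimen stage sequences are median filtered to
remove single-frame misclassifications, short trajectories (mostly
fast-moving adults that fragment at low frame rates) are discarded, and
pupation/eclosion time points are extracted with a sliding majority
window over the smoothed stage labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import StageLabel, Track, TrackerConfig

__all__ = [
    "EventType",
    "EventRecord",
    "smooth_stages",
    "filter_short_tracks",
    "extract_events",
    "collect_events",
]


class EventType(enum.Enum):
    PUPATION = "pupation"
    ECLOSION = "eclosion"


@dataclass(frozen=True)
class EventRecord:
    """A developmental transition of one tracked specimen."""

    track_id: int
    event_type: EventType
    frame_index: int
    time_min: float


def smooth_stages(track: Track, window: int = 5) -> Track:
    """Centered median filter over the developmental-stage ordinals.

    The median is taken over the ordinal codes (larva=0 < full pupa=1 <
    empty pupa=2 < adult=3) in a centered window and decoded back to a
    label; the first/last floor(window/2) frames keep their raw labels
    (no window shrinking at the edges).  Boxes and positions are not
    touched.  Isolated misclassifications vanish while true transitions
    survive.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    frames = track.frames
    ordinals = np.array([track.records[f].stage.ordinal for f in frames])
    smoothed = ordinals.copy()
    half = window // 2
    for k in range(half, len(frames) - half):
        smoothed[k] = int(np.median(ordinals[k - half : k + half + 1]))
    track.smoothed_stages = {
        f: StageLabel.from_ordinal(int(code)) for f, code in zip(frames, smoothed)
    }
    return track


def filter_short_tracks(tracks: Iterable[Track], min_len: int = 30) -> list[Track]:
    """Discard trajectories covering fewer than ``min_len`` frames
    (length counts gap-bridged frames); order preserved."""
    return [t for t in tracks if t.length >= min_len]


def extract_events(
    track: Track, tau: int = 7, frame_interval_min: float = 10.0
) -> list[EventRecord]:
    """Extract pupation/eclosion time points with a sliding majority window.

    Scanning ascending t over the track, a time point t is marked when a
    majority (>= ceil(tau/2)) of the window [t, ..., t+tau-1] carries the
    full-pupa (pupation) or empty-pupa (eclosion) label.  The earliest
    qualifying t is reported, so the marked frame systematically precedes
    the visible transition by up to floor(tau/2) frames.  Pupation
    additionally requires some frame before t that is not full pupa, so a
    track that is a pupa from birth yields no pupation event.  Windows
    truncated by the end of the track are not evaluated.  Uses the
    smoothed stage sequence (smoothing must have been applied).
    """
    if tau % 2 == 0 or tau < 1:
        raise ValueError("tau must be odd and >= 1")
    if track.smoothed_stages is None:
        raise ValueError(f"track {track.track_id} not smoothed; run smooth_stages first")
    frames = track.frames
    labels = [track.smoothed_stages[f] for f in frames]
    majority = tau // 2 + 1

    events: list[EventRecord] = []
    pupation_idx = None
    eclosion_idx = None
    seen_non_fp = False
    for k in range(len(frames) - tau + 1):
        window = labels[k : k + tau]
        if (
            pupation_idx is None
            and seen_non_fp
            and sum(s is StageLabel.FULL_PUPA for s in window) >= majority
        ):
            pupation_idx = k
        if (
            eclosion_idx is None
            and sum(s is StageLabel.EMPTY_PUPA for s in window) >= majority
        ):
            eclosion_idx = k
        if labels[k] is not StageLabel.FULL_PUPA:
            seen_non_fp = True
        if pupation_idx is not None and eclosion_idx is not None:
            break

    if pupation_idx is not None:
        f = frames[pupation_idx]
        events.append(EventRecord(track.track_id, EventType.PUPATION, f, f * frame_interval_min))
    if eclosion_idx is not None:
        f = frames[eclosion_idx]
        events.append(EventRecord(track.track_id, EventType.ECLOSION, f, f * frame_interval_min))
    return events


def collect_events(
    tracks: Sequence[Track],
    cfg: Optional[TrackerConfig] = None,
    event_type: Optional[EventType] = None,
) -> list[EventRecord]:
    """Extract events from all tracks, sorted by time (then track id);
    optionally restricted to one event type, e.g. eclosions only for the
    circadian analysis."""
    cfg = cfg or TrackerConfig()
    events: list[EventRecord] = []
    for track in tracks:
        events.extend(
            extract_events(track, tau=cfg.event_window_tau, frame_interval_min=cfg.frame_interval_min)
        )
    if event_type is not None:
        events = [e for e in events if e.event_type is event_type]
    events.sort(key=lambda e: (e.time_min, e.track_id))
    return events
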