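"""HDF5 persistence of tracking results and full pipeline orchestration.

Layout::

    /meta                  attrs: format_version, config (JSON), frame_interval_min,
                           start_time (ISO-8601, optional)
    /tracks/<id>/frames    int64          frame indices (sorted)
    /tracks/<id>/bboxes    float64 (n,4)  x_min, y_min, x_max, y_max
    /tracks/<id>/stages_raw       int8    stage ordinals
    /tracks/<id>/stages_smoothed  int8    optional
    /tracks/<id>/observed  bool
    /events                columns track_id, event_type, frame_index, time_min
    /sensors/<channel>     float64 time series (+ /sensors/time_min)

Times are minutes since experiment start (frame index x capture
interval).  Stage labels are stored as their ordinal codes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import BBox, SensorRecord, StageLabel, Track, TrackRecord, TrackerConfig
from .detect_io import read_detections, split_by_vial
from .postprocess import (
    EventRecord,
    EventType,
    collect_events,
    filter_short_tracks,
    smooth_stages,
)
from .rhythm import Periodogram, estimate_rhythm
from .tracker import track_sequence

__all__ = ["save_results", "load_results", "events_to_csv", "periodogram_to_csv", "run_pipeline"]

FORMAT_VERSION = 1

_SENSOR_CHANNELS = ("temperature_c", "humidity_rh", "pressure_hpa", "light_lux")
_EVENT_CODE = {EventType.PUPATION: 0, EventType.ECLOSION: 1}
_EVENT_FROM_CODE = {v: k for k, v in _EVENT_CODE.items()}


def save_results(
    tracks: Sequence[Track],
    events: Sequence[EventRecord],
    sensors: Sequence[SensorRecord],
    config: TrackerConfig,
    path: str | Path,
    start_time: Optional[str] = None,
) -> None:
    """Write tracks, events and sensor streams to an HDF5 file."""
    try:
        fh = h5py.File(path, "w")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    with fh:
        meta = fh.create_group("meta")
        meta.attrs["format_version"] = FORMAT_VERSION
        meta.attrs["config"] = json.dumps(config.to_dict())
        meta.attrs["frame_interval_min"] = config.frame_interval_min
        meta.attrs["stage_codes"] = json.dumps(
            {s.value: s.ordinal for s in StageLabel if s.trackable}
        )
        if start_time is not None:
            meta.attrs["start_time"] = start_time

        tg = fh.create_group("tracks")
        for track in tracks:
            g = tg.create_group(str(track.track_id))
            frames = track.frames
            g.create_dataset("frames", data=np.array(frames, dtype=np.int64))
            g.create_dataset(
                "bboxes",
                data=np.array([track.records[f].bbox.as_tuple() for f in frames], dtype=np.float64),
            )
            g.create_dataset(
                "stages_raw",
                data=np.array([track.records[f].stage.ordinal for f in frames], dtype=np.int8),
            )
            g.create_dataset(
                "observed",
                data=np.array([track.records[f].observed for f in frames], dtype=bool),
            )
            if track.smoothed_stages is not None:
                g.create_dataset(
                    "stages_smoothed",
                    data=np.array(
                        [track.smoothed_stages[f].ordinal for f in frames], dtype=np.int8
                    ),
                )

        eg = fh.create_group("events")
        eg.create_dataset("track_id", data=np.array([e.track_id for e in events], dtype=np.int64))
        eg.create_dataset(
            "event_type", data=np.array([_EVENT_CODE[e.event_type] for e in events], dtype=np.int8)
        )
        eg.create_dataset(
            "frame_index", data=np.array([e.frame_index for e in events], dtype=np.int64)
        )
        eg.create_dataset("time_min", data=np.array([e.time_min for e in events], dtype=np.float64))

        sg = fh.create_group("sensors")
        if sensors:
            sg.create_dataset(
                "time_min", data=np.array([s.time_min for s in sensors], dtype=np.float64)
            )
            for channel in _SENSOR_CHANNELS:
                values = [getattr(s, channel) for s in sensors]
                if any(v is not None for v in values):
                    sg.create_dataset(
                        channel,
                        data=np.array(
                            [np.nan if v is None else v for v in values], dtype=np.float64
                        ),
                    )


def load_results(
    path: str | Path,
) -> tuple[list[Track], list[EventRecord], list[SensorRecord], TrackerConfig]:
    """Reload a results file; inverse of :func:`save_results`."""
    with h5py.File(path, "r") as fh:
        version = int(fh["meta"].attrs["format_version"])
        if version != FORMAT_VERSION:
            raise ValueError(f"unsupported format version {version}")
        config = TrackerConfig.from_dict(json.loads(fh["meta"].attrs["config"]))

        tracks = []
        for tid in sorted(fh["tracks"], key=int):
            g = fh["tracks"][tid]
            frames = g["frames"][:]
            bboxes = g["bboxes"][:]
            raw = g["stages_raw"][:]
            observed = g["observed"][:]
            records = {
                int(f): TrackRecord(
                    bbox=BBox(*bboxes[i]),
                    stage=StageLabel.from_ordinal(int(raw[i])),
                    observed=bool(observed[i]),
                )
                for i, f in enumerate(frames)
            }
            smoothed = None
            if "stages_smoothed" in g:
                sm = g["stages_smoothed"][:]
                smoothed = {
                    int(f): StageLabel.from_ordinal(int(sm[i])) for i, f in enumerate(frames)
                }
            tracks.append(Track(track_id=int(tid), records=records, smoothed_stages=smoothed))

        ev = fh["events"]
        events = [
            EventRecord(
                track_id=int(ev["track_id"][i]),
                event_type=_EVENT_FROM_CODE[int(ev["event_type"][i])],
                frame_index=int(ev["frame_index"][i]),
                time_min=float(ev["time_min"][i]),
            )
            for i in range(len(ev["track_id"]))
        ]

        sensors = []
        sg = fh["sensors"]
        if "time_min" in sg:
            time_min = sg["time_min"][:]
            channels = {c: sg[c][:] if c in sg else None for c in _SENSOR_CHANNELS}
            for i, t in enumerate(time_min):
                kwargs = {}
                for c, arr in channels.items():
                    if arr is not None and not np.isnan(arr[i]):
                        kwargs[c] = float(arr[i])
                sensors.append(SensorRecord(time_min=float(t), **kwargs))

    return tracks, events, sensors, config


def events_to_csv(events: Sequence[EventRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "track_id": [e.track_id for e in events],
            "event_type": [e.event_type.value for e in events],
            "frame_index": [e.frame_index for e in events],
            "time_min": [e.time_min for e in events],
        }
    ).to_csv(path, index=False)


def events_from_csv(path: str | Path) -> list[EventRecord]:
    df = pd.read_csv(path)
    return [
        EventRecord(
            track_id=int(r.track_id),
            event_type=EventType(r.event_type),
            frame_index=int(r.frame_index),
            time_min=float(r.time_min),
        )
        for r in df.itertuples()
    ]


def periodogram_to_csv(pg: Periodogram, path: str | Path) -> None:
    pd.DataFrame({"period_h": pg.periods_h, "power": pg.power}).to_csv(path, index=False)


def run_pipeline(
    detections_path: str | Path,
    config_path: Optional[str | Path] = None,
    out_path: Optional[str | Path] = None,
    event_type: EventType = EventType.ECLOSION,
) -> dict:
    """Full analysis: ingest -> per-vial tracking -> stage smoothing ->
    length filtering -> event extraction -> rhythm estimation -> save.

    Deterministic for fixed inputs.  Returns a summary dict with track
    and event counts and, when enough events were found, the peak rhythm
    period and its significance.
    """
    cfg = TrackerConfig.from_file(config_path) if config_path else TrackerConfig()

    try:
        frames = read_detections(detections_path, dialect="jsonl")
    except ValueError as exc:
        raise RuntimeError(f"[ingest] {exc}") from exc

    try:
        per_vial = split_by_vial(frames)
        tracks: list[Track] = []
        offset = 0
        for vid in sorted(per_vial):
            vial_tracks = track_sequence(per_vial[vid], cfg)
            for tr in vial_tracks:
                tr.track_id += offset
            offset += len(vial_tracks)
            tracks.extend(vial_tracks)
    except ValueError as exc:
        raise RuntimeError(f"[track] {exc}") from exc

    tracks = filter_short_tracks(tracks, min_len=cfg.min_track_length)
    for tr in tracks:
        smooth_stages(tr, window=cfg.median_window)
    all_events = collect_events(tracks, cfg)
    selected = [e for e in all_events if e.event_type is event_type]

    summary: dict = {
        "n_frames": len(frames),
        "n_tracks": len(tracks),
        "n_pupation": sum(e.event_type is EventType.PUPATION for e in all_events),
        "n_eclosion": sum(e.event_type is EventType.ECLOSION for e in all_events),
        "peak_period_h": None,
        "peak_p_value": None,
    }
    periodogram = None
    if len(selected) >= 8:
        try:
            periodogram = estimate_rhythm(selected)
            summary["peak_period_h"] = periodogram.peak_period_h
            summary["peak_p_value"] = periodogram.p_value
        except ValueError:
            pass  # too few occupied bins: report counts only

    if out_path is not None:
        try:
            save_results(tracks, all_events, [], cfg, out_path)
        except OSError as exc:
            raise RuntimeError(f"[save] {exc}") from exc

    return summary
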