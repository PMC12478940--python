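"""Detection ingestion, vial calibration and per-vial splitting.

The canonical on-disk detection format is JSON-lines: one frame per line
with absolute pixel corner boxes, stage names and confidences.  A reader
for YOLO-style normalized text files (one ``.txt`` per frame plus a
sidecar metadata file) is provided as a convenience.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml
from skimage.filters import threshold_otsu

from .core import BBox, Detection, FrameDetections, StageLabel

__all__ = [
    "VialLayout",
    "read_detections",
    "write_detections",
    "calibrate_vials",
    "assign_vials",
]

MAX_VIALS = 3


@dataclass
class VialLayout:
    """Per-vial regions of interest from the one-time calibration step.

    ``vials`` maps left-to-right, vial_id 0..n-1; ROIs are full-height
    rectangles and must be pairwise non-overlapping.
    """

    vials: list[tuple[int, BBox]] = field(default_factory=list)
    masks: Optional[dict[int, np.ndarray]] = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.vials) <= MAX_VIALS:
            raise ValueError(f"need 1..{MAX_VIALS} vials, got {len(self.vials)}")
        rois = [roi for _, roi in self.vials]
        for i in range(len(rois)):
            for j in range(i + 1, len(rois)):
                if rois[i].intersects(rois[j]):
                    raise ValueError("vial ROIs overlap")

    def to_json(self) -> str:
        return json.dumps(
            {"vials": [{"vial_id": vid, "roi": roi.as_tuple()} for vid, roi in self.vials]}
        )

    @classmethod
    def from_json(cls, text: str) -> "VialLayout":
        data = json.loads(text)
        return cls(vials=[(v["vial_id"], BBox(*v["roi"])) for v in data["vials"]])


# ---------------------------------------------------------------------------
# readers / writers


def _frame_from_obj(obj: dict, source: str) -> FrameDetections:
    dets = []
    for d in obj.get("detections", []):
        dets.append(
            Detection(
                bbox=BBox(*d["bbox"]),
                stage=StageLabel(d["stage"]),
                confidence=d.get("confidence", 1.0),
                vial_id=d.get("vial_id", 0),
            )
        )
    return FrameDetections(
        frame_index=obj["frame_index"], time_min=obj["time_min"], detections=dets
    )


def read_detections(path: str | Path, dialect: str = "jsonl") -> list[FrameDetections]:
    """Read a detection stream, sorted by frame index.

    dialect ``jsonl``: one JSON object per line with keys ``frame_index``,
    ``time_min`` and ``detections`` (list of ``{bbox: [x0,y0,x1,y1],
    stage, confidence, vial_id}``).

    dialect ``yolo_txt``: *path* is a directory of per-frame ``.txt``
    files with lines ``class_idx cx cy w h [confidence]`` in normalized
    image coordinates, plus a ``meta.yaml``/``meta.json`` sidecar defining
    ``image_width``, ``image_height``, ``class_map`` (class index ->
    stage name) and optionally ``frame_interval_min`` (default 10).
    Frame indices are parsed from the trailing integer of each file stem.
    """
    path = Path(path)
    if dialect == "jsonl":
        frames = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    frames.append(_frame_from_obj(json.loads(line), str(path)))
                except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed frame record: {exc}") from exc
        frames.sort(key=lambda f: f.frame_index)
        return frames
    if dialect == "yolo_txt":
        return _read_yolo_dir(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_yolo_dir(directory: Path) -> list[FrameDetections]:
    meta_path = None
    for name in ("meta.yaml", "meta.yml", "meta.json"):
        if (directory / name).exists():
            meta_path = directory / name
            break
    if meta_path is None:
        raise ValueError(f"{directory}: missing meta.yaml/meta.json sidecar")
    meta = yaml.safe_load(meta_path.read_text())
    width = float(meta["image_width"])
    height = float(meta["image_height"])
    class_map = {int(k): StageLabel(v) for k, v in meta["class_map"].items()}
    interval = float(meta.get("frame_interval_min", 10.0))

    frames = []
    for txt in sorted(directory.glob("*.txt")):
        m = re.search(r"(\d+)$", txt.stem)
        if m is None:
            raise ValueError(f"{txt}: cannot parse frame index from filename")
        idx = int(m.group(1))
        dets = []
        for lineno, line in enumerate(txt.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise ValueError(f"{txt}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
            try:
                cls_idx = int(parts[0])
                cx, cy, w, h = (float(p) for p in parts[1:5])
                conf = float(parts[5]) if len(parts) == 6 else 1.0
            except ValueError as exc:
                raise ValueError(f"{txt}:{lineno}: malformed line: {exc}") from exc
            if cls_idx not in class_map:
                raise ValueError(f"{txt}:{lineno}: unknown class index {cls_idx}")
            bbox = BBox(
                (cx - w / 2) * width,
                (cy - h / 2) * height,
                (cx + w / 2) * width,
                (cy + h / 2) * height,
            )
            dets.append(Detection(bbox=bbox, stage=class_map[cls_idx], confidence=conf))
        frames.append(FrameDetections(frame_index=idx, time_min=idx * interval, detections=dets))
    frames.sort(key=lambda f: f.frame_index)
    return frames


def write_detections(frames: Iterable[FrameDetections], path: str | Path) -> None:
    """Write frames in the canonical JSON-lines dialect (lossless roundtrip)."""
    with open(path, "w") as fh:
        for fd in frames:
            obj = {
                "frame_index": fd.frame_index,
                "time_min": fd.time_min,
                "detections": [
                    {
                        "bbox": list(d.bbox.as_tuple()),
                        "stage": d.stage.value,
                        "confidence": d.confidence,
                        "vial_id": d.vial_id,
                    }
                    for d in fd.detections
                ],
            }
            fh.write(json.dumps(obj) + "\n")


# ---------------------------------------------------------------------------
# vial calibration


def calibrate_vials(
    frames: Sequence[np.ndarray],
    max_vials: int = MAX_VIALS,
    manual_rois: Optional[Sequence[BBox]] = None,
) -> VialLayout:
    """Locate up to three vertical vial regions in backlit grayscale frames.

    The scene is transmitted-light: background bright, vial walls and
    specimens dark.  The mean frame is Otsu-thresholded, foreground
    density is projected onto columns, the profile smoothed, and the up to
    ``max_vials`` widest plateaus above half the peak density become
    full-height ROIs, ordered left to right (vial_id = 0, 1, 2).

    ``manual_rois`` bypasses detection and is returned verbatim.
    """
    if manual_rois is not None:
        return VialLayout(vials=[(i, roi) for i, roi in enumerate(manual_rois)])
    if not frames:
        raise ValueError("need at least one calibration frame")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("calibration frames must share dimensions")
    mean = np.mean([f.astype(float) for f in frames], axis=0)
    if mean.max() - mean.min() < 1e-9:
        raise ValueError(
            "no vial-like region found (uniform image); provide ROIs manually"
        )
    thresh = threshold_otsu(mean)
    foreground = mean < thresh  # dark objects on light background
    profile = foreground.mean(axis=0)
    # smooth over ~2% of the width to bridge specimen-level gaps
    win = max(3, int(round(shape[1] * 0.02)) | 1)
    kernel = np.ones(win) / win
    profile = np.convolve(profile, kernel, mode="same")

    level = 0.5 * profile.max()
    above = profile > level
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(above)))
    # ignore slivers narrower than 2% of the frame
    runs = [(a, b) for a, b in runs if b - a >= max(3, shape[1] * 0.02)]
    if not runs:
        raise ValueError("no vial-like region found; provide ROIs manually")
    runs = sorted(runs, key=lambda r: r[1] - r[0], reverse=True)[:max_vials]
    runs.sort()  # left-to-right
    height = shape[0]
    vials = [(vid, BBox(a, 0.0, b, float(height))) for vid, (a, b) in enumerate(runs)]
    return VialLayout(vials=vials)


def assign_vials(fd: FrameDetections, layout: VialLayout) -> FrameDetections:
    """Assign each detection to the ROI containing its box center.

    Detections outside every ROI are dropped; a center on a shared
    boundary goes to the lower vial_id (vials are scanned in id order).
    """
    kept = []
    for det in fd.detections:
        cx, cy = det.bbox.center
        for vid, roi in sorted(layout.vials):
            if roi.contains(cx, cy):
                kept.append(
                    Detection(bbox=det.bbox, stage=det.stage, confidence=det.confidence, vial_id=vid)
                )
                break
    return FrameDetections(frame_index=fd.frame_index, time_min=fd.time_min, detections=kept)


def split_by_vial(frames: Sequence[FrameDetections]) -> dict[int, list[FrameDetections]]:
    """Split a detection stream into independent per-vial streams."""
    vial_ids = sorted({d.vial_id for fd in frames for d in fd.detections})
    out: dict[int, list[FrameDetections]] = {vid: [] for vid in vial_ids}
    for fd in frames:
        for vid in vial_ids:
            out[vid].append(
                FrameDetections(
                    frame_index=fd.frame_index,
                    time_min=fd.time_min,
                    detections=[d for d in fd.detections if d.vial_id == vid],
                )
            )
    return out
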