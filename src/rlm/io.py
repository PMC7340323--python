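"""Standard-format I/O: multi-page TIFF frame stacks with JSON metadata
sidecars, event-image TIFFs, and CSV tables.

A frame stack on disk is ``<name>.tif`` (16-bit grayscale, one page per
frame) plus ``<name>.tif.json`` holding pixel pitch, timestamps and the
camera/optics snapshot; the pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import FrameFormatError
from .optics import FrameStack
from .reconstruction import EventImage


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_frame_stack(stack: FrameStack, path) -> None:
    """Write frames as multi-page 16-bit TIFF + JSON metadata sidecar."""
    path = Path(path)
    frames = np.asarray(stack.frames)
    if frames.dtype != np.uint16:
        if frames.max(initial=0) > 65535 or frames.min(initial=0) < 0:
            raise FrameFormatError("frames do not fit in uint16")
        frames = frames.astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "pixel_pitch_object_um": stack.pixel_pitch_object_um,
        "timestamps_s": np.asarray(stack.timestamps_s).tolist(),
        "metadata": _jsonify(stack.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_frame_stack(path, memmap: bool = True) -> FrameStack:
    """Read a frame stack written by :func:`write_frame_stack`.

    With ``memmap=True`` (default) pixel data stay on disk and pages are
    mapped lazily, keeping memory bounded for 10,000-frame stacks.
    """
    path = Path(path)
    try:
        out = "memmap" if memmap else None
        frames = tifffile.imread(path, out=out)
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise FrameFormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None, ...]
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        pitch = float(meta["pixel_pitch_object_um"])
        ts = np.asarray(meta["timestamps_s"], dtype=float)
        extra = meta.get("metadata", {})
    else:
        pitch, ts, extra = 1.0, np.arange(len(frames), dtype=float), {}
    if len(ts) != len(frames):
        raise FrameFormatError(
            f"{path}: sidecar lists {len(ts)} timestamps for {len(frames)} pages")
    return FrameStack(frames, pitch, ts, extra)


def write_event_image(image: EventImage, path) -> None:
    """Event image as 16-bit TIFF + pitch sidecar."""
    counts = np.asarray(image.counts)
    if counts.max(initial=0) > 65535:
        raise FrameFormatError("event counts exceed uint16 range")
    tifffile.imwrite(Path(path), counts.astype(np.uint16), photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps({"pixel_pitch_object_um": image.pixel_pitch_object_um}))


def read_event_image(path) -> EventImage:
    path = Path(path)
    try:
        counts = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise FrameFormatError(f"cannot read event image {path}: {exc}") from exc
    side = _sidecar_path(path)
    pitch = 1.0
    if side.exists():
        pitch = float(json.loads(side.read_text())["pixel_pitch_object_um"])
    return EventImage(counts.astype(np.int64), pitch)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj
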