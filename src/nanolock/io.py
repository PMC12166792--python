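"""Frame/stack TIFF persistence with JSON sidecars, and JSONL loop logs.

Reference stacks are stored as multi-page TIFF (x/y: one page per frame;
z: a single 2D page, planes × sorted-index) next to a JSON sidecar carrying
axis, positions_nm, step_nm and center_index.  Loop logs are JSONL: a header
line embedding the fully resolved configuration and seeds, then one record
per iteration, flushed per record so a crash loses at most one line.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import tifffile

from .control import LoopRecord
from .estimation import Frame, ReferenceStack, SortedProfile

__all__ = [
    "StackLoadError",
    "write_frame",
    "read_frame",
    "write_stack",
    "read_stack",
    "roi_crop",
    "JsonlLogWriter",
    "read_log",
]

_ALLOWED_DTYPES = (np.uint16, np.float32, np.float64)


class StackLoadError(Exception):
    """Stack files incomplete or inconsistent."""


def write_frame(path: Union[str, Path], frame: Frame) -> Path:
    """Write one frame as a single-page float TIFF (lossless for float data)."""
    path = Path(path)
    tifffile.imwrite(path, frame.pixels.astype(np.float64))
    return path


def read_frame(path: Union[str, Path]) -> Frame:
    """Read a frame; accepts 16-bit unsigned or 32/64-bit float TIFF."""
    arr = tifffile.imread(Path(path))
    if arr.dtype not in [np.dtype(d) for d in _ALLOWED_DTYPES]:
        raise TypeError(
            f"unsupported frame dtype {arr.dtype}; expected uint16/float32/float64"
        )
    return Frame(np.asarray(arr, dtype=np.float64))


def roi_crop(pixels: np.ndarray, row0: int, col0: int, nrows: int, ncols: int) -> np.ndarray:
    """Crop an ROI: 0-based, row-major, origin top-left."""
    if row0 < 0 or col0 < 0 or row0 + nrows > pixels.shape[0] or col0 + ncols > pixels.shape[1]:
        raise ValueError("ROI exceeds frame bounds")
    return pixels[row0 : row0 + nrows, col0 : col0 + ncols]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(path: Union[str, Path], stack: ReferenceStack) -> Path:
    """Write a reference stack as TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    if stack.axis == "z":
        data = np.stack([e.values for e in stack.entries]).astype(np.float64)
        tifffile.imwrite(path, data)
        kind = "profiles"
    else:
        data = np.stack([e.pixels for e in stack.entries]).astype(np.float64)
        tifffile.imwrite(path, data)
        kind = "frames"
    meta = {
        "axis": stack.axis,
        "kind": kind,
        "positions_nm": [float(p) for p in stack.positions_nm],
        "step_nm": float(stack.step_nm),
        "center_index": int(stack.center_index),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: Union[str, Path]) -> ReferenceStack:
    """Read a reference stack written by :func:`write_stack`.

    A missing sidecar raises :class:`StackLoadError` with the expected path.
    """
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise StackLoadError(
            f"missing metadata sidecar {side}; stacks need axis/positions_nm/"
            "step_nm/center_index to be interpretable"
        )
    meta = json.loads(side.read_text())
    data = tifffile.imread(path)
    if meta["kind"] == "profiles":
        entries = [SortedProfile(row, normalized=True) for row in data]
    else:
        if data.ndim == 2:
            data = data[None]
        entries = [Frame(page, normalized=True) for page in data]
    return ReferenceStack(
        axis=meta["axis"],
        entries=entries,
        positions_nm=np.asarray(meta["positions_nm"], dtype=np.float64),
        step_nm=float(meta["step_nm"]),
        center_index=int(meta["center_index"]),
    )


class JsonlLogWriter:
    """Append-only JSONL loop log, flushed per record (crash-safe).

    The first line is a header embedding the resolved config and seeds, so
    any log is exactly reproducible from its own header.
    """

    def __init__(self, path: Union[str, Path], header: Optional[dict] = None):
        self.path = Path(path)
        self._fh = open(self.path, "w")
        if header is not None:
            self._emit({"type": "header", **header})

    def _emit(self, obj: dict) -> None:
        self._fh.write(json.dumps(obj) + "\n")
        self._fh.flush()

    def write(self, record: LoopRecord) -> None:
        self._emit({"type": "record", **record.to_dict()})

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "JsonlLogWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_log(path: Union[str, Path]) -> Tuple[Optional[dict], List[LoopRecord]]:
    """Read a JSONL loop log; returns (header, records).

    A truncated final line (interrupted write) is skipped with a warning.
    """
    header = None
    records: List[LoopRecord] = []
    lines = Path(path).read_text().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    for k, line in enumerate(lines):
        try:
            obj = json.loads(line)
        except json.JSONDecodeError:
            if k == len(lines) - 1:
                warnings.warn(f"skipping truncated final line in {path}", stacklevel=2)
                continue
            raise
        if obj.get("type") == "header":
            header = {k: v for k, v in obj.items() if k != "type"}
        else:
            records.append(LoopRecord.from_dict(obj))
    return header, records
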