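"""Frame-sequence, annotation and optical-flow I/O.

Conventions used throughout the package (declared once here):

* frames are H×W×3 arrays with real values in ``[0, 1]``; 8-bit quantisation
  happens only at file boundaries,
* row-major grids with the origin at the top-left corner, ``x`` = column,
  ``y`` = row,
* flow fields store channels in ``(dx, dy)`` order, in pixels,
* lexicographic filename ordering defines temporal order of a frame
  directory.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")
FLO_MAGIC = 202021.25  # Middlebury sanity-check tag ("PIEH" as float)


@dataclass
class FrameSequence:
    """An ordered RGB frame sequence of one video, values in [0, 1]."""

    frames: np.ndarray                       # (T, H, W, 3) float
    frame_indices: np.ndarray                # (T,) original source indices
    source_fps: Optional[float] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must be (T, H, W, 3)")
        self.frames = np.clip(self.frames, 0.0, 1.0)
        self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
        if len(self.frame_indices) != len(self.frames):
            raise ValueError("frame_indices length mismatch")
        if np.any(np.diff(self.frame_indices) <= 0):
            raise ValueError("frame_indices must be strictly increasing")

    def __len__(self):
        return len(self.frames)

    @property
    def image_size(self):
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class MaskSequence:
    """Per-frame binary foreground masks aligned with a FrameSequence."""

    masks: np.ndarray                        # (T, H, W) in {0, 1}
    extractor: str = "oracle"                # oracle | temporal_median | ...

    def __post_init__(self):
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (T, H, W)")
        uniq = np.unique(self.masks)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("masks must be binary")
        self.masks = self.masks.astype(np.uint8)

    def __len__(self):
        return len(self.masks)


@dataclass
class PhaseAnnotation:
    """Frame-wise surgical-phase label."""

    frame_index: int
    phase_id: int

    def __post_init__(self):
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


def _list_frame_files(dir_path: Path) -> list[Path]:
    files = sorted(p for p in Path(dir_path).iterdir()
                   if p.suffix.lower() in IMAGE_SUFFIXES)
    return files


def load_frame_sequence(dir_path, stride: int = 1,
                        limit: Optional[int] = None,
                        source_fps: Optional[float] = None) -> FrameSequence:
    """Load every ``stride``-th frame of a directory of PNG/JPEG frames.

    Sampling is anchored at the first file, so indices 0, stride, 2·stride, …
    are taken; at most ``limit`` frames are returned.  Surgical video is
    typically subsampled this way (e.g. every 40th frame of a 25/30 FPS
    recording) before translation.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    if limit is not None and limit < 1:
        raise ValueError("limit must be a positive integer")
    files = _list_frame_files(Path(dir_path))
    if not files:
        raise FileNotFoundError(f"no frames found in {dir_path}")
    picked = files[::stride]
    indices = list(range(0, len(files), stride))
    if limit is not None:
        picked, indices = picked[:limit], indices[:limit]
    frames = []
    for f in picked:
        try:
            img = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - re-raise with file name
            raise IOError(f"could not read frame file {f}") from exc
        img = np.asarray(img)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[-1] == 4:
            img = img[..., :3]
        if img.dtype == np.uint8:
            img = img.astype(np.float32) / 255.0
        elif img.dtype == np.uint16:
            img = img.astype(np.float32) / 65535.0
        frames.append(img.astype(np.float32))
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames in {dir_path} have inconsistent sizes: {shapes}")
    return FrameSequence(np.stack(frames), np.asarray(indices),
                         source_fps=source_fps)


def save_frame_sequence(seq: FrameSequence, dir_path, prefix="frame") -> None:
    """Write a sequence as 8-bit PNG frames (zero-padded lexicographic names)."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        q = np.clip(np.round(frame * 255.0), 0, 255).astype(np.uint8)
        iio.imwrite(out / f"{prefix}_{i:06d}.png", q)


def resize_sequence(seq: FrameSequence, size) -> FrameSequence:
    """Bilinearly resample every frame to ``size = (H', W')``."""
    h, w = int(size[0]), int(size[1])
    if h < 8 or w < 8:
        raise ValueError("target size must be at least 8x8")
    if (h, w) == seq.image_size:
        return FrameSequence(seq.frames.copy(), seq.frame_indices.copy(),
                             seq.source_fps)
    frames = np.stack([
        _sk_resize(f, (h, w), order=1, mode="edge", anti_aliasing=False,
                   preserve_range=True)
        for f in seq.frames
    ]).astype(np.float32)
    return FrameSequence(frames, seq.frame_indices.copy(), seq.source_fps)


# ---------------------------------------------------------------------------
# Middlebury .flo
# ---------------------------------------------------------------------------

def write_flo(path, flow) -> None:
    """Write an H×W×2 (dx, dy) field as a Middlebury .flo file."""
    values = np.asarray(getattr(flow, "values", flow), dtype=np.float32)
    if values.ndim != 3 or values.shape[2] != 2:
        raise ValueError("flow must be H x W x 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("flow contains non-finite values")
    h, w = values.shape[:2]
    with open(path, "wb") as fh:
        fh.write(struct.pack("<f", FLO_MAGIC))
        fh.write(struct.pack("<ii", w, h))
        fh.write(values.astype("<f4").tobytes())


def read_flo(path) -> np.ndarray:
    """Read a Middlebury .flo file into an H×W×2 (dx, dy) float32 array."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 12:
        raise ValueError(f"{path}: truncated .flo header")
    magic, = struct.unpack_from("<f", raw, 0)
    if abs(magic - FLO_MAGIC) > 1e-3:
        raise ValueError(f"{path}: bad .flo magic tag {magic!r}")
    w, h = struct.unpack_from("<ii", raw, 4)
    expected = 12 + 4 * 2 * w * h
    if len(raw) < expected:
        raise ValueError(f"{path}: truncated .flo payload "
                         f"({len(raw)} bytes, expected {expected})")
    values = np.frombuffer(raw, dtype="<f4", count=2 * w * h, offset=12)
    return values.reshape(h, w, 2).copy()


# ---------------------------------------------------------------------------
# phase annotations
# ---------------------------------------------------------------------------

def read_phase_annotations(path, n_phases: Optional[int] = None
                           ) -> list[PhaseAnnotation]:
    """Read a 2-column CSV ``frame_index,phase_id`` (with header)."""
    import csv

    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                set(map(str.strip, reader.fieldnames)) < {"frame_index", "phase_id"}:
            raise ValueError(f"{path}: expected header 'frame_index,phase_id'")
        for row in reader:
            ann = PhaseAnnotation(int(row["frame_index"]), int(row["phase_id"]))
            if n_phases is not None and not 0 <= ann.phase_id < n_phases:
                raise ValueError(f"{path}: phase_id {ann.phase_id} outside "
                                 f"label set of size {n_phases}")
            out.append(ann)
    return out


def write_phase_annotations(path, annotations: Sequence[PhaseAnnotation]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "phase_id"])
        for ann in annotations:
            writer.writerow([ann.frame_index, ann.phase_id])
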