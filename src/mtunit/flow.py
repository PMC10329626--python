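"""Flow fields, the backward-warping operator and pluggable flow estimators.

A flow field is an H×W×2 grid of pixel displacements in ``(dx, dy)`` order.
Two conventions are distinguished explicitly:

* ``forward`` — displacement of the content of pixel ``p`` from frame *t* to
  frame *t+1* (the convention every estimator returns),
* ``backward`` — per-target-pixel *source offset*: warping resamples the
  source frame at ``p + flow(p)``.

Negating a forward field gives the backward field that predicts frame *t+1*
from frame *t* (exact for rigid motion away from occlusion boundaries); this
is the direction the motion-cycle loss and the warping-error metric use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from . import nn

FORWARD = "forward"
BACKWARD = "backward"


class CapabilityError(RuntimeError):
    """An estimator/embedder backend is not available in this installation."""


@dataclass
class FlowField:
    """Per-pixel displacement grid in pixels, channels ``(dx, dy)``."""

    values: np.ndarray          # (H, W, 2)
    convention: str = FORWARD

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[2] != 2:
            raise ValueError("flow values must be H x W x 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("flow contains non-finite values")
        if self.convention not in (FORWARD, BACKWARD):
            raise ValueError(f"unknown flow convention {self.convention!r}")

    @property
    def shape(self):
        return self.values.shape[:2]


def to_backward(flow: FlowField) -> FlowField:
    """Negate a forward field into the backward (sampling-offset) convention.

    Exact for uniform/rigid motion on non-occluded pixels; approximate for
    spatially varying flow (the offset is read at the target pixel rather
    than the source pixel).
    """
    if flow.convention == BACKWARD:
        return FlowField(-flow.values, FORWARD)
    return FlowField(-flow.values, BACKWARD)


def warp(frame: np.ndarray, flow: FlowField) -> np.ndarray:
    """Backward-warp an H×W×C frame: ``out(p) = frame(p + flow(p))``.

    Bilinear sampling with border clamping; linear in the frame values and
    bit-exact for zero flow.
    """
    if flow.convention != BACKWARD:
        raise ValueError("warp expects a backward-convention flow "
                         "(use to_backward on estimator output)")
    frame = np.asarray(frame)
    squeeze = frame.ndim == 2
    if squeeze:
        frame = frame[..., None]
    if frame.shape[:2] != flow.shape:
        raise ValueError(f"frame {frame.shape[:2]} and flow {flow.shape} "
                         "shapes do not match")
    nchw = frame.transpose(2, 0, 1)[None]
    fl = flow.values.transpose(2, 0, 1)[None]
    out = nn.warp_bilinear(nchw.astype(np.float32, copy=False),
                           fl.astype(np.float32, copy=False))
    out = out[0].transpose(1, 2, 0)
    return out[..., 0] if squeeze else out


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

@runtime_checkable
class FlowEstimator(Protocol):
    """Anything with a ``name`` and ``estimate(f1, f2) -> FlowField``."""

    name: str

    def estimate(self, f1: np.ndarray, f2: np.ndarray) -> FlowField: ...


def _to_gray(frame):
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 3:
        return frame @ np.array([0.2989, 0.5870, 0.1140])
    return frame


class ClassicalEstimator:
    """Classical coarse-to-fine estimator (iterative Lucas–Kanade or TV-L1).

    Self-contained (no learned weights); adequate for the desk-scale
    synthetic scenes and for sanity checks on real frames.
    """

    def __init__(self, method: str = "ilk", **kwargs):
        if method not in ("ilk", "tvl1"):
            raise ValueError("method must be 'ilk' or 'tvl1'")
        self.name = f"classical-{method}"
        self.method = method
        self.kwargs = kwargs

    def estimate(self, f1, f2) -> FlowField:
        from skimage.registration import optical_flow_ilk, optical_flow_tvl1

        if np.asarray(f1).shape != np.asarray(f2).shape:
            raise ValueError("frames must share a shape")
        g1, g2 = _to_gray(f1), _to_gray(f2)
        fn = optical_flow_ilk if self.method == "ilk" else optical_flow_tvl1
        rowcol = fn(g1, g2, **self.kwargs)  # (2, H, W) as (d_row, d_col)
        values = np.stack([rowcol[1], rowcol[0]], axis=-1)
        return FlowField(values.astype(np.float32), FORWARD)


class OracleEstimator:
    """Exact flow lookup for frames produced by the synthetic generator.

    Matches the query pair against the sample's stored frames and returns
    the analytic forward flow; anything else is an error (never a silent
    fallback).
    """

    name = "oracle"

    def __init__(self, sample):
        self.sample = sample

    def estimate(self, f1, f2) -> FlowField:
        frames = self.sample.frames.frames
        for t in range(len(frames) - 1):
            if np.array_equal(frames[t], f1) and np.array_equal(frames[t + 1], f2):
                return FlowField(self.sample.flows_fwd[t].values.copy(), FORWARD)
        raise CapabilityError("oracle estimator: query frames are not a "
                              "consecutive pair of the attached synthetic sample")


class RAFTAdapter:
    """Adapter slot for an external learned estimator (e.g. RAFT).

    The package does not bundle learned weights; constructing the adapter
    without a backend raises a capability error so callers can fall back
    explicitly.
    """

    name = "raft"

    def __init__(self, backend=None):
        if backend is None:
            raise CapabilityError(
                "no learned optical-flow backend is installed; pass a "
                "callable backend(f1, f2) -> (H, W, 2) forward flow, or use "
                "the 'classical'/'oracle' estimators")
        self.backend = backend

    def estimate(self, f1, f2) -> FlowField:
        values = np.asarray(self.backend(f1, f2), dtype=np.float32)
        return FlowField(values, FORWARD)


def get_estimator(name: str, **kwargs) -> FlowEstimator:
    """Resolve an estimator by config name: oracle | classical | raft."""
    if name == "classical":
        return ClassicalEstimator(**kwargs)
    if name == "oracle":
        sample = kwargs.get("sample")
        if sample is None:
            raise CapabilityError("oracle estimator needs a synthetic sample")
        return OracleEstimator(sample)
    if name == "raft":
        return RAFTAdapter(kwargs.get("backend"))
    raise ValueError(f"unknown flow estimator {name!r}")


def estimate_flow(f1, f2, estimator: FlowEstimator) -> FlowField:
    """Forward-convention flow between two same-shape frames."""
    if np.asarray(f1).shape != np.asarray(f2).shape:
        raise ValueError("frames must share a shape")
    field = estimator.estimate(f1, f2)
    if field.values.shape[:2] != np.asarray(f1).shape[:2]:
        raise ValueError("estimator returned a field of the wrong size")
    return field
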