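"""Synthetic two-domain "surgical" scenes with exact flow and mask ground truth.

Each scene emulates the shared content / distinct style situation of two
cataract-surgery video datasets at desk scale: a static circular
iris/pupil-like background whose palette, radial gradient and noise texture
are the *style*, plus one or two rigid elongated tool sprites translating
with known per-frame velocities (the shared *content*).  Because only the
sprites move and motion is rigid, the forward/backward optical flow and the
binary foreground masks are known analytically, giving exact oracles for
warping and metric tests.

Sprites are rasterised on the integer pixel grid (positions are rounded
before rendering); the emitted flow is the rasterised displacement, so the
warping closure ``warp(frame_t, -flow_fwd) == frame_{t+1}`` holds exactly on
the validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .flow import FlowField, FORWARD, BACKWARD
from .seqio import FrameSequence, MaskSequence

_SEED_MOD = 2 ** 31


@dataclass
class ToolSpec:
    """A rigid elongated sprite moving by translation."""

    shape: str = "rectangle"              # rectangle | capsule
    size: tuple = (6, 20)                 # (h, w) pixels
    color: tuple = (0.85, 0.85, 0.9)
    velocity: tuple = (2.0, 0.0)          # (vx, vy) pixels/frame
    start_position: tuple = (10.0, 10.0)  # (x, y) top-left corner

    def __post_init__(self):
        if self.shape not in ("rectangle", "capsule"):
            raise ValueError(f"unknown tool shape {self.shape!r}")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("tool velocity must be finite")


@dataclass
class BackgroundStyle:
    """Domain-specific palette/texture of the static circular background."""

    base_color: tuple = (0.55, 0.35, 0.25)
    pupil_color: tuple = (0.08, 0.05, 0.05)
    pupil_radius: float = 0.35            # fraction of min(H, W)/2
    gradient_strength: float = 0.5
    noise_amp: float = 0.02


@dataclass
class SceneSpec:
    image_size: tuple = (64, 64)          # (H, W)
    background_style: BackgroundStyle = field(default_factory=BackgroundStyle)
    tools: Sequence[ToolSpec] = field(default_factory=lambda: [ToolSpec()])
    jitter_sd: float = 0.0                # per-frame velocity noise (pixels)
    boundary: str = "error"               # error | clamp | wrap

    def __post_init__(self):
        h, w = self.image_size
        for tool in self.tools:
            if tool.size[0] > h or tool.size[1] > w:
                raise ValueError("tool does not fit within the image")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.boundary not in ("error", "clamp", "wrap"):
            raise ValueError(f"unknown boundary policy {self.boundary!r}")


@dataclass
class SyntheticSample:
    """Frames plus exact flow/mask/validity ground truth for one scene."""

    frames: FrameSequence
    flows_fwd: list                       # T-1 forward FlowFields (t -> t+1)
    flows_bwd: list                       # T-1 backward FlowFields (grid t+1)
    masks: MaskSequence                   # T binary foreground masks
    valid: list                           # T-1 (H, W) bool validity masks
    background: np.ndarray                # (H, W, 3) static background render
    spec: SceneSpec
    seed: int

    def __post_init__(self):
        t = len(self.frames)
        if not (len(self.flows_fwd) == len(self.flows_bwd)
                == len(self.valid) == t - 1 and len(self.masks.masks) == t):
            raise ValueError("inconsistent frame/flow/mask counts")


def _render_background(style: BackgroundStyle, size, rng) -> np.ndarray:
    h, w = size
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / (min(h, w) / 2.0)
    base = np.asarray(style.base_color, dtype=np.float64)
    img = base[None, None] * (1.0 - style.gradient_strength
                              * np.clip(r, 0.0, 1.0))[..., None]
    pupil = r < style.pupil_radius
    img[pupil] = np.asarray(style.pupil_color, dtype=np.float64)
    if style.noise_amp > 0:
        img = img + rng.normal(0.0, style.noise_amp, size=(h, w, 1))
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def _footprint(tool: ToolSpec, pos, size) -> np.ndarray:
    """Binary sprite footprint for an integer top-left position."""
    h, w = size
    th, tw = tool.size
    x0, y0 = int(pos[0]), int(pos[1])
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    if tool.shape == "rectangle":
        return ((xx >= x0) & (xx < x0 + tw) & (yy >= y0) & (yy < y0 + th))
    # capsule: rectangle core with semicircular caps, radius th/2
    rad = th / 2.0
    cy = y0 + (th - 1) / 2.0
    ax0, ax1 = x0 + rad - 0.5, x0 + tw - rad - 0.5
    px = np.clip(xx, ax0, ax1)
    dist = np.sqrt((xx - px) ** 2 + (yy - cy) ** 2)
    return dist <= rad


def _tool_positions(spec: SceneSpec, T: int, rng) -> list:
    """Integer rendered positions per tool per frame, honouring boundary."""
    h, w = spec.image_size
    out = []
    for tool in spec.tools:
        th, tw = tool.size
        pos = np.asarray(tool.start_position, dtype=np.float64)
        track = []
        for t in range(T):
            q = np.round(pos).astype(np.int64)
            if spec.boundary == "wrap":
                q = np.array([q[0] % w, q[1] % h])
            elif spec.boundary == "clamp":
                q = np.array([np.clip(q[0], 0, w - tw),
                              np.clip(q[1], 0, h - th)])
            else:
                if q[0] + tw <= 0 or q[0] >= w or q[1] + th <= 0 or q[1] >= h:
                    raise ValueError(
                        f"tool left the canvas entirely at frame {t} "
                        "(set boundary='clamp' or 'wrap' to allow this)")
            track.append(q)
            vel = np.asarray(tool.velocity, dtype=np.float64)
            if spec.jitter_sd > 0:
                vel = vel + rng.normal(0.0, spec.jitter_sd, size=2)
            pos = pos + vel
        out.append(track)
    return out


def generate_scene(spec: SceneSpec, T: int, seed: int) -> SyntheticSample:
    """Render a deterministic scene of ``T`` frames with exact ground truth."""
    if T < 2:
        raise ValueError("T must be >= 2")
    h, w = spec.image_size
    rng = np.random.default_rng(seed)
    background = _render_background(spec.background_style, (h, w), rng)
    tracks = _tool_positions(spec, T, rng)

    footprints = [[_footprint(tool, tracks[k][t], (h, w))
                   for k, tool in enumerate(spec.tools)] for t in range(T)]

    frames = np.empty((T, h, w, 3), dtype=np.float32)
    masks = np.zeros((T, h, w), dtype=np.uint8)
    for t in range(T):
        frame = background.copy()
        for k, tool in enumerate(spec.tools):
            fp = footprints[t][k]
            frame[fp] = np.asarray(tool.color, dtype=np.float32)
            masks[t][fp] = 1
        frames[t] = frame

    flows_fwd, flows_bwd, valid = [], [], []
    for t in range(T - 1):
        fwd = np.zeros((h, w, 2), dtype=np.float32)
        bwd = np.zeros((h, w, 2), dtype=np.float32)
        ok = np.ones((h, w), dtype=bool)
        overlap_t = np.zeros((h, w), dtype=np.int32)
        overlap_t1 = np.zeros((h, w), dtype=np.int32)
        for k in range(len(spec.tools)):
            disp = (tracks[k][t + 1] - tracks[k][t]).astype(np.float32)
            fp_t, fp_t1 = footprints[t][k], footprints[t + 1][k]
            fwd[fp_t] = disp
            bwd[fp_t1] = -disp
            ok &= ~(fp_t ^ fp_t1)          # occlusion/disocclusion band
            overlap_t += fp_t
            overlap_t1 += fp_t1
        ok &= (overlap_t < 2) & (overlap_t1 < 2)
        flows_fwd.append(FlowField(fwd, FORWARD))
        flows_bwd.append(FlowField(bwd, BACKWARD))
        valid.append(ok)

    seq = FrameSequence(frames, np.arange(T))
    return SyntheticSample(seq, flows_fwd, flows_bwd,
                           MaskSequence(masks, extractor="oracle"),
                           valid, background, spec, int(seed))


# ---------------------------------------------------------------------------
# corruption operators (temporal-artifact emulation)
# ---------------------------------------------------------------------------

def corrupt_sequence(sample: SyntheticSample, mode: str,
                     params: Optional[dict] = None) -> FrameSequence:
    """Apply a controlled temporal corruption to a synthetic sample.

    ``drop_tool`` removes the sprites in the stated frames (disappearing
    tools), ``flicker`` perturbs the global brightness per frame (style
    flicker), ``static_collapse`` replaces every frame with the first
    (mode-collapse emulation).
    """
    params = dict(params or {})
    frames = sample.frames.frames.copy()
    T = len(frames)
    if mode == "drop_tool":
        drop = sorted(int(t) for t in params.get("frames", []))
        if any(t < 0 or t >= T for t in drop):
            raise ValueError(f"drop frames must lie in [0, {T - 1}]")
        for t in drop:
            frames[t] = sample.background
    elif mode == "flicker":
        amp = float(params.get("amplitude", 0.2))
        if amp < 0:
            raise ValueError("flicker amplitude must be >= 0")
        if amp > 0:
            rng = np.random.default_rng(params.get("seed", sample.seed + 1))
            gains = 1.0 + amp * rng.uniform(-1.0, 1.0, size=T)
            frames = np.clip(frames * gains[:, None, None, None],
                             0.0, 1.0).astype(np.float32)
    elif mode == "static_collapse":
        frames = np.repeat(frames[:1], T, axis=0)
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return FrameSequence(frames, sample.frames.frame_indices.copy(),
                         sample.frames.source_fps)


# ---------------------------------------------------------------------------
# unpaired two-domain pairs
# ---------------------------------------------------------------------------

def _derive_seed(seed: int, salt: int) -> int:
    return int((np.uint64(seed) * np.uint64(2654435761)
                + np.uint64(salt)) % _SEED_MOD)


def make_domain_pair(spec_shared: SceneSpec, style_A: BackgroundStyle,
                     style_B: BackgroundStyle, T: int, seed: int,
                     randomize_motion: bool = True):
    """Two style-distinct samples with matched structure, independent motion.

    Both domains use the shared tool count/size/colour distribution from
    ``spec_shared`` but draw their own start positions and velocity signs
    from domain-specific derived seeds, emulating the unpaired setting.
    """
    out = []
    for salt, style in ((1, style_A), (2, style_B)):
        sub_seed = _derive_seed(seed, salt)
        tools = list(spec_shared.tools)
        if randomize_motion:
            rng = np.random.default_rng(_derive_seed(seed, salt + 10))
            h, w = spec_shared.image_size
            new_tools = []
            for tool in tools:
                th, tw = tool.size
                vel = (np.asarray(tool.velocity, dtype=np.float64)
                       * rng.choice([-1.0, 1.0], size=2))
                # keep the whole track inside the canvas for T frames
                dx, dy = vel * (T - 1)
                lo_x = max(0.0, -dx)
                hi_x = min(w - tw, w - tw - dx)
                lo_y = max(0.0, -dy)
                hi_y = min(h - th, h - th - dy)
                if hi_x < lo_x or hi_y < lo_y:
                    start = tool.start_position
                else:
                    start = (rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y))
                new_tools.append(replace(tool, velocity=tuple(vel),
                                         start_position=tuple(start)))
            tools = new_tools
        spec = replace(spec_shared, background_style=style, tools=tools)
        out.append(generate_scene(spec, T, sub_seed))
    return out[0], out[1]
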