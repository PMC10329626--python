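"""Temporal-consistency and image-quality evaluation of translated sequences.

Temporal consistency of a source sequence ``a`` and its translation ``b̂``
is measured on foreground (instrument) masks over *all* ordered frame pairs:

    M_TC^d = 1/(T(T−1)) · Σ_{t≠t'} d( |fg(a_t) − fg(a_{t'})|,
                                      |fg(b̂_t) − fg(b̂_{t'})| )

with ``d`` either RMSE (lower is better, range [0,1]) or single-scale SSIM
(higher is better, ideal 1).  The diagonal ``t = t'`` compares two all-zero
images and is excluded; the printed normalisation 1/(T(T−1)) then makes the
SSIM variant exactly 1 for a perfectly consistent translation.

Three further sequence metrics follow the temporal-consistency literature:
``tOF`` (mean absolute difference of estimated flow fields), ``tLP`` (mean
absolute difference of consecutive-frame perceptual distances) and the
warping error ``M_W`` (error of flow-warped frame predictions in the target
domain).  Frame-quality metrics are FID, KID and LPIPS-style diversity over
pluggable feature embedders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import linalg as sla
from scipy import ndimage
from skimage.metrics import structural_similarity

from .flow import (BACKWARD, CapabilityError, FlowEstimator, FlowField,
                   estimate_flow, warp)
from .seqio import FrameSequence, MaskSequence

__all__ = [
    "MaskSequence", "Embedder", "DefaultEmbedder", "MetricReport",
    "extract_foreground", "temporal_consistency", "tof_distance",
    "tlp_distance", "warping_error", "fid", "kid", "lpips_diversity",
    "evaluate_sequences",
]


# ---------------------------------------------------------------------------
# embedders
# ---------------------------------------------------------------------------

@runtime_checkable
class Embedder(Protocol):
    """Deterministic map from an H×W×3 frame to a fixed-size feature vector."""

    name: str

    def embed(self, frame: np.ndarray) -> np.ndarray: ...

    def distance(self, f1: np.ndarray, f2: np.ndarray) -> float: ...


class DefaultEmbedder:
    """Seeded random-projection CNN embedder (self-contained default).

    Three fixed random conv+ReLU+pool stages followed by global mean/std
    pooling.  Random filters are a classic untrained baseline for perceptual
    feature distances; externally trained perceptual embedders can be
    plugged in through the same protocol when absolute numbers comparable
    with published tables are needed.
    """

    WORK_SIZE = 32   # frames are resampled here so the depth always fits

    def __init__(self, seed: int = 0, widths=(8, 16, 32)):
        self.name = f"random-proj-cnn-{seed}"
        rng = np.random.default_rng(seed)
        self.filters = []
        c_in = 3
        for w in widths:
            k = rng.normal(0.0, 1.0, size=(w, c_in, 3, 3))
            k /= np.sqrt(9 * c_in)
            self.filters.append(k.astype(np.float64))
            c_in = w
        self.dim = 2 * sum(widths)

    def embed(self, frame: np.ndarray) -> np.ndarray:
        from skimage.transform import resize

        x = np.asarray(frame, dtype=np.float64)
        if x.ndim == 2:
            x = np.stack([x] * 3, axis=-1)
        if x.shape[:2] != (self.WORK_SIZE, self.WORK_SIZE):
            x = resize(x, (self.WORK_SIZE, self.WORK_SIZE), order=1,
                       mode="edge", anti_aliasing=False, preserve_range=True)
        x = x.transpose(2, 0, 1)[None]
        feats = []
        for k in self.filters:
            x = _conv_nchw(x, k)
            x = np.maximum(x, 0.0)
            feats.append(x.mean(axis=(0, 2, 3)))
            feats.append(x.std(axis=(0, 2, 3)))
            x = _pool2(x)
        return np.concatenate(feats)

    def distance(self, f1, f2) -> float:
        return float(np.linalg.norm(self.embed(f1) - self.embed(f2)))


def _conv_nchw(x, w):
    kh, kw = w.shape[2:]
    n, c, h, wd = x.shape
    oh, ow = h - kh + 1, wd - kw + 1
    out = np.zeros((n, w.shape[0], oh, ow))
    for i in range(kh):
        for j in range(kw):
            out += np.tensordot(w[:, :, i, j], x[:, :, i:i + oh, j:j + ow],
                                axes=([1], [1])).transpose(1, 0, 2, 3)
    return out


def _pool2(x):
    n, c, h, w = x.shape
    x = x[:, :, :h - h % 2, :w - w % 2]
    return x.reshape(n, c, x.shape[2] // 2, 2, x.shape[3] // 2, 2).mean((3, 5))


def get_embedder(name: str, **kwargs) -> Embedder:
    if name == "default":
        return DefaultEmbedder(**kwargs)
    if name == "lpips":
        raise CapabilityError(
            "no externally trained perceptual embedder is installed; use "
            "'default' or plug in an object satisfying the Embedder protocol")
    raise ValueError(f"unknown embedder {name!r}")


# ---------------------------------------------------------------------------
# foreground extraction
# ---------------------------------------------------------------------------

def extract_foreground(seq: FrameSequence, method: str = "temporal_median",
                       params: Optional[dict] = None,
                       sample=None) -> MaskSequence:
    """Per-frame binary foreground (moving instrument) masks.

    ``oracle`` returns the exact masks of the synthetic sample that produced
    ``seq``; ``temporal_median`` thresholds the absolute grayscale deviation
    from the per-pixel temporal median and applies one binary opening.
    """
    params = dict(params or {})
    if method == "oracle":
        if sample is None or not hasattr(sample, "masks"):
            raise ValueError("oracle extraction requires the synthetic "
                             "sample that generated the sequence")
        return MaskSequence(sample.masks.masks.copy(), extractor="oracle")
    if method != "temporal_median":
        raise ValueError(f"unknown extraction method {method!r}")
    if len(seq) < 2:
        raise ValueError("temporal_median needs at least 2 frames")
    threshold = float(params.get("threshold", 0.1))
    gray = seq.frames @ np.array([0.2989, 0.5870, 0.1140])
    median = np.median(gray, axis=0)
    masks = (np.abs(gray - median[None]) > threshold)
    structure = ndimage.generate_binary_structure(2, 1)
    opened = np.stack([ndimage.binary_opening(m, structure=structure)
                       for m in masks])
    return MaskSequence(opened.astype(np.uint8), extractor="temporal_median")


# ---------------------------------------------------------------------------
# temporal-consistency metrics
# ---------------------------------------------------------------------------

def _pair_distance(u, v, d: str) -> float:
    if d == "RMSE":
        return float(np.sqrt(np.mean((u - v) ** 2)))
    if d == "SSIM":
        # single-scale SSIM with the standard 7px window, shrunk (odd) for
        # tiny mask images; below 3px fall back to global image statistics
        win = min(7, min(u.shape))
        if win % 2 == 0:
            win -= 1
        if win < 3:
            c1, c2 = 0.01 ** 2, 0.03 ** 2
            mu, mv = u.mean(), v.mean()
            vu, vv = u.var(), v.var()
            cov = ((u - mu) * (v - mv)).mean()
            return float(((2 * mu * mv + c1) * (2 * cov + c2))
                         / ((mu ** 2 + mv ** 2 + c1) * (vu + vv + c2)))
        return float(structural_similarity(u, v, data_range=1.0,
                                           win_size=win))
    raise ValueError("d must be 'RMSE' or 'SSIM'")


def temporal_consistency(masks_src: MaskSequence, masks_trans: MaskSequence,
                         d: str = "SSIM") -> float:
    """Mask-difference consistency over all ordered frame pairs (t ≠ t')."""
    ms = masks_src.masks.astype(np.float64)
    mt = masks_trans.masks.astype(np.float64)
    if ms.shape != mt.shape:
        raise ValueError("mask sequences must share length and size")
    t_len = len(ms)
    if t_len < 2:
        raise ValueError("need at least 2 frames")
    acc = 0.0
    for t in range(t_len):
        for t2 in range(t_len):
            if t == t2:
                continue
            acc += _pair_distance(np.abs(ms[t] - ms[t2]),
                                  np.abs(mt[t] - mt[t2]), d)
    return acc / (t_len * (t_len - 1))


def tof_distance(seq_src: FrameSequence, seq_trans: FrameSequence,
                 estimator: FlowEstimator) -> float:
    """Mean absolute difference of source vs. translated flow fields."""
    if len(seq_src) != len(seq_trans):
        raise ValueError("sequences must have equal length")
    if len(seq_src) < 2:
        raise ValueError("need at least 2 frames")
    diffs = []
    for t in range(len(seq_src) - 1):
        f_src = estimate_flow(seq_src.frames[t], seq_src.frames[t + 1],
                              estimator)
        f_trn = estimate_flow(seq_trans.frames[t], seq_trans.frames[t + 1],
                              estimator)
        diffs.append(np.mean(np.abs(f_src.values - f_trn.values)))
    return float(np.mean(diffs))


def tlp_distance(seq_src: FrameSequence, seq_trans: FrameSequence,
                 embedder: Embedder) -> float:
    """Mean |d(src_t, src_{t+1}) − d(trans_t, trans_{t+1})| over t."""
    if len(seq_src) != len(seq_trans):
        raise ValueError("sequences must have equal length")
    if len(seq_src) < 2:
        raise ValueError("need at least 2 frames")
    vals = []
    for t in range(len(seq_src) - 1):
        ds = embedder.distance(seq_src.frames[t], seq_src.frames[t + 1])
        dt = embedder.distance(seq_trans.frames[t], seq_trans.frames[t + 1])
        vals.append(abs(ds - dt))
    return float(np.mean(vals))


def warping_error(seq_trans: FrameSequence, flows_src_bwd: Sequence,
                  valid: Optional[Sequence] = None) -> float:
    """Mean |trans_{t+1} − warp(trans_t, flow_t)| using source-domain flow.

    ``flows_src_bwd`` holds T−1 backward-convention fields (the sampling
    offsets that predict frame t+1 from frame t); ``valid`` optionally
    restricts each term to non-occluded pixels.
    """
    t_len = len(seq_trans)
    if len(flows_src_bwd) != t_len - 1:
        raise ValueError(f"need {t_len - 1} flow fields, got "
                         f"{len(flows_src_bwd)}")
    if valid is not None and len(valid) != t_len - 1:
        raise ValueError("validity mask count mismatch")
    errs = []
    for t in range(t_len - 1):
        fl = flows_src_bwd[t]
        if not isinstance(fl, FlowField):
            fl = FlowField(fl, BACKWARD)
        pred = warp(seq_trans.frames[t], fl)
        err = np.abs(seq_trans.frames[t + 1].astype(np.float64) - pred)
        if valid is not None:
            sel = np.asarray(valid[t], dtype=bool)
            errs.append(float(err[sel].mean()) if sel.any() else 0.0)
        else:
            errs.append(float(err.mean()))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# distribution metrics
# ---------------------------------------------------------------------------

def fid(features_x: np.ndarray, features_y: np.ndarray,
        eps: float = 1e-6) -> float:
    """Fréchet distance between Gaussian fits of two feature sets."""
    x = np.asarray(features_x, dtype=np.float64)
    y = np.asarray(features_y, dtype=np.float64)
    if x.ndim != 2 or y.ndim != 2 or len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 feature vectors per set")
    mu_x, mu_y = x.mean(0), y.mean(0)
    cov_x = np.cov(x, rowvar=False)
    cov_y = np.cov(y, rowvar=False)
    diff = mu_x - mu_y
    prod = cov_x @ cov_y
    covmean, _ = sla.sqrtm(prod, disp=False)
    if not np.isfinite(covmean).all():
        # near-singular covariance: regularise with eps*I
        offset = eps * np.eye(cov_x.shape[0])
        covmean, _ = sla.sqrtm((cov_x + offset) @ (cov_y + offset),
                               disp=False)
    covmean = np.real(covmean)
    value = diff @ diff + np.trace(cov_x + cov_y - 2.0 * covmean)
    return float(max(value, 0.0))


def _poly_kernel(x, y):
    d = x.shape[1]
    return (x @ y.T / d + 1.0) ** 3


def kid(features_x: np.ndarray, features_y: np.ndarray,
        subset_size: int = 100, n_subsets: int = 10, seed: int = 0):
    """Unbiased squared MMD with the cubic polynomial kernel.

    Averaged over ``n_subsets`` seeded subsets of ``subset_size``; returns
    ``(mean, sd)``.
    """
    x = np.asarray(features_x, dtype=np.float64)
    y = np.asarray(features_y, dtype=np.float64)
    m = min(subset_size, len(x), len(y))
    if m < 2:
        raise ValueError("need at least 2 vectors per subset")
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_subsets):
        ix = rng.choice(len(x), m, replace=False)
        iy = ix if len(x) == len(y) else rng.choice(len(y), m, replace=False)
        xs, ys = x[ix], y[iy]
        kxx = _poly_kernel(xs, xs)
        kyy = _poly_kernel(ys, ys)
        kxy = _poly_kernel(xs, ys)
        # the cross-term diagonal is dropped as well: unbiased for
        # independent sets, exactly zero (and symmetric) for identical ones
        term_x = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
        term_y = (kyy.sum() - np.trace(kyy)) / (m * (m - 1))
        cross = (kxy.sum() - np.trace(kxy)) / (m * (m - 1))
        vals.append(term_x + term_y - 2.0 * cross)
    return float(np.mean(vals)), float(np.std(vals))


def lpips_diversity(frames: Sequence[np.ndarray], embedder: Embedder,
                    n_pairs: int = 50, seed: int = 0) -> float:
    """Mean embedder distance over seeded random unordered frame pairs."""
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    feats = [embedder.embed(f) for f in frames]
    vals = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(frames), 2, replace=False)
        vals.append(np.linalg.norm(feats[i] - feats[j]))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Named metric values plus the configuration that produced them."""

    values: dict
    config: dict
    n_items: int
    per_pair: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"metric {name!r} is not finite")


_DEFAULT_METRICS = ("tc_rmse", "tc_ssim", "tof", "tlp", "w")


def evaluate_sequences(pairs, config: Optional[dict] = None) -> MetricReport:
    """Aggregate consistency metrics over (source, translated) pairs.

    ``pairs`` is a list of ``(src, trans)`` FrameSequences, or
    ``(src, trans, extras)`` where ``extras`` may carry ``masks_src``,
    ``masks_trans``, ``flows_bwd`` and ``valid`` ground truth; anything
    missing is derived with the configured extractor/estimator.
    """
    config = dict(config or {})
    metrics = tuple(config.get("metrics", _DEFAULT_METRICS))
    estimator = config.get("estimator")
    embedder = config.get("embedder") or DefaultEmbedder()
    threshold = float(config.get("fg_threshold", 0.1))
    if not pairs:
        raise ValueError("no sequence pairs supplied")

    per_pair: dict = {m: [] for m in metrics}
    for idx, item in enumerate(pairs):
        src, trans = item[0], item[1]
        extras = item[2] if len(item) > 2 else {}
        if len(src) != len(trans):
            raise ValueError(f"pair {idx}: source and translation lengths "
                             "differ")
        try:
            masks_src = extras.get("masks_src")
            masks_trans = extras.get("masks_trans")
            if any(m.startswith("tc_") for m in metrics):
                if masks_src is None:
                    masks_src = extract_foreground(
                        src, "temporal_median", {"threshold": threshold})
                if masks_trans is None:
                    masks_trans = extract_foreground(
                        trans, "temporal_median", {"threshold": threshold})
            for m in metrics:
                if m == "tc_rmse":
                    v = temporal_consistency(masks_src, masks_trans, "RMSE")
                elif m == "tc_ssim":
                    v = temporal_consistency(masks_src, masks_trans, "SSIM")
                elif m == "tof":
                    if estimator is None:
                        raise CapabilityError("tof needs a flow estimator")
                    v = tof_distance(src, trans, estimator)
                elif m == "tlp":
                    v = tlp_distance(src, trans, embedder)
                elif m == "w":
                    flows = extras.get("flows_bwd")
                    if flows is None:
                        if estimator is None:
                            raise CapabilityError(
                                "warping error needs source flows or an "
                                "estimator")
                        flows = [FlowField(
                            -estimate_flow(src.frames[t], src.frames[t + 1],
                                           estimator).values, BACKWARD)
                            for t in range(len(src) - 1)]
                    v = warping_error(trans, flows, extras.get("valid"))
                else:
                    raise ValueError(f"unknown metric {m!r}")
                per_pair[m].append(float(v))
        except Exception as exc:
            raise RuntimeError(f"metric failed on pair {idx}: {exc}") from exc

    values = {m: float(np.mean(v)) for m, v in per_pair.items()}
    cfg_out = {
        "metrics": list(metrics),
        "estimator": getattr(estimator, "name", None),
        "embedder": getattr(embedder, "name", None),
        "fg_threshold": threshold,
    }
    return MetricReport(values, cfg_out, n_items=len(pairs),
                        per_pair=per_pair)
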