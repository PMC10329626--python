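"""Optimisation loop: schedule, single joint generator+MT step, fit/resume.

One training step performs (in this fixed order) a discriminator update on
real vs. freshly translated frames, then a *single joint* update of the
generators and both MT modules that minimises the backbone objective plus
the motion-cycle and MS-SSIM consistency terms for both directions.  Source
flows are inputs (oracle flow for synthetic data, a classical or learned
estimator otherwise) and can be cached as .flo files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as onp

import autograd.numpy as np
from autograd import value_and_grad

from . import nn
from .flow import estimate_flow
from .losses import (LossReport, LossWeights, backbone_weight_map,
                     joint_generator_terms)
from .models import (DiscriminatorSpec, GeneratorSpec, ModelBundle,
                     MTModuleSpec, build_bundle, translate_batch)
from .seqio import FrameSequence, read_flo, write_flo


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    image_size: int = 192
    lr0: float = 2e-4
    betas: tuple = (0.5, 0.999)
    weight_decay: float = 1e-4
    decay_start_epoch: int = 100
    seed: int = 0
    frames_per_sample: int = 2     # consecutive frames per sample
    norm: str = "l1"               # motion-cycle norm
    # Eq.-1 gradient routing: "flow_and_frame" lets the motion-cycle term
    # update the generator through the warped frame (the printed equation
    # stops only the successor frame and the MT-module input);
    # "flow_only" stops the warped frame too, updating just the MT module.
    mt_routing: str = "flow_and_frame"
    msssim_scales: Optional[int] = None
    checkpoint_every: int = 0      # extra periodic checkpoints; 0 = final only

    def __post_init__(self):
        if not 0 <= self.decay_start_epoch < self.epochs:
            raise ValueError("need 0 <= decay_start_epoch < epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.frames_per_sample != 2:
            raise ValueError("training samples are consecutive frame pairs")
        if self.mt_routing not in ("flow_and_frame", "flow_only"):
            raise ValueError("mt_routing must be 'flow_and_frame' or "
                             "'flow_only'")


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Constant ``lr0`` up to the decay start, then linear decay to 0."""
    if not 0 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    if epoch < cfg.decay_start_epoch:
        return cfg.lr0
    span = cfg.epochs - cfg.decay_start_epoch
    return cfg.lr0 * (cfg.epochs - epoch) / span


class PairSample(NamedTuple):
    """One training item: consecutive frames and their forward source flow."""

    frame_t: onp.ndarray    # (H, W, 3) in [0, 1]
    frame_t1: onp.ndarray
    flow_fwd: onp.ndarray   # (H, W, 2) forward flow t -> t+1


def pairs_from_sample(sample) -> list:
    """Consecutive-pair dataset from a synthetic sample (oracle flow)."""
    frames = sample.frames.frames
    return [PairSample(frames[t], frames[t + 1], sample.flows_fwd[t].values)
            for t in range(len(frames) - 1)]


def pairs_from_sequence(seq: FrameSequence, estimator,
                        cache_dir=None) -> list:
    """Consecutive-pair dataset with estimated flows, optionally .flo-cached."""
    out = []
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    for t in range(len(seq) - 1):
        path = cache / f"flow_{t:06d}.flo" if cache else None
        if path is not None and path.exists():
            values = read_flo(path)
        else:
            values = estimate_flow(seq.frames[t], seq.frames[t + 1],
                                   estimator).values
            if path is not None:
                write_flo(path, values)
        out.append(PairSample(seq.frames[t], seq.frames[t + 1], values))
    return out


@dataclass
class TrainState:
    """Everything needed to continue training bit-exactly."""

    epoch: int
    step: int
    rng: onp.random.Generator
    opt_g: nn.Adam
    opt_d: nn.Adam

    @classmethod
    def fresh(cls, bundle: ModelBundle, cfg: TrainConfig) -> "TrainState":
        gm_keys = bundle.generator_keys + bundle.mt_keys
        opt_g = nn.Adam(gm_keys, lr=cfg.lr0, betas=cfg.betas,
                        weight_decay=cfg.weight_decay)
        opt_d = nn.Adam(bundle.discriminator_keys, lr=cfg.lr0,
                        betas=cfg.betas, weight_decay=cfg.weight_decay)
        return cls(0, 0, onp.random.default_rng(cfg.seed), opt_g, opt_d)


def _batch_nchw(frames) -> onp.ndarray:
    arr = onp.stack([onp.asarray(f, dtype=nn.DTYPE) for f in frames])
    return arr.transpose(0, 3, 1, 2)


def _latent_shape(gen_spec: GeneratorSpec, batch_shape):
    n, _, h, w = batch_shape
    f = 2 ** gen_spec.n_downsample
    return (n, gen_spec.bottleneck_width, h // f, w // f)


def train_step(bundle: ModelBundle, batch_A: Sequence[PairSample],
               batch_B: Sequence[PairSample], cfg: TrainConfig,
               state: TrainState, weights: Optional[LossWeights] = None,
               lr: Optional[float] = None):
    """One discriminator update, then one joint generator+MT update.

    Deterministic given (bundle, state, inputs).  Returns the loss report;
    ``state`` and ``bundle.params`` are updated in place.
    """
    weights = weights or LossWeights()
    lr = lr_at_epoch(state.epoch, cfg) if lr is None else lr
    xa_t = _batch_nchw([p.frame_t for p in batch_A])
    xa_t1 = _batch_nchw([p.frame_t1 for p in batch_A])
    xb_t = _batch_nchw([p.frame_t for p in batch_B])
    xb_t1 = _batch_nchw([p.frame_t1 for p in batch_B])
    fa = onp.stack([p.flow_fwd for p in batch_A]).transpose(0, 3, 1, 2)
    fb = onp.stack([p.flow_fwd for p in batch_B]).transpose(0, 3, 1, 2)
    fa = fa.astype(nn.DTYPE)
    fb = fb.astype(nn.DTYPE)
    if xa_t.shape != xb_t.shape:
        raise ValueError("domain batches must share a shape")

    zshape = _latent_shape(bundle.gen_spec, xa_t.shape)
    noise = {k: state.rng.standard_normal(zshape).astype(nn.DTYPE)
             for k in ("eps_a", "eps_b", "eps_ab", "eps_ba")}
    temporal = weights.delta_mt > 0 or weights.delta_ssim > 0
    gspec, dspec, mspec = bundle.gen_spec, bundle.disc_spec, bundle.mt_spec

    # ---- discriminator update (fakes are constants) -----------------------
    fake_ab = onp.asarray(translate_batch(bundle.params, gspec, xa_t, "A->B",
                                          noise["eps_a"]))
    fake_ba = onp.asarray(translate_batch(bundle.params, gspec, xb_t, "B->A",
                                          noise["eps_b"]))
    frozen = dict(bundle.params)

    def d_objective(dparams):
        from .models import discriminate

        p = {**frozen, **dparams}
        loss = 0.0
        n = xa_t.shape[0]
        for real, fake, dom in ((xb_t, fake_ab, "B"), (xa_t, fake_ba, "A")):
            outs = discriminate(p, dspec, np.concatenate([real, fake],
                                                         axis=0), dom)
            per_scale = [0.5 * (np.mean((o[:n] - 1.0) ** 2)
                                + np.mean(o[n:] ** 2)) for o in outs]
            loss = loss + sum(per_scale) / len(per_scale)
        return loss

    dsub = {k: bundle.params[k] for k in bundle.discriminator_keys}
    d_val, d_grads = value_and_grad(d_objective)(dsub)
    state.opt_d.step(dsub, d_grads, lr=lr)
    bundle.params.update(dsub)

    # ---- joint generator + MT update --------------------------------------
    frozen = dict(bundle.params)
    wmap = backbone_weight_map(weights)
    raw_terms: dict = {}

    def g_objective(gparams):
        p = {**frozen, **gparams}
        terms = joint_generator_terms(
            p, gspec, dspec, mspec, xa_t, xa_t1, xb_t, xb_t1, fa, fb,
            noise=noise, temporal=temporal, norm=cfg.norm,
            msssim_scales=cfg.msssim_scales,
            stop_warped_frame=cfg.mt_routing == "flow_only")
        total = None
        for name, value in terms.items():
            contrib = wmap.get(name, 1.0) * value
            total = contrib if total is None else total + contrib
        for name, value in terms.items():
            raw_terms[name] = float(value._value
                                    if hasattr(value, "_value") else value)
        return total

    gm_keys = bundle.generator_keys + bundle.mt_keys
    gsub = {k: bundle.params[k] for k in gm_keys}
    g_val, g_grads = value_and_grad(g_objective)(gsub)
    for key, grad_arr in g_grads.items():
        if not onp.all(onp.isfinite(grad_arr)):
            raise FloatingPointError(f"non-finite gradient for {key}")
    state.opt_g.step(gsub, g_grads, lr=lr)
    bundle.params.update(gsub)
    state.step += 1

    raw_terms["disc_A"] = raw_terms["disc_B"] = float(d_val) / 2.0
    report = LossReport.build(raw_terms, {**wmap, "disc_A": 1.0,
                                          "disc_B": 1.0})
    return report, state


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, bundle: ModelBundle, state: TrainState,
                    cfg: TrainConfig) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "gen_spec": vars(bundle.gen_spec),
        "mt_spec": vars(bundle.mt_spec),
        "disc_spec": vars(bundle.disc_spec),
        "init_seed": bundle.init_seed,
        "cfg": {**vars(cfg), "betas": list(cfg.betas)},
        "epoch": state.epoch,
        "step": state.step,
        "opt_t": {"g": state.opt_g.t, "d": state.opt_d.t},
        "rng_state": state.rng.bit_generator.state,
    }
    arrays = {f"p::{k}": v for k, v in bundle.params.items()}
    for name, opt in (("g", state.opt_g), ("d", state.opt_d)):
        for k in opt.m:
            if opt.m[k] is not None:
                arrays[f"m{name}::{k}"] = opt.m[k]
                arrays[f"v{name}::{k}"] = opt.v[k]
    onp.savez(path, __meta__=json.dumps(meta, default=str), **arrays)
    return path


def load_checkpoint(path):
    data = onp.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    gen_spec = GeneratorSpec(**meta["gen_spec"])
    mt_spec = MTModuleSpec(**meta["mt_spec"])
    disc_spec = DiscriminatorSpec(**meta["disc_spec"])
    params = {k[len("p::"):]: data[k] for k in data.files
              if k.startswith("p::")}
    bundle = ModelBundle(params, gen_spec, mt_spec, disc_spec,
                         int(meta["init_seed"]))
    cfg_dict = dict(meta["cfg"])
    cfg_dict["betas"] = tuple(float(b) for b in cfg_dict["betas"])
    for key in ("epochs", "batch_size", "image_size", "decay_start_epoch",
                "seed", "frames_per_sample", "checkpoint_every"):
        cfg_dict[key] = int(cfg_dict[key])
    for key in ("lr0", "weight_decay"):
        cfg_dict[key] = float(cfg_dict[key])
    if cfg_dict.get("msssim_scales") is not None:
        cfg_dict["msssim_scales"] = int(cfg_dict["msssim_scales"])
    cfg = TrainConfig(**cfg_dict)
    state = TrainState.fresh(bundle, cfg)
    state.epoch = int(meta["epoch"])
    state.step = int(meta["step"])
    state.opt_g.t = int(meta["opt_t"]["g"])
    state.opt_d.t = int(meta["opt_t"]["d"])
    for name, opt in (("g", state.opt_g), ("d", state.opt_d)):
        for k in opt.m:
            key = f"m{name}::{k}"
            if key in data.files:
                opt.m[k] = data[key]
                opt.v[k] = data[f"v{name}::{k}"]
    rng = onp.random.default_rng()
    rng.bit_generator.state = _rng_state_from_meta(meta["rng_state"])
    state.rng = rng
    return bundle, state, cfg


def _rng_state_from_meta(st):
    # json stringifies the uint128 seeds; restore integer types
    def fix(v):
        if isinstance(v, dict):
            return {k: fix(x) for k, x in v.items()}
        if isinstance(v, str) and v.lstrip("-").isdigit():
            return int(v)
        return v
    return fix(st)


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def fit(cfg: TrainConfig, dataset_A: Sequence[PairSample],
        dataset_B: Sequence[PairSample], out_dir,
        weights: Optional[LossWeights] = None,
        bundle: Optional[ModelBundle] = None,
        gen_spec: Optional[GeneratorSpec] = None,
        mt_spec: Optional[MTModuleSpec] = None,
        disc_spec: Optional[DiscriminatorSpec] = None,
        resume_from=None, max_steps: Optional[int] = None) -> Path:
    """Run the training schedule; returns the final checkpoint path.

    Writes ``losses.csv`` (one row per epoch of mean weighted totals and
    terms) and ``checkpoint.npz`` under ``out_dir``.  ``resume_from``
    restores a checkpoint and continues bit-exactly.
    """
    if not dataset_A or not dataset_B:
        raise ValueError("both datasets must be non-empty")
    n_batches = min(len(dataset_A), len(dataset_B)) // cfg.batch_size
    if n_batches < 1:
        raise ValueError("datasets are shorter than one batch")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if resume_from is not None:
        bundle, state, cfg = load_checkpoint(resume_from)
        start_epoch = state.epoch
    else:
        if bundle is None:
            bundle = build_bundle(gen_spec, mt_spec, disc_spec, seed=cfg.seed)
        state = TrainState.fresh(bundle, cfg)
        start_epoch = 0

    weights = weights or LossWeights()
    csv_path = out / "losses.csv"
    new_csv = resume_from is None or not csv_path.exists()
    fieldnames = None
    rows = []
    steps_done = 0
    for epoch in range(start_epoch, cfg.epochs):
        state.epoch = epoch
        lr = lr_at_epoch(epoch, cfg)
        idx_a = state.rng.permutation(len(dataset_A))
        idx_b = state.rng.permutation(len(dataset_B))
        epoch_terms: dict = {}
        epoch_totals = []
        for b in range(n_batches):
            sel_a = idx_a[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            sel_b = idx_b[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            report, state = train_step(
                bundle, [dataset_A[i] for i in sel_a],
                [dataset_B[i] for i in sel_b], cfg, state, weights, lr=lr)
            epoch_totals.append(report.total)
            for k, v in report.terms.items():
                epoch_terms.setdefault(k, []).append(v)
            steps_done += 1
            if max_steps is not None and steps_done >= max_steps:
                break
        row = {"epoch": epoch, "lr": lr,
               "total": float(onp.mean(epoch_totals))}
        row.update({k: float(onp.mean(v)) for k, v in epoch_terms.items()})
        rows.append(row)
        if fieldnames is None:
            fieldnames = list(row.keys())
        state.epoch = epoch + 1
        if cfg.checkpoint_every and (epoch + 1) % cfg.checkpoint_every == 0:
            save_checkpoint(out / f"checkpoint_ep{epoch + 1:04d}.npz",
                            bundle, state, cfg)
        if max_steps is not None and steps_done >= max_steps:
            break

    mode = "w" if new_csv else "a"
    with open(csv_path, mode, newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        if new_csv:
            writer.writeheader()
        writer.writerows(rows)
    return save_checkpoint(out / "checkpoint.npz", bundle, state, cfg)


def translate_sequence(bundle: ModelBundle, seq: FrameSequence,
                       direction: str) -> FrameSequence:
    """Frame-by-frame deterministic translation of a whole sequence."""
    from .models import translate_frame

    frames = onp.stack([translate_frame(bundle, f, direction)
                        for f in seq.frames])
    return FrameSequence(frames, seq.frame_indices.copy(), seq.source_fps)
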