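"""Network architectures: shared-latent translators, discriminators, MT modules.

The backbone follows the shared-latent-space VAE-GAN recipe: per-domain
encoders ``E_A``/``E_B`` and decoders ``G_A``/``G_B`` whose innermost
residual blocks are *shared* across domains, so corresponding images map to
a common Gaussian latent.  Cross-domain translation is
``f_B(a) = G_B(E_A(a))`` and vice versa.  Two multi-scale patch
discriminators ``D_A``/``D_B`` judge realism per domain.

Motion translation: ``M_AB`` is a U-Net taking the 11-channel concatenation
``(a_t, a_{t+1}, sg(b̂_t), F_A)`` — two source frames, one gradient-stopped
translated frame, and the 2-channel source flow — and emitting a 2-channel
backward-convention flow field ready for warping.  ``M_AB`` and ``M_BA`` are
independent modules.

All parameters live in one flat dict keyed by prefixes (EA/EB/ES/GS/GA/GB/
DA/DB/MAB/MBA); shared blocks are simply keys used by both domain paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as onp

import autograd.numpy as np

from . import nn
from .flow import BACKWARD, FlowField


@dataclass
class GeneratorSpec:
    input_channels: int = 3
    base_width: int = 16
    n_downsample: int = 2
    n_resblocks: int = 2
    n_shared_resblocks: int = 1   # innermost latent blocks shared across domains

    def __post_init__(self):
        if self.input_channels != 3:
            raise ValueError("generators expect RGB input")
        if self.n_downsample < 1 or self.n_resblocks < 1:
            raise ValueError("need at least one downsample and one resblock")
        if not 1 <= self.n_shared_resblocks <= self.n_resblocks:
            raise ValueError("shared block count must be in [1, n_resblocks]")

    @property
    def bottleneck_width(self):
        return self.base_width * 2 ** self.n_downsample


@dataclass
class MTModuleSpec:
    in_channels: int = 11   # a_t (3) + a_{t+1} (3) + translated frame (3) + flow (2)
    out_channels: int = 2
    unet_depth: int = 3
    base_width: int = 16
    flow_in_scale: float = 8.0    # source-flow conditioning divisor
    flow_out_scale: float = 8.0   # head output multiplier (pixels)

    def __post_init__(self):
        if self.in_channels != 11:
            raise ValueError("MT module input must be 11 channels "
                             "(frame t, frame t+1, translated frame, flow)")
        if self.out_channels != 2:
            raise ValueError("MT module output must be a 2-channel flow field")
        if self.unet_depth < 2:
            raise ValueError("unet_depth must be >= 2")


@dataclass
class DiscriminatorSpec:
    n_scales: int = 2
    n_layers: int = 3
    base_width: int = 16

    def __post_init__(self):
        if min(self.n_scales, self.n_layers, self.base_width) < 1:
            raise ValueError("discriminator spec fields must be positive")


@dataclass
class ModelBundle:
    """All parameter sets plus the specs and the initialisation seed."""

    params: dict
    gen_spec: GeneratorSpec
    mt_spec: MTModuleSpec
    disc_spec: DiscriminatorSpec
    init_seed: int

    def keys_of(self, *prefixes) -> list:
        return [k for k in self.params
                if any(k.startswith(p + ".") for p in prefixes)]

    @property
    def generator_keys(self):
        return self.keys_of("EA", "EB", "ES", "GS", "GA", "GB")

    @property
    def mt_keys(self):
        return self.keys_of("MAB", "MBA")

    @property
    def discriminator_keys(self):
        return self.keys_of("DA", "DB")


# ---------------------------------------------------------------------------
# parameter initialisation
# ---------------------------------------------------------------------------

def _init_resblock(params, rng, prefix, width):
    nn.add_conv(params, rng, f"{prefix}.c1", width, width, 3)
    nn.add_conv(params, rng, f"{prefix}.c2", width, width, 3)


def _init_encoder(params, rng, prefix, spec: GeneratorSpec):
    w = spec.base_width
    nn.add_conv(params, rng, f"{prefix}.in", w, 3, 7)
    for i in range(spec.n_downsample):
        nn.add_conv(params, rng, f"{prefix}.down{i}", w * 2, w, 3)
        w *= 2
    for i in range(spec.n_resblocks - spec.n_shared_resblocks):
        _init_resblock(params, rng, f"{prefix}.res{i}", w)


def _init_decoder(params, rng, prefix, spec: GeneratorSpec):
    w = spec.bottleneck_width
    for i in range(spec.n_resblocks - spec.n_shared_resblocks):
        _init_resblock(params, rng, f"{prefix}.res{i}", w)
    for i in range(spec.n_downsample):
        nn.add_conv(params, rng, f"{prefix}.up{i}", w // 2, w, 3)
        w //= 2
    nn.add_conv(params, rng, f"{prefix}.out", 3, w, 7)


def _init_discriminator(params, rng, prefix, spec: DiscriminatorSpec):
    for s in range(spec.n_scales):
        w_in, w = 3, spec.base_width
        for layer in range(spec.n_layers):
            nn.add_conv(params, rng, f"{prefix}.s{s}.c{layer}", w, w_in, 4)
            w_in, w = w, min(w * 2, 8 * spec.base_width)
        nn.add_conv(params, rng, f"{prefix}.s{s}.out", 1, w_in, 3)


def _init_mt(params, rng, prefix, spec: MTModuleSpec):
    w = spec.base_width
    nn.add_conv(params, rng, f"{prefix}.in", w, spec.in_channels, 3)
    for i in range(1, spec.unet_depth):
        nn.add_conv(params, rng, f"{prefix}.down{i}", w * 2, w, 3)
        nn.add_conv(params, rng, f"{prefix}.enc{i}", w * 2, w * 2, 3)
        w *= 2
    for i in range(spec.unet_depth - 1, 0, -1):
        nn.add_conv(params, rng, f"{prefix}.up{i}", w // 2, w, 3)
        nn.add_conv(params, rng, f"{prefix}.dec{i}", w // 2, w, 3)
        w //= 2
    # zero-initialised head: the predicted flow starts at exactly zero
    nn.add_conv(params, rng, f"{prefix}.head", spec.out_channels, w, 1,
                zero=True)


def build_bundle(gen_spec: Optional[GeneratorSpec] = None,
                 mt_spec: Optional[MTModuleSpec] = None,
                 disc_spec: Optional[DiscriminatorSpec] = None,
                 seed: int = 0) -> ModelBundle:
    """Xavier-initialise every network deterministically from ``seed``."""
    gen_spec = gen_spec or GeneratorSpec()
    mt_spec = mt_spec or MTModuleSpec()
    disc_spec = disc_spec or DiscriminatorSpec()
    rng = onp.random.default_rng(seed)
    params: dict = {}
    for prefix in ("EA", "EB"):
        _init_encoder(params, rng, prefix, gen_spec)
    for i in range(gen_spec.n_shared_resblocks):
        _init_resblock(params, rng, f"ES.res{i}", gen_spec.bottleneck_width)
        _init_resblock(params, rng, f"GS.res{i}", gen_spec.bottleneck_width)
    for prefix in ("GA", "GB"):
        _init_decoder(params, rng, prefix, gen_spec)
    for prefix in ("DA", "DB"):
        _init_discriminator(params, rng, prefix, disc_spec)
    for prefix in ("MAB", "MBA"):
        _init_mt(params, rng, prefix, mt_spec)
    return ModelBundle(params, gen_spec, mt_spec, disc_spec, int(seed))


# ---------------------------------------------------------------------------
# forward passes (pure functions of the params dict; autograd-traceable)
# ---------------------------------------------------------------------------

def _resblock(params, prefix, x):
    y = nn.instance_norm(nn.apply_conv(params, f"{prefix}.c1", x, pad=1))
    y = nn.relu(y)
    y = nn.instance_norm(nn.apply_conv(params, f"{prefix}.c2", y, pad=1))
    return x + y


def encode(params, gen_spec: GeneratorSpec, x01, domain: str):
    """Map a [0,1] NCHW batch to the shared latent mean ``mu``."""
    prefix = {"A": "EA", "B": "EB"}[domain]
    x = 2.0 * x01 - 1.0
    h = nn.relu(nn.instance_norm(nn.apply_conv(params, f"{prefix}.in", x,
                                               pad=3)))
    for i in range(gen_spec.n_downsample):
        h = nn.relu(nn.instance_norm(
            nn.apply_conv(params, f"{prefix}.down{i}", h, stride=2, pad=1)))
    for i in range(gen_spec.n_resblocks - gen_spec.n_shared_resblocks):
        h = _resblock(params, f"{prefix}.res{i}", h)
    for i in range(gen_spec.n_shared_resblocks):
        h = _resblock(params, f"ES.res{i}", h)
    return h


def decode(params, gen_spec: GeneratorSpec, z, domain: str):
    """Map a latent code to a [0,1] NCHW image batch."""
    prefix = {"A": "GA", "B": "GB"}[domain]
    h = z
    for i in range(gen_spec.n_shared_resblocks):
        h = _resblock(params, f"GS.res{i}", h)
    for i in range(gen_spec.n_resblocks - gen_spec.n_shared_resblocks):
        h = _resblock(params, f"{prefix}.res{i}", h)
    for i in range(gen_spec.n_downsample):
        h = nn.upsample2(h)
        h = nn.relu(nn.instance_norm(
            nn.apply_conv(params, f"{prefix}.up{i}", h, pad=1)))
    y = nn.tanh(nn.apply_conv(params, f"{prefix}.out", h, pad=3))
    return (y + 1.0) / 2.0


def translate_batch(params, gen_spec: GeneratorSpec, x01, direction: str,
                    noise=None):
    """Cross-domain translation of an NCHW batch; deterministic if no noise."""
    src, dst = _parse_direction(direction)
    mu = encode(params, gen_spec, x01, src)
    z = mu if noise is None else mu + noise
    return decode(params, gen_spec, z, dst)


def discriminate(params, disc_spec: DiscriminatorSpec, x01, domain: str):
    """Multi-scale patch discriminator logits (list of NCHW maps)."""
    prefix = {"A": "DA", "B": "DB"}[domain]
    x = 2.0 * x01 - 1.0
    outs = []
    for s in range(disc_spec.n_scales):
        h = x
        for layer in range(disc_spec.n_layers):
            h = nn.leaky_relu(nn.apply_conv(params, f"{prefix}.s{s}.c{layer}",
                                            h, stride=2, pad=1))
        outs.append(nn.apply_conv(params, f"{prefix}.s{s}.out", h, pad=1))
        x = nn.avg_pool2(x)
    return outs


def mt_forward(params, mt_spec: MTModuleSpec, x_t, x_t1, trans_t, flow_src,
               direction: str):
    """Translated backward flow from the 11-channel conditioning stack.

    ``trans_t`` (the translated frame) is gradient-stopped here, so this
    path never updates the generator that produced it.
    """
    prefix = {"A->B": "MAB", "B->A": "MBA"}[_canon_direction(direction)]
    stack = np.concatenate([
        2.0 * x_t - 1.0,
        2.0 * x_t1 - 1.0,
        nn.stop_gradient(2.0 * trans_t - 1.0),
        flow_src / mt_spec.flow_in_scale,
    ], axis=1)
    if stack.shape[1] != mt_spec.in_channels:
        raise ValueError(f"conditioning stack has {stack.shape[1]} channels, "
                         f"expected {mt_spec.in_channels}")
    h = nn.leaky_relu(nn.apply_conv(params, f"{prefix}.in", stack, pad=1))
    skips = [h]
    w = mt_spec.base_width
    for i in range(1, mt_spec.unet_depth):
        h = nn.leaky_relu(nn.instance_norm(
            nn.apply_conv(params, f"{prefix}.down{i}", h, stride=2, pad=1)))
        h = nn.leaky_relu(nn.instance_norm(
            nn.apply_conv(params, f"{prefix}.enc{i}", h, pad=1)))
        skips.append(h)
        w *= 2
    for i in range(mt_spec.unet_depth - 1, 0, -1):
        h = nn.upsample2(h)
        h = nn.leaky_relu(nn.apply_conv(params, f"{prefix}.up{i}", h, pad=1))
        h = np.concatenate([h, skips[i - 1]], axis=1)
        h = nn.leaky_relu(nn.apply_conv(params, f"{prefix}.dec{i}", h, pad=1))
    raw = nn.apply_conv(params, f"{prefix}.head", h)
    return raw * mt_spec.flow_out_scale


# ---------------------------------------------------------------------------
# public single-frame interface
# ---------------------------------------------------------------------------

def _canon_direction(direction: str) -> str:
    d = direction.replace("a2b", "A->B").replace("b2a", "B->A")
    if d not in ("A->B", "B->A"):
        raise ValueError(f"unknown direction {direction!r}")
    return d


def _parse_direction(direction: str):
    d = _canon_direction(direction)
    return ("A", "B") if d == "A->B" else ("B", "A")


def _to_nchw(frame):
    frame = onp.asarray(frame, dtype=nn.DTYPE)
    return frame.transpose(2, 0, 1)[None]


def translate_frame(bundle: ModelBundle, frame, direction: str,
                    sample_latent: bool = False, rng=None) -> onp.ndarray:
    """Translate one H×W×3 frame in [0,1] across domains.

    With ``sample_latent`` off the latent mean is used, so repeated calls
    are identical; with it on, unit-Gaussian noise from ``rng`` is added.
    """
    x = _to_nchw(frame)
    if onp.min(x) < 0 or onp.max(x) > 1:
        raise ValueError("frame values must lie in [0, 1]")
    noise = None
    if sample_latent:
        rng = rng or onp.random.default_rng()
        src, _ = _parse_direction(direction)
        mu = encode(bundle.params, bundle.gen_spec, x, src)
        noise = rng.standard_normal(mu.shape).astype(nn.DTYPE)
    y = translate_batch(bundle.params, bundle.gen_spec, x, direction, noise)
    return onp.clip(onp.asarray(y)[0].transpose(1, 2, 0), 0.0, 1.0)


def translate_motion(bundle: ModelBundle, a_t, a_t1, b_hat_t,
                     f_src: FlowField, direction: str) -> FlowField:
    """Translate source motion into a backward flow for the target domain."""
    shapes = {onp.asarray(a_t).shape, onp.asarray(a_t1).shape,
              onp.asarray(b_hat_t).shape}
    if len(shapes) != 1:
        raise ValueError("frames must share a shape")
    if f_src.values.shape[:2] != onp.asarray(a_t).shape[:2]:
        raise ValueError("flow spatial size must match the frames")
    out = mt_forward(bundle.params, bundle.mt_spec, _to_nchw(a_t),
                     _to_nchw(a_t1), _to_nchw(b_hat_t),
                     f_src.values.transpose(2, 0, 1)[None].astype(nn.DTYPE),
                     direction)
    return FlowField(onp.asarray(out)[0].transpose(1, 2, 0), BACKWARD)
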