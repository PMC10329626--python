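"""Objective terms: VAE-GAN backbone, motion-cycle and MS-SSIM consistency.

Two spatio-temporal terms ride on top of the shared-latent backbone, for
translated consecutive frames ``b̂_t = f_B(a_t)``, ``b̂_{t+1} = f_B(a_{t+1})``
and the translated backward flow ``F̂`` from the MT module:

* motion-cycle:   ``L_MT  =  δ_MT · ‖ sg(b̂_{t+1}) − f̃(b̂_t, F̂) ‖``
* structural:     ``L_SSIM = −δ_SSIM · MS-SSIM( b̂_t, sg(f̃(b̂_t, F̂)) )``

where ``f̃`` is bilinear backward warping and ``sg`` the stop-gradient.  The
successor frame and the MT-module input are always gradient-stopped, so the
MT modules train jointly with the generators in a single optimisation step;
whether the motion-cycle term also updates the generator through the warped
frame is configurable (see :func:`motion_cycle_loss` and the training
config).  The structural term updates the generator through its first
argument only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as onp

import autograd.numpy as np

from . import nn
from .flow import BACKWARD, FlowField
from .models import (DiscriminatorSpec, GeneratorSpec, ModelBundle, decode,
                     discriminate, encode)

# canonical MS-SSIM scale weights (standard five-scale setting)
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
_WIN = 11
_SIGMA = 1.5
_C1 = 0.01 ** 2
_C2 = 0.03 ** 2


@dataclass
class LossWeights:
    """Objective weights; defaults are the full-scale training setting."""

    lambda0: float = 10.0   # adversarial, A->B direction
    lambda1: float = 0.1    # VAE KL (per domain)
    lambda2: float = 100.0  # VAE reconstruction (per domain)
    lambda3: float = 0.1    # cycle KL
    lambda4: float = 100.0  # cycle reconstruction
    lambda5: float = 10.0   # adversarial, B->A direction
    delta_mt: float = 10.0  # motion-cycle weight
    delta_ssim: float = 10.0  # structural-consistency weight

    def __post_init__(self):
        for name in ("lambda0", "lambda1", "lambda2", "lambda3", "lambda4",
                     "lambda5", "delta_mt", "delta_ssim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class LossReport:
    """Named raw terms, their weights, and the weighted total."""

    terms: dict
    weight_of: dict
    total: float

    @classmethod
    def build(cls, terms: dict, weight_of: dict) -> "LossReport":
        clean = {}
        for name, value in terms.items():
            v = float(value)
            if not onp.isfinite(v):
                raise FloatingPointError(f"loss term {name!r} is not finite")
            clean[name] = v
        total = sum(weight_of.get(name, 1.0) * v for name, v in clean.items())
        return cls(clean, dict(weight_of), float(total))


# ---------------------------------------------------------------------------
# shape plumbing
# ---------------------------------------------------------------------------

def _as_nchw(x):
    """Accept H×W, H×W×C or N×C×H×W (plain or traced) arrays.

    Plain arrays are made contiguous so that numerically identical inputs
    take bit-identical BLAS paths (keeps e.g. MS-SSIM(x, x) exactly 1).
    """
    if x.ndim == 2:
        out = np.reshape(x, (1, 1) + x.shape)
    elif x.ndim == 3:
        out = np.transpose(x, (2, 0, 1))[None]
    elif x.ndim == 4:
        out = x
    else:
        raise ValueError(f"cannot interpret array of ndim {x.ndim} as images")
    if isinstance(out, onp.ndarray):
        out = onp.ascontiguousarray(out)
    return out


def _flow_nchw(flow):
    if isinstance(flow, FlowField):
        if flow.convention != BACKWARD:
            raise ValueError("losses expect a backward-convention flow")
        return flow.values.transpose(2, 0, 1)[None]
    if flow.ndim == 3:
        return np.transpose(flow, (2, 0, 1))[None]
    return flow


# ---------------------------------------------------------------------------
# MS-SSIM
# ---------------------------------------------------------------------------

def _gauss_kernel():
    ax = onp.arange(_WIN) - (_WIN - 1) / 2.0
    k = onp.exp(-(ax ** 2) / (2 * _SIGMA ** 2))
    return k / k.sum()


_KERNEL_1D = _gauss_kernel()


def _blur(x):
    return nn.gauss_blur_valid(x, _KERNEL_1D)


def max_feasible_scales(h: int, w: int) -> int:
    """Largest scale count such that the coarsest level still fits the window."""
    m = 0
    s = min(h, w)
    while s >= _WIN and m < len(MSSSIM_WEIGHTS):
        m += 1
        s //= 2
    return m


def _ssim_terms(x, y):
    mu_x, mu_y = _blur(x), _blur(y)
    sxx = _blur(x * x) - mu_x * mu_x
    syy = _blur(y * y) - mu_y * mu_y
    sxy = _blur(x * y) - mu_x * mu_y
    lum = (2.0 * mu_x * mu_y + _C1) / (mu_x * mu_x + mu_y * mu_y + _C1)
    cs = (2.0 * sxy + _C2) / (sxx + syy + _C2)
    return lum, cs


def ms_ssim(x, y, n_scales: Optional[int] = None, weights=None):
    """Multi-scale structural similarity of two [0,1] images (or batches).

    Per-scale contrast/structure means are combined with the coarsest-scale
    luminance using the canonical exponent weights; ``n_scales=None`` picks
    the largest feasible count for the image size (weights renormalised).
    Symmetric, equal to 1 exactly at ``x == y``.  Differentiable.
    """
    xb, yb = _as_nchw(x), _as_nchw(y)
    if xb.shape != yb.shape:
        raise ValueError("ms_ssim inputs must share a shape")
    h, w = xb.shape[2], xb.shape[3]
    feasible = max_feasible_scales(h, w)
    if feasible < 1:
        raise ValueError(f"image {h}x{w} is smaller than the {_WIN}px window")
    if n_scales is None:
        n_scales = feasible
    if n_scales > feasible:
        raise ValueError(
            f"{n_scales} scales infeasible for a {h}x{w} image with an "
            f"{_WIN}px window; use n_scales <= {feasible}")
    if weights is None:
        weights = MSSSIM_WEIGHTS[:n_scales]
    if len(weights) != n_scales:
        raise ValueError("one weight per scale required")
    wsum = float(sum(weights))
    weights = [wt / wsum for wt in weights]

    value = 1.0
    for s in range(n_scales):
        lum, cs = _ssim_terms(xb, yb)
        if s == n_scales - 1:
            term = np.mean(lum * cs)
        else:
            term = np.mean(cs)
            xb, yb = nn.avg_pool2(xb), nn.avg_pool2(yb)
        value = value * np.maximum(term, 1e-8) ** weights[s]
    return value


# ---------------------------------------------------------------------------
# temporal terms
# ---------------------------------------------------------------------------

def motion_cycle_loss(b_hat_t, b_hat_t1, f_hat, delta_mt: float = 10.0,
                      norm: str = "l1", stop_warped_frame: bool = True):
    """Motion-cycle consistency between warped and translated successors.

    The successor frame is always gradient-stopped; by default the warped
    frame is stopped too, so the gradient reaches only the flow (hence the
    MT module).  Set ``stop_warped_frame=False`` to also update the
    generator through the warp.
    """
    xt = _as_nchw(b_hat_t)
    xt1 = _as_nchw(b_hat_t1)
    fl = _flow_nchw(f_hat)
    if xt.shape != xt1.shape or fl.shape[2:] != xt.shape[2:]:
        raise ValueError("frame/flow shapes do not match")
    if stop_warped_frame:
        xt = nn.stop_gradient(xt)
    warped = nn.warp_bilinear(xt, fl)
    diff = nn.stop_gradient(xt1) - warped
    if norm == "l1":
        core = np.mean(np.abs(diff))
    elif norm == "l2":
        core = np.mean(diff * diff)
    else:
        raise ValueError("norm must be 'l1' or 'l2'")
    return delta_mt * core


def structural_consistency_loss(b_hat_t, f_hat, delta_ssim: float = 10.0,
                                n_scales: Optional[int] = None):
    """Penalise low MS-SSIM between a frame and its (stopped) warped self.

    Returns ``−δ_SSIM · MS-SSIM(b̂_t, sg(f̃(b̂_t, F̂)))``; the gradient reaches
    the generator only through the first argument.  Equals ``−δ_SSIM``
    exactly at zero flow and is bounded below by it.
    """
    xt = _as_nchw(b_hat_t)
    fl = _flow_nchw(f_hat)
    warped = nn.stop_gradient(nn.warp_bilinear(nn.stop_gradient(xt), fl))
    return -delta_ssim * ms_ssim(xt, warped, n_scales=n_scales)


# ---------------------------------------------------------------------------
# backbone objective
# ---------------------------------------------------------------------------

def _gan_generator_term(params, disc_spec, fake, domain):
    outs = discriminate(params, disc_spec, fake, domain)
    return sum(np.mean((o - 1.0) ** 2) for o in outs) / len(outs)


def discriminator_loss(params, disc_spec: DiscriminatorSpec, real, fake,
                       domain: str):
    """Least-squares discriminator objective (real -> 1, fake -> 0)."""
    real_outs = discriminate(params, disc_spec, real, domain)
    fake_outs = discriminate(params, disc_spec, fake, domain)
    loss = 0.0
    for ro, fo in zip(real_outs, fake_outs):
        loss = loss + 0.5 * (np.mean((ro - 1.0) ** 2) + np.mean(fo ** 2))
    return loss / len(real_outs)


def backbone_terms(params, gen_spec: GeneratorSpec,
                   disc_spec: DiscriminatorSpec, xa, xb, noise=None):
    """Raw generator-side backbone terms for NCHW batches ``xa``/``xb``.

    ``noise`` is an optional dict of unit-Gaussian latent perturbations
    (keys eps_a, eps_b, eps_ab, eps_ba); without it the latent means are
    used, making the computation deterministic.
    """
    noise = noise or {}

    def z_of(mu, key):
        eps = noise.get(key)
        return mu if eps is None else mu + eps

    terms = {}
    mu_a = encode(params, gen_spec, xa, "A")
    mu_b = encode(params, gen_spec, xb, "B")
    terms["vae_kl_A"] = np.mean(mu_a ** 2)
    terms["vae_kl_B"] = np.mean(mu_b ** 2)
    x_aa = decode(params, gen_spec, z_of(mu_a, "eps_a"), "A")
    x_bb = decode(params, gen_spec, z_of(mu_b, "eps_b"), "B")
    terms["vae_rec_A"] = np.mean(np.abs(x_aa - xa))
    terms["vae_rec_B"] = np.mean(np.abs(x_bb - xb))
    x_ab = decode(params, gen_spec, z_of(mu_a, "eps_a"), "B")
    x_ba = decode(params, gen_spec, z_of(mu_b, "eps_b"), "A")
    terms["gan_B"] = _gan_generator_term(params, disc_spec, x_ab, "B")
    terms["gan_A"] = _gan_generator_term(params, disc_spec, x_ba, "A")
    mu_ab = encode(params, gen_spec, x_ab, "B")
    mu_ba = encode(params, gen_spec, x_ba, "A")
    terms["cyc_kl_A"] = np.mean(mu_ab ** 2)
    terms["cyc_kl_B"] = np.mean(mu_ba ** 2)
    x_aba = decode(params, gen_spec, z_of(mu_ab, "eps_ab"), "A")
    x_bab = decode(params, gen_spec, z_of(mu_ba, "eps_ba"), "B")
    terms["cyc_rec_A"] = np.mean(np.abs(x_aba - xa))
    terms["cyc_rec_B"] = np.mean(np.abs(x_bab - xb))
    return terms, {"x_ab": x_ab, "x_ba": x_ba}


def joint_generator_terms(params, gen_spec, disc_spec, mt_spec,
                          xa_t, xa_t1, xb_t, xb_t1, fa, fb, noise=None,
                          temporal: bool = True, norm: str = "l1",
                          msssim_scales: Optional[int] = None,
                          stop_warped_frame: bool = False) -> dict:
    """All generator-side raw terms for one step, with batched forwards.

    Numerically identical to :func:`backbone_terms` plus the temporal terms;
    the independent encoder/decoder passes are stacked along the batch axis
    so the whole objective runs in a handful of large convolutions.  Frames
    are NCHW pairs ``(x_t, x_{t+1})`` per domain; ``fa``/``fb`` are the
    forward source flows as (N,2,H,W).
    """
    from .models import mt_forward

    noise = noise or {}
    n = xa_t.shape[0]

    def z_of(mu, key):
        eps = noise.get(key)
        return mu if eps is None else mu + eps

    enc_a_in = np.concatenate([xa_t, xa_t1], axis=0) if temporal else xa_t
    enc_b_in = np.concatenate([xb_t, xb_t1], axis=0) if temporal else xb_t
    mu_a_all = encode(params, gen_spec, enc_a_in, "A")
    mu_b_all = encode(params, gen_spec, enc_b_in, "B")
    mu_a, mu_a1 = mu_a_all[:n], mu_a_all[n:]
    mu_b, mu_b1 = mu_b_all[:n], mu_b_all[n:]

    terms = {"vae_kl_A": np.mean(mu_a ** 2), "vae_kl_B": np.mean(mu_b ** 2)}
    z_a, z_b = z_of(mu_a, "eps_a"), z_of(mu_b, "eps_b")
    dec_a_in = [z_a, z_b]
    dec_b_in = [z_b, z_a]
    if temporal:
        dec_a_in.append(z_of(mu_b1, "eps_b"))
        dec_b_in.append(z_of(mu_a1, "eps_a"))
    dec_a = decode(params, gen_spec, np.concatenate(dec_a_in, axis=0), "A")
    dec_b = decode(params, gen_spec, np.concatenate(dec_b_in, axis=0), "B")
    x_aa, x_ba = dec_a[:n], dec_a[n:2 * n]
    x_bb, x_ab = dec_b[:n], dec_b[n:2 * n]
    terms["vae_rec_A"] = np.mean(np.abs(x_aa - xa_t))
    terms["vae_rec_B"] = np.mean(np.abs(x_bb - xb_t))
    terms["gan_B"] = _gan_generator_term(params, disc_spec, x_ab, "B")
    terms["gan_A"] = _gan_generator_term(params, disc_spec, x_ba, "A")
    mu_ab = encode(params, gen_spec, x_ab, "B")
    mu_ba = encode(params, gen_spec, x_ba, "A")
    terms["cyc_kl_A"] = np.mean(mu_ab ** 2)
    terms["cyc_kl_B"] = np.mean(mu_ba ** 2)
    x_aba = decode(params, gen_spec, z_of(mu_ab, "eps_ab"), "A")
    x_bab = decode(params, gen_spec, z_of(mu_ba, "eps_ba"), "B")
    terms["cyc_rec_A"] = np.mean(np.abs(x_aba - xa_t))
    terms["cyc_rec_B"] = np.mean(np.abs(x_bab - xb_t))

    if temporal:
        b_hat_t, b_hat_t1 = x_ab, dec_b[2 * n:]
        a_hat_t, a_hat_t1 = x_ba, dec_a[2 * n:]
        f_hat_b = mt_forward(params, mt_spec, xa_t, xa_t1, b_hat_t, fa,
                             "A->B")
        f_hat_a = mt_forward(params, mt_spec, xb_t, xb_t1, a_hat_t, fb,
                             "B->A")
        terms["mt_A"] = motion_cycle_loss(
            b_hat_t, b_hat_t1, f_hat_b, delta_mt=1.0, norm=norm,
            stop_warped_frame=stop_warped_frame)
        terms["mt_B"] = motion_cycle_loss(
            a_hat_t, a_hat_t1, f_hat_a, delta_mt=1.0, norm=norm,
            stop_warped_frame=stop_warped_frame)
        terms["msssim_A"] = structural_consistency_loss(
            b_hat_t, f_hat_b, delta_ssim=1.0, n_scales=msssim_scales)
        terms["msssim_B"] = structural_consistency_loss(
            a_hat_t, f_hat_a, delta_ssim=1.0, n_scales=msssim_scales)
    return terms


def backbone_weight_map(weights: LossWeights) -> dict:
    return {
        "gan_B": weights.lambda0, "gan_A": weights.lambda5,
        "vae_kl_A": weights.lambda1, "vae_kl_B": weights.lambda1,
        "vae_rec_A": weights.lambda2, "vae_rec_B": weights.lambda2,
        "cyc_kl_A": weights.lambda3, "cyc_kl_B": weights.lambda3,
        "cyc_rec_A": weights.lambda4, "cyc_rec_B": weights.lambda4,
        "mt_A": weights.delta_mt, "mt_B": weights.delta_mt,
        "msssim_A": weights.delta_ssim, "msssim_B": weights.delta_ssim,
    }


def backbone_losses(bundle: ModelBundle, batch_A, batch_B,
                    weights: Optional[LossWeights] = None,
                    rng=None) -> LossReport:
    """Evaluate the backbone objective on [0,1] NCHW (or T×H×W×C) batches."""
    weights = weights or LossWeights()
    xa = _as_nchw(onp.asarray(batch_A, dtype=nn.DTYPE))
    xb = _as_nchw(onp.asarray(batch_B, dtype=nn.DTYPE))
    if xa.shape != xb.shape:
        raise ValueError("batches must share a shape")
    noise = None
    if rng is not None:
        mu = encode(bundle.params, bundle.gen_spec, xa, "A")
        noise = {k: rng.standard_normal(mu.shape).astype(nn.DTYPE)
                 for k in ("eps_a", "eps_b", "eps_ab", "eps_ba")}
    terms, _ = backbone_terms(bundle.params, bundle.gen_spec,
                              bundle.disc_spec, xa, xb, noise)
    return LossReport.build({k: float(v) for k, v in terms.items()},
                            backbone_weight_map(weights))
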