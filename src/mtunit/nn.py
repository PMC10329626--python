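"""Minimal differentiable building blocks on top of ``autograd``.

All tensors are numpy arrays in NCHW layout (batch, channels, height, width),
float32 by default.  Model parameters live in flat ``dict[str, ndarray]``
containers; autograd differentiates straight through the dict, so a "module"
here is just a pure function ``(params, x) -> y`` plus an initializer that
fills the dict.

Only what the translation networks need is implemented: 2-d convolution
(direct accumulation over kernel offsets, which autograd differentiates via
fast slice/tensordot VJPs), nearest-neighbour upsampling, average pooling,
instance normalisation, the usual activations, a ``stop_gradient`` primitive
and a bilinear warp primitive with hand-written VJPs for both the image and
the flow field.
"""

from __future__ import annotations

import numpy as onp

import autograd.numpy as np
from autograd.extend import defvjp, primitive

DTYPE = onp.float32


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

@primitive
def stop_gradient(x):
    """Identity whose gradient is exactly zero (the ``sg`` operator)."""
    return x


defvjp(stop_gradient, lambda ans, x: lambda g: onp.zeros_like(x))


def _warp_parts(frame, flow):
    """Shared forward computation for the warp primitive and its VJPs."""
    n, c, h, w = frame.shape
    ys, xs = onp.meshgrid(onp.arange(h), onp.arange(w), indexing="ij")
    gx = xs[None] + flow[:, 0]
    gy = ys[None] + flow[:, 1]
    # border clamp; remember where the clamp was active so flow gradients
    # vanish outside the image (matches a clipped sampling grid)
    in_x = (gx > 0.0) & (gx < w - 1.0)
    in_y = (gy > 0.0) & (gy < h - 1.0)
    gx = onp.clip(gx, 0.0, w - 1.0)
    gy = onp.clip(gy, 0.0, h - 1.0)
    x0 = onp.floor(gx).astype(onp.int64)
    y0 = onp.floor(gy).astype(onp.int64)
    x1 = onp.minimum(x0 + 1, w - 1)
    y1 = onp.minimum(y0 + 1, h - 1)
    fx = (gx - x0).astype(frame.dtype)
    fy = (gy - y0).astype(frame.dtype)
    flat = frame.reshape(n, c, h * w)

    def gather(yy, xx):
        idx = (yy * w + xx).reshape(n, 1, h * w)
        return onp.take_along_axis(flat, idx, axis=2).reshape(n, c, h, w)

    i00, i01 = gather(y0, x0), gather(y0, x1)
    i10, i11 = gather(y1, x0), gather(y1, x1)
    fx_, fy_ = fx[:, None], fy[:, None]
    out = ((1 - fy_) * ((1 - fx_) * i00 + fx_ * i01)
           + fy_ * ((1 - fx_) * i10 + fx_ * i11))
    return out, (y0, x0, y1, x1, fx, fy, in_x, in_y, i00, i01, i10, i11)


@primitive
def warp_bilinear(frame, flow):
    """Backward-warp ``frame`` (N,C,H,W) by ``flow`` (N,2,H,W).

    ``out[n, :, y, x]`` is the bilinear sample of ``frame`` at
    ``(x + flow[n,0,y,x], y + flow[n,1,y,x])`` with border clamping.
    Exact identity (bit-equal) for zero flow.
    """
    out, _ = _warp_parts(onp.asarray(frame), onp.asarray(flow))
    return out


def _warp_vjp_frame(ans, frame, flow):
    frame = onp.asarray(frame)
    flow = onp.asarray(flow)
    _, (y0, x0, y1, x1, fx, fy, *_rest) = _warp_parts(frame, flow)
    n, c, h, w = frame.shape

    def vjp(g):
        # scatter-add via bincount on flattened (n, c, pixel) indices
        base = (onp.arange(n * c) * (h * w)).reshape(n, c, 1, 1)
        fx_, fy_ = fx[:, None], fy[:, None]
        out = onp.zeros(n * c * h * w, dtype=onp.float64)
        for yy, xx, wgt in (
            (y0, x0, (1 - fy_) * (1 - fx_)),
            (y0, x1, (1 - fy_) * fx_),
            (y1, x0, fy_ * (1 - fx_)),
            (y1, x1, fy_ * fx_),
        ):
            idx = base + (yy * w + xx)[:, None]
            out += onp.bincount(idx.ravel(), weights=(g * wgt).ravel(),
                                minlength=n * c * h * w)
        return out.reshape(frame.shape).astype(frame.dtype)

    return vjp


def _warp_vjp_flow(ans, frame, flow):
    frame = onp.asarray(frame)
    flow = onp.asarray(flow)
    _, (y0, x0, y1, x1, fx, fy, in_x, in_y, i00, i01, i10, i11) = _warp_parts(
        frame, flow)

    def vjp(g):
        fx_, fy_ = fx[:, None], fy[:, None]
        dfx = (1 - fy_) * (i01 - i00) + fy_ * (i11 - i10)
        dfy = (1 - fx_) * (i10 - i00) + fx_ * (i11 - i01)
        gx = (g * dfx).sum(axis=1) * in_x
        gy = (g * dfy).sum(axis=1) * in_y
        return onp.stack([gx, gy], axis=1).astype(flow.dtype)

    return vjp


defvjp(warp_bilinear, _warp_vjp_frame, _warp_vjp_flow)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def pad2d(x, p):
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="constant")


def _im2col(x, kh, kw, stride):
    """Padded (N,C,H,W) -> (C·kh·kw, N·oh·ow) patch matrix (one copy)."""
    from numpy.lib.stride_tricks import sliding_window_view

    n, c = x.shape[0], x.shape[1]
    v = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = v.shape[2], v.shape[3]
    col = v.transpose(1, 4, 5, 0, 2, 3).reshape(c * kh * kw, n * oh * ow)
    return onp.ascontiguousarray(col), oh, ow


def _conv_forward(x, w, stride, pad):
    if pad:
        x = onp.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    o, c, kh, kw = w.shape
    col, oh, ow = _im2col(x, kh, kw, stride)
    out = (w.reshape(o, c * kh * kw) @ col).reshape(o, x.shape[0], oh, ow)
    return out.swapaxes(0, 1), col


@primitive
def conv2d_raw(x, w, stride=1, pad=0):
    """2-d cross-correlation, x (N,C,H,W), w (O,C,kh,kw); custom VJPs."""
    out, _ = _conv_forward(onp.asarray(x), onp.asarray(w), stride, pad)
    return out


def _g_mat(g, o):
    return onp.ascontiguousarray(g.swapaxes(0, 1)).reshape(o, -1)


def _conv_vjp_x(ans, x, w, stride=1, pad=0):
    # input gradient as a transposed convolution: correlate the (dilated)
    # output gradient with the flipped, channel-transposed kernel
    w = onp.asarray(w)
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    wt = onp.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    hp, wp = h + 2 * pad, wd + 2 * pad

    def vjp(g):
        if stride > 1:
            oh, ow = g.shape[2], g.shape[3]
            gd = onp.zeros((n, o, (oh - 1) * stride + 1,
                            (ow - 1) * stride + 1), dtype=g.dtype)
            gd[:, :, ::stride, ::stride] = g
            g = gd
        full, _ = _conv_forward(g, wt, 1, pad=max(kh, kw) - 1)
        if full.shape[2] < hp or full.shape[3] < wp:
            gx = onp.zeros((n, c, hp, wp), dtype=full.dtype)
            gx[:, :, :full.shape[2], :full.shape[3]] = full
        else:
            gx = full
        return gx[:, :, pad:pad + h, pad:pad + wd]

    return vjp


def _conv_vjp_w(ans, x, w, stride=1, pad=0):
    x = onp.asarray(x)
    if pad:
        x = onp.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    o, c, kh, kw = onp.shape(w)
    col, _, _ = _im2col(x, kh, kw, stride)  # recomputed; forward buffer freed

    def vjp(g):
        return (_g_mat(g, o) @ col.T).reshape(o, c, kh, kw)

    return vjp


defvjp(conv2d_raw, _conv_vjp_x, _conv_vjp_w)


def conv2d(x, w, b=None, stride=1, pad=0):
    """2-d convolution (cross-correlation), x (N,C,H,W), w (O,C,kh,kw)."""
    out = conv2d_raw(x, w, stride, pad)
    if b is not None:
        out = out + b[None, :, None, None]
    return out


@primitive
def gauss_blur_valid(x, kernel):
    """Separable valid-mode Gaussian blur of an (N,C,H,W) batch.

    ``kernel`` is the 1-d window; output spatial size shrinks by
    ``len(kernel) - 1`` per axis.
    """
    from scipy.ndimage import correlate1d

    x = onp.asarray(x)
    r = (len(kernel) - 1) // 2
    out = correlate1d(x, kernel, axis=2, mode="constant")
    out = correlate1d(out, kernel, axis=3, mode="constant")
    return out[:, :, r:x.shape[2] - r, r:x.shape[3] - r]


def _blur_vjp_x(ans, x, kernel):
    from scipy.ndimage import correlate1d

    r = (len(kernel) - 1) // 2
    h, w = onp.shape(x)[2], onp.shape(x)[3]

    def vjp(g):
        # adjoint of valid correlation with a symmetric kernel is the
        # zero-padded ("full") correlation with the same kernel
        gp = onp.zeros(onp.shape(x), dtype=g.dtype)
        gp[:, :, r:h - r, r:w - r] = g
        out = correlate1d(gp, kernel, axis=2, mode="constant")
        out = correlate1d(out, kernel, axis=3, mode="constant")
        return out

    return vjp


defvjp(gauss_blur_valid, _blur_vjp_x)


def upsample2(x):
    """Nearest-neighbour 2x upsampling."""
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def avg_pool2(x):
    n, c, h, w = x.shape
    x = x[:, :, :h - h % 2, :w - w % 2]
    h2, w2 = x.shape[2] // 2, x.shape[3] // 2
    return np.reshape(x, (n, c, h2, 2, w2, 2)).mean(axis=(3, 5))


@primitive
def leaky_relu(x, slope=0.2):
    x = onp.asarray(x)
    return onp.where(x > 0, x, slope * x)


defvjp(leaky_relu,
       lambda ans, x, slope=0.2:
       lambda g: g * onp.where(onp.asarray(x) > 0, 1.0, slope)
       .astype(onp.asarray(x).dtype))


def relu(x):
    return leaky_relu(x, 0.0)


def tanh(x):
    return np.tanh(x)


@primitive
def instance_norm(x, eps=1e-5):
    """Per-sample, per-channel spatial normalisation (no affine terms)."""
    x = onp.asarray(x)
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
    return (x - mu) / onp.sqrt(var + eps)


def _instance_norm_vjp(ans, x, eps=1e-5):
    x = onp.asarray(x)
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
    inv = 1.0 / onp.sqrt(var + eps)

    def vjp(g):
        g_mean = g.mean(axis=(2, 3), keepdims=True)
        gy_mean = (g * ans).mean(axis=(2, 3), keepdims=True)
        return (inv * (g - g_mean - ans * gy_mean)).astype(x.dtype)

    return vjp


defvjp(instance_norm, _instance_norm_vjp)


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def xavier_conv(rng, out_ch, in_ch, kh, kw):
    """Xavier/Glorot normal initialisation for a conv kernel."""
    fan_in = in_ch * kh * kw
    fan_out = out_ch * kh * kw
    std = onp.sqrt(2.0 / (fan_in + fan_out))
    return (rng.normal(0.0, std, size=(out_ch, in_ch, kh, kw))
            .astype(DTYPE))


def add_conv(params, rng, name, out_ch, in_ch, k, zero=False):
    if zero:
        params[name + ".w"] = onp.zeros((out_ch, in_ch, k, k), dtype=DTYPE)
    else:
        params[name + ".w"] = xavier_conv(rng, out_ch, in_ch, k, k)
    params[name + ".b"] = onp.zeros(out_ch, dtype=DTYPE)
    return params


def apply_conv(params, name, x, stride=1, pad=0):
    return conv2d(x, params[name + ".w"], params[name + ".b"],
                  stride=stride, pad=pad)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with classic (coupled) L2 weight decay added to the gradient."""

    def __init__(self, keys, lr=2e-4, betas=(0.5, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: None for k in keys}
        self.v = {k: None for k in keys}

    def step(self, params, grads, lr=None):
        """In-place update of ``params`` from ``grads`` (both dicts)."""
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k in self.m:
            g = onp.asarray(grads[k], dtype=DTYPE)
            if self.weight_decay:
                g = g + self.weight_decay * params[k]
            if self.m[k] is None:
                self.m[k] = onp.zeros_like(params[k])
                self.v[k] = onp.zeros_like(params[k])
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] = params[k] - lr * mhat / (onp.sqrt(vhat) + self.eps)

    def state_dict(self):
        return {"t": self.t,
                "m": {k: v for k, v in self.m.items()},
                "v": {k: v for k, v in self.v.items()}}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = dict(state["m"])
        self.v = dict(state["v"])
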