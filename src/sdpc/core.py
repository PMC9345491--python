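"""Two-layer convolutional sparse-coding network with predictive-coding feedback.

The generative model reads, for an input image ``x``:

    x        = W_S^T gamma_S + eps_S
    p(gamma_S) = W_C^T gamma_C + eps_C

where ``W_S`` (first layer, "simple" cells) and ``W_C`` (second layer,
"complex" cells) are banks of unit-norm convolution kernels, ``W^T`` denotes
the transpose convolution that synthesises a map from sparse coefficients,
and ``p`` is a max-pooling operator (see :mod:`sdpc.pooling`).  Neural
responses ``gamma`` are inferred by minimising

    F = 1/2 ||eps_S||^2 + 1/2 ||eps_C||^2 + lam_S ||gamma_S||_1 + lam_C ||gamma_C||_1

with proximal gradient (ISTA) steps under a non-negativity constraint.  The
feedback term of the first-layer update routes the second-layer prediction
error back through the recorded pooling argmax switches (unpooling), which
approximates the derivative of the max operation.  Kernels are learned by
gradient steps on F with momentum, followed by renormalisation of every
kernel to unit Euclidean norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view

from .pooling import PoolAssignment, PoolingSpec, PoolStage, compose_pooling, unpool


class ConvergenceError(RuntimeError):
    """Raised when the inference loop diverges (loss rising persistently)."""


# ---------------------------------------------------------------------------
# configuration containers


@dataclass(frozen=True)
class LayerSpec:
    """One convolutional layer: number of kernels, geometry and sparsity target."""

    n_units: int
    kernel_size: int
    stride: int = 1
    sparsity: float = 0.1          # final lambda after the ramp
    padding: int = 0

    def __post_init__(self):
        if self.n_units < 1 or self.kernel_size < 1 or self.stride < 1:
            raise ValueError("n_units, kernel_size and stride must be >= 1")
        if self.sparsity < 0 or self.padding < 0:
            raise ValueError("sparsity and padding must be nonnegative")


@dataclass(frozen=True)
class NetworkConfig:
    """Full architecture + optimisation settings of a two-layer network."""

    layers: tuple[LayerSpec, ...]
    pooling: PoolingSpec
    inference_step: float | str = "auto"    # eta, or "auto" = 0.9 / L per layer
    inference_max_iters: int = 200
    inference_tol: float = 1e-4
    learning_rate: float = 0.01             # omega
    momentum: float = 0.9                   # beta
    lambda_ramp_frac: float = 0.5           # linear ramp over this fraction of training
    feedback_enabled: bool = True
    seed: int = 0
    n_iterations: int = 28125
    batch_size: int = 32

    def __post_init__(self):
        if self.inference_step != "auto" and not float(self.inference_step) > 0:
            raise ValueError("inference_step must be positive or 'auto'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")

    @property
    def lambdas(self) -> tuple[float, ...]:
        return tuple(l.sparsity for l in self.layers)

    def to_dict(self) -> dict:
        d = {
            "layers": [vars(l).copy() for l in self.layers],
            "pooling": self.pooling.to_dict(),
        }
        for k in ("inference_step", "inference_max_iters", "inference_tol",
                  "learning_rate", "momentum", "lambda_ramp_frac",
                  "feedback_enabled", "seed", "n_iterations", "batch_size"):
            d[k] = getattr(self, k)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        layers = tuple(LayerSpec(**l) for l in d.pop("layers"))
        pooling = PoolingSpec.from_dict(d.pop("pooling"))
        return cls(layers=layers, pooling=pooling, **d)


def reference_config(m_s: int = 100, m_c: int = 100, pooling_variant: str = "spatial_2d+feature_2d",
                 **overrides) -> NetworkConfig:
    """The reference architecture: 7x7 stride-1 first layer, 4x4 stride-1 second
    layer, 2x2/2 spatial pooling, lambda ramped to 0.1, omega 0.01, momentum 0.9."""
    defaults = dict(
        layers=(LayerSpec(m_s, 7, 1, 0.1), LayerSpec(m_c, 4, 1, 0.1)),
        pooling=PoolingSpec.from_name(pooling_variant),
        learning_rate=0.01, momentum=0.9,
    )
    defaults.update(overrides)
    return NetworkConfig(**defaults)


@dataclass
class Dictionary:
    """A bank of convolution kernels [n_units, in_channels, k, k] for one layer."""

    kernels: np.ndarray
    layer_index: int = 0

    def __post_init__(self):
        self.kernels = np.asarray(self.kernels, dtype=np.float64)
        if self.kernels.ndim != 4:
            raise ValueError("kernels must be [n_units, in_channels, k, k]")
        if not np.all(np.isfinite(self.kernels)):
            raise ValueError("kernels contain non-finite values")

    @property
    def n_units(self) -> int:
        return self.kernels.shape[0]

    def norms(self) -> np.ndarray:
        return np.sqrt((self.kernels ** 2).sum(axis=(1, 2, 3)))

    def normalized(self) -> "Dictionary":
        n = self.norms()
        out = self.kernels / np.where(n > 0, n, 1.0)[:, None, None, None]
        return Dictionary(out, self.layer_index)

    @classmethod
    def random(cls, n_units: int, in_channels: int, kernel_size: int,
               rng: np.random.Generator, layer_index: int = 0) -> "Dictionary":
        k = rng.standard_normal((n_units, in_channels, kernel_size, kernel_size))
        return cls(k, layer_index).normalized()


@dataclass
class ActivityState:
    """Inferred responses and prediction errors for one batch."""

    gamma: list[np.ndarray]            # [gamma_S, gamma_C], each [B, M, h, w], >= 0
    errors: list[np.ndarray]           # [eps_S, eps_C]
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    assignment: PoolAssignment | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.loss_trace)

    def sparsity_fractions(self) -> list[float]:
        return [float(np.mean(g == 0)) for g in self.gamma]


@dataclass
class TrainingTrace:
    """Per-iteration log of the training loop."""

    iteration: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    err_energy_s: list[float] = field(default_factory=list)
    err_energy_c: list[float] = field(default_factory=list)
    sparsity_s: list[float] = field(default_factory=list)
    sparsity_c: list[float] = field(default_factory=list)
    lambda_s: list[float] = field(default_factory=list)
    lambda_c: list[float] = field(default_factory=list)

    def append(self, it, loss, es, ec, ss, sc, ls, lc):
        self.iteration.append(it)
        self.loss.append(float(loss))
        self.err_energy_s.append(float(es))
        self.err_energy_c.append(float(ec))
        self.sparsity_s.append(float(ss))
        self.sparsity_c.append(float(sc))
        self.lambda_s.append(float(ls))
        self.lambda_c.append(float(lc))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(vars(self))


# ---------------------------------------------------------------------------
# convolution primitives (im2col + BLAS)


def correlate(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of [B, C, H, W] with [M, C, k, k] -> [B, M, H', W']."""
    b, c, h, w = x.shape
    m, ck, k, _ = kernels.shape
    if ck != c:
        raise ValueError(f"channel mismatch: input {c} vs kernels {ck}")
    if h < k or w < k:
        raise ValueError(f"input {h}x{w} smaller than kernel {k}")
    win = sliding_window_view(x, (k, k), axis=(2, 3))          # [B,C,H',W',k,k]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    out = cols @ kernels.reshape(m, -1).T
    return out.reshape(b, ho, wo, m).transpose(0, 3, 1, 2)


def conv_transpose(gamma: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Transpose convolution (stride 1): [B, M, h, w] x [M, C, k, k] -> [B, C, h+k-1, w+k-1].

    This is the synthesis operator of the generative model, the adjoint of
    :func:`correlate`.
    """
    k = kernels.shape[-1]
    gp = np.pad(gamma, ((0, 0), (0, 0), (k - 1, k - 1), (k - 1, k - 1)))
    flipped = kernels[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # [C, M, k, k]
    return correlate(gp, np.ascontiguousarray(flipped))


def kernel_gradient(gamma: np.ndarray, err: np.ndarray, kernel_size: int) -> np.ndarray:
    """Correlation of responses with errors: d(1/2||err||^2)/dW for err = t - W^T gamma
    is minus this quantity.  Shapes [B, M, h, w] x [B, C, H, W] -> [M, C, k, k]."""
    b, m, h, w = gamma.shape
    c = err.shape[1]
    k = kernel_size
    win = sliding_window_view(err, (k, k), axis=(2, 3))        # [B,C,h,w,k,k]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
    gmat = gamma.transpose(0, 2, 3, 1).reshape(b * h * w, m)
    return (gmat.T @ cols).reshape(m, c, k, k)


# ---------------------------------------------------------------------------
# model operations


def fft_correlate(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """FFT-based valid cross-correlation; numerically equivalent to :func:`correlate`."""
    _, _, h, w = x.shape
    k = kernels.shape[-1]
    fx = sfft.rfft2(x)
    fk = np.conj(sfft.rfft2(kernels, s=(h, w)))
    prod = np.matmul(fx.transpose(2, 3, 0, 1), fk.transpose(2, 3, 1, 0))
    out = sfft.irfft2(prod.transpose(2, 3, 0, 1), s=(h, w))
    return out[:, :, :h - k + 1, :w - k + 1]


def fft_conv_transpose(gamma: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """FFT-based transpose convolution; equivalent to :func:`conv_transpose`."""
    _, _, h, w = gamma.shape
    k = kernels.shape[-1]
    s = (h + k - 1, w + k - 1)
    fg = sfft.rfft2(gamma, s=s)
    fk = sfft.rfft2(kernels.astype(gamma.dtype, copy=False), s=s)
    if fg.dtype != fk.dtype:
        fk = fk.astype(fg.dtype)
    prod = np.matmul(fg.transpose(2, 3, 0, 1), fk.transpose(2, 3, 0, 1))
    return sfft.irfft2(prod.transpose(2, 3, 0, 1), s=s)


def fft_kernel_gradient(gamma: np.ndarray, err: np.ndarray, kernel_size: int) -> np.ndarray:
    """FFT-based response/error correlation; equivalent to :func:`kernel_gradient`."""
    h, w = err.shape[-2:]
    fg = np.conj(sfft.rfft2(gamma, s=(h, w)))
    fe = sfft.rfft2(err)
    prod = np.matmul(fg.transpose(2, 3, 1, 0), fe.transpose(2, 3, 0, 1))
    out = sfft.irfft2(prod.transpose(2, 3, 0, 1), s=(h, w))
    return out[:, :, :kernel_size, :kernel_size]


class _ConvPlan:
    """Cached kernel FFTs for repeated correlate/conv_transpose calls during
    inference, where the dictionary is fixed but the signal changes."""

    def __init__(self, kernels: np.ndarray, signal_hw: tuple[int, int],
                 dtype=np.float64):
        self.k = kernels.shape[-1]
        self.h, self.w = signal_hw                      # size of the synthesised map
        self.gh, self.gw = self.h - self.k + 1, self.w - self.k + 1
        cdtype = np.complex64 if np.dtype(dtype) == np.float32 else np.complex128
        fk = sfft.rfft2(kernels.astype(dtype), s=(self.h, self.w)).astype(cdtype)
        self.fk_corr = np.ascontiguousarray(np.conj(fk).transpose(2, 3, 1, 0))
        self.fk_ct = np.ascontiguousarray(fk.transpose(2, 3, 0, 1))

    def correlate(self, x: np.ndarray) -> np.ndarray:
        fx = sfft.rfft2(x)
        prod = np.matmul(fx.transpose(2, 3, 0, 1), self.fk_corr)
        out = sfft.irfft2(prod.transpose(2, 3, 0, 1), s=(self.h, self.w))
        return out[:, :, :self.gh, :self.gw]

    def conv_transpose(self, gamma: np.ndarray) -> np.ndarray:
        fg = sfft.rfft2(gamma, s=(self.h, self.w))
        prod = np.matmul(fg.transpose(2, 3, 0, 1), self.fk_ct)
        return sfft.irfft2(prod.transpose(2, 3, 0, 1), s=(self.h, self.w))


def soft_threshold(x: np.ndarray, threshold: float) -> np.ndarray:
    """Non-negative soft thresholding: max(x - threshold, 0) elementwise."""
    if threshold < 0:
        raise ValueError(f"threshold must be nonnegative, got {threshold}")
    return np.maximum(np.asarray(x) - threshold, 0.0)


def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.dtype != np.float32:   # float32 inputs keep the fast single-precision path
        x = x.astype(np.float64)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4:
        raise ValueError("image input must be [H,W], [B,H,W] or [B,C,H,W]")
    return x


def resolve_pooling(spec: PoolingSpec, gamma_hw: tuple[int, int]) -> PoolingSpec:
    """Concretise the spatial padding of a pooling spec for a given first-layer
    map size: the smallest symmetric zero padding making the strided window
    arithmetic exact."""
    stages = []
    for s in spec.stages:
        if s.kind == "spatial_2d":
            pad = s.pad
            h = min(gamma_hw)
            while (h + 2 * pad - s.kernel) % s.stride or (h + 2 * pad) < s.kernel:
                pad += 1
            stages.append(PoolStage(s.kind, s.kernel, s.stride, pad))
        else:
            stages.append(s)
    return PoolingSpec(tuple(stages))


def compute_loss(x: np.ndarray, dicts: list[Dictionary], state: ActivityState,
                 pooling: PoolingSpec, lambdas) -> float:
    """Evaluate F = 1/2||eps_S||^2 + 1/2||eps_C||^2 + lam_S||gamma_S||_1 + lam_C||gamma_C||_1
    from scratch (errors recomputed from their definitions)."""
    x = _as_batch(x)
    lam = list(lambdas)
    if any(l < 0 for l in lam):
        raise ValueError("lambdas must be nonnegative")
    g_s = state.gamma[0]
    recon = conv_transpose(g_s, dicts[0].kernels)
    if recon.shape != x.shape:
        raise ValueError(f"shape mismatch: reconstruction {recon.shape} vs input {x.shape}")
    eps_s = x - recon
    loss = 0.5 * float(np.sum(eps_s ** 2)) + lam[0] * float(np.sum(np.abs(g_s)))
    if len(state.gamma) > 1 and dicts[1] is not None:
        spec = resolve_pooling(pooling, g_s.shape[-2:])
        pooled, _ = compose_pooling(spec, g_s)
        eps_c = pooled - conv_transpose(state.gamma[1], dicts[1].kernels)
        loss += 0.5 * float(np.sum(eps_c ** 2)) + lam[1] * float(np.sum(np.abs(state.gamma[1])))
    return loss


def estimate_lipschitz(dictionary: Dictionary, spatial_shape: tuple[int, int],
                       n_iter: int = 20, seed: int = 0) -> float:
    """Squared spectral norm of the convolutional synthesis operator, by power
    iteration on W W^T acting on a coefficient map of the given spatial size."""
    rng = np.random.default_rng(seed)
    m = dictionary.n_units
    k = dictionary.kernels.shape[-1]
    plan = _ConvPlan(dictionary.kernels, (spatial_shape[0] + k - 1, spatial_shape[1] + k - 1))
    v = rng.standard_normal((1, m, *spatial_shape))
    v /= np.linalg.norm(v)
    lam = 1.0
    for _ in range(n_iter):
        u = plan.conv_transpose(v)
        v = plan.correlate(u)
        lam = np.linalg.norm(v)
        if lam == 0:
            return 1.0
        v /= lam
    return float(lam)


def _step_sizes(config: NetworkConfig, dicts, gamma_s_hw, gamma_c_hw) -> tuple[float, float]:
    if config.inference_step != "auto":
        eta = float(config.inference_step)
        return eta, eta
    l_s = estimate_lipschitz(dicts[0], gamma_s_hw)
    l_s += config.pooling.max_overlap()        # the eps_C term seen through the switches
    eta_s = 0.9 / l_s
    if len(dicts) > 1 and dicts[1] is not None:
        eta_c = 0.9 / estimate_lipschitz(dicts[1], gamma_c_hw)
    else:
        eta_c = eta_s
    return eta_s, eta_c


def infer(x: np.ndarray, dicts: list[Dictionary], config: NetworkConfig,
          lambdas=None, step_sizes: tuple[float, float] | None = None,
          monotone: bool | None = None) -> ActivityState:
    """Infer sparse responses gamma_S, gamma_C for a batch of images.

    Alternates non-negative proximal gradient steps per layer, with Nesterov
    acceleration: the first-layer update combines the bottom-up error
    (correlation with eps_S) with top-down feedback, i.e. eps_C routed back
    through the pooling argmax switches; the second-layer update uses eps_C
    only.  Switches are recomputed at every iteration.  Stops when the
    relative loss change drops below ``config.inference_tol`` or after
    ``config.inference_max_iters`` steps.

    With ``monotone`` (the default under the "auto" step rule) every iteration
    is checked against the previous loss and backtracked on any increase, so
    the recorded loss trace is non-increasing.  ``monotone=False`` selects a
    leaner accelerated loop (about half the transforms per iteration) used on
    the training and probing hot paths.
    """
    x = _as_batch(x)
    lam = list(lambdas if lambdas is not None else config.lambdas)
    w_s, w_c = dicts[0].kernels, (dicts[1].kernels if len(dicts) > 1 and dicts[1] is not None else None)
    b = x.shape[0]
    hs = x.shape[-2] - w_s.shape[-1] + 1
    ws_ = x.shape[-1] - w_s.shape[-1] + 1
    spec = resolve_pooling(config.pooling, (hs, ws_))
    pooled_shape = spec.output_shape((dicts[0].n_units, hs, ws_))
    g_s = np.zeros((b, dicts[0].n_units, hs, ws_), dtype=x.dtype)
    two_layer = w_c is not None
    if two_layer:
        hc = pooled_shape[1] - w_c.shape[-1] + 1
        wc_ = pooled_shape[2] - w_c.shape[-1] + 1
        if hc < 1 or wc_ < 1:
            raise ValueError("pooled map too small for the second-layer kernel")
        g_c = np.zeros((b, dicts[1].n_units, hc, wc_), dtype=x.dtype)
    if monotone is None:
        monotone = config.inference_step == "auto"
    if step_sizes is None:
        step_sizes = _step_sizes(config, dicts, (hs, ws_), (hc, wc_) if two_layer else (hs, ws_))
    eta_s, eta_c = step_sizes

    plan_s = _ConvPlan(w_s, x.shape[-2:], dtype=x.dtype)
    plan_c = _ConvPlan(w_c, pooled_shape[1:], dtype=x.dtype) if two_layer else None

    def forward(gs, gc):
        eps_s = x - plan_s.conv_transpose(gs)
        pooled, asg = compose_pooling(spec, gs)
        if two_layer:
            eps_c = pooled - plan_c.conv_transpose(gc)
        else:
            eps_c = np.zeros_like(pooled)
        smooth = 0.5 * float(np.sum(eps_s ** 2)) + 0.5 * float(np.sum(eps_c ** 2))
        return eps_s, eps_c, asg, smooth, pooled

    def total(smooth, gs, gc):
        return smooth + lam[0] * gs.sum() + (lam[1] * gc.sum() if two_layer else 0.0)

    if not monotone:
        # lean accelerated loop: one forward pass per iteration, objective
        # tracked at the extrapolated point (sufficient for the stopping rule)
        g_s_prev = g_s
        g_c_prev = g_c if two_layer else None
        t_mom, prev_obj, rise = 1.0, np.inf, 0
        trace = []
        for it in range(config.inference_max_iters):
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
            beta_f = (t_mom - 1.0) / t_next
            y_s = g_s + beta_f * (g_s - g_s_prev) if it else g_s
            y_c = (g_c + beta_f * (g_c - g_c_prev) if it else g_c) if two_layer else None
            eps_s = x - plan_s.conv_transpose(y_s)
            pooled, asg = compose_pooling(spec, y_s)
            eps_c = (pooled - plan_c.conv_transpose(y_c)) if two_layer else np.zeros_like(pooled)
            obj = (0.5 * float(np.sum(eps_s ** 2)) + 0.5 * float(np.sum(eps_c ** 2))
                   + lam[0] * float(np.abs(y_s).sum())
                   + (lam[1] * float(np.abs(y_c).sum()) if two_layer else 0.0))
            trace.append(obj)
            if not np.isfinite(obj):
                raise ConvergenceError(f"non-finite loss during inference (eta_S={eta_s:.3g})")
            if obj > prev_obj + 1e-12 * max(1.0, abs(prev_obj)):
                rise += 1
                if config.inference_step == "auto":
                    # adaptive restart; if even an unaccelerated step rose, the
                    # Lipschitz estimate is stale -> shorten the steps
                    if t_mom == 1.0:
                        eta_s, eta_c = eta_s / 2, eta_c / 2
                    t_next, beta_f = 1.0, 0.0
                    if rise > 40:
                        raise ConvergenceError(
                            f"inference diverging despite step halving (eta_S={eta_s:.3g})")
                elif rise > 10:
                    raise ConvergenceError(
                        f"inference diverging: loss rose {rise} consecutive iterations "
                        f"(step sizes eta_S={eta_s:.3g}, eta_C={eta_c:.3g})")
            else:
                rise = 0
            grad_s = -plan_s.correlate(eps_s)
            if two_layer and config.feedback_enabled:
                grad_s += unpool(eps_c, asg)
            g_s_prev, g_s = g_s, soft_threshold(y_s - eta_s * grad_s, eta_s * lam[0])
            if two_layer:
                g_c_prev, g_c = g_c, soft_threshold(y_c + eta_c * plan_c.correlate(eps_c),
                                                    eta_c * lam[1])
            t_mom = t_next
            if it and abs(prev_obj - obj) <= config.inference_tol * max(abs(obj), 1e-30):
                break
            prev_obj = obj
        eps_s = x - plan_s.conv_transpose(g_s)
        pooled, asg = compose_pooling(spec, g_s)
        eps_c = (pooled - plan_c.conv_transpose(g_c)) if two_layer else np.zeros_like(pooled)
        trace.append(total(0.5 * float(np.sum(eps_s ** 2)) + 0.5 * float(np.sum(eps_c ** 2)),
                           g_s, g_c if two_layer else g_s))
        return ActivityState(gamma=[g_s, g_c] if two_layer else [g_s],
                             errors=[eps_s, eps_c] if two_layer else [eps_s],
                             loss_trace=np.asarray(trace), assignment=asg)

    def grad_first(eps_s_, eps_c_, asg_):
        g = -plan_s.correlate(eps_s_)
        if two_layer and config.feedback_enabled:
            g += unpool(eps_c_, asg_)
        return g

    trace = []
    eps_s, eps_c, asg, smooth, pooled = forward(g_s, g_c if two_layer else None)
    loss = total(smooth, g_s, g_c if two_layer else g_s)
    g_s_prev, g_c_prev = g_s, (g_c if two_layer else None)
    t_mom = 1.0
    rise_count = 0
    for it in range(config.inference_max_iters):
        trace.append(loss)
        accepted = False
        # accelerated (FISTA) step from the extrapolated point; restart on any
        # loss increase so the trace stays monotone under the auto step rule
        if it > 0 and t_mom > 1.0:
            beta_f = (t_prev - 1.0) / t_mom
            y_s = g_s + beta_f * (g_s - g_s_prev)
            y_c = g_c + beta_f * (g_c - g_c_prev) if two_layer else None
            eps_s_y, eps_c_y, asg_y, _, _ = forward(y_s, y_c)
            cand_s = soft_threshold(y_s - eta_s * grad_first(eps_s_y, eps_c_y, asg_y),
                                    eta_s * lam[0])
            cand_c = (soft_threshold(y_c + eta_c * plan_c.correlate(eps_c_y), eta_c * lam[1])
                      if two_layer else None)
            eps_s_n, eps_c_n, asg_n, smooth_n, pooled_n = forward(cand_s, cand_c)
            cand_loss = total(smooth_n, cand_s, cand_c if two_layer else cand_s)
            if not monotone or cand_loss <= loss + 1e-12 * max(1.0, abs(loss)):
                g_s_prev, g_c_prev = g_s, g_c if two_layer else None
                g_s, eps_s, eps_c, asg, pooled = cand_s, eps_s_n, eps_c_n, asg_n, pooled_n
                if two_layer:
                    g_c = cand_c
                new_loss = cand_loss
                accepted = True
            else:
                t_mom = 1.0      # momentum restart: fall through to a plain step
        if not accepted:
            # sequential proximal steps with per-layer backtracking
            grad_s = grad_first(eps_s, eps_c, asg)
            l1_gc = lam[1] * g_c.sum() if two_layer else 0.0
            eta_local = eta_s
            for attempt in range(13):
                g_s_new = soft_threshold(g_s - eta_local * grad_s, eta_local * lam[0])
                eps_s_n, eps_c_n, asg_n, smooth_n, pooled_n = forward(
                    g_s_new, g_c if two_layer else None)
                l1_new = smooth_n + lam[0] * g_s_new.sum() + l1_gc
                if not monotone or l1_new <= loss + 1e-12 * max(1.0, abs(loss)):
                    break
                if attempt == 11:
                    # the max-pooling switch flip made every step length uphill: stay put
                    g_s_new = g_s
                    eps_s_n, eps_c_n, asg_n, smooth_n, pooled_n = forward(
                        g_s, g_c if two_layer else None)
                    break
                eta_local /= 2  # switch flip broke the fixed-switch descent bound
            g_s_prev, g_c_prev = g_s, g_c if two_layer else None
            g_s, eps_s, eps_c, asg, pooled = g_s_new, eps_s_n, eps_c_n, asg_n, pooled_n
            smooth = smooth_n
            if two_layer:
                loss_mid = total(smooth, g_s, g_c)
                grad_c = plan_c.correlate(eps_c)
                eta_local = eta_c
                for attempt in range(13):
                    g_c_new = soft_threshold(g_c + eta_local * grad_c, eta_local * lam[1])
                    # first-layer state unchanged: refresh only the top-layer error
                    eps_c_n2 = pooled - plan_c.conv_transpose(g_c_new)
                    smooth_n2 = 0.5 * float(np.sum(eps_s ** 2)) + 0.5 * float(np.sum(eps_c_n2 ** 2))
                    l_new = total(smooth_n2, g_s, g_c_new)
                    if not monotone or l_new <= loss_mid + 1e-12 * max(1.0, abs(loss_mid)):
                        break
                    if attempt == 11:
                        g_c_new, eps_c_n2 = g_c, eps_c
                        smooth_n2 = smooth
                        break
                    eta_local /= 2  # stale Lipschitz estimate: shorten the step
                g_c, eps_c, smooth = g_c_new, eps_c_n2, smooth_n2
            new_loss = total(smooth, g_s, g_c if two_layer else g_s)
        t_prev = max(t_mom, 1.0)
        t_mom = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_prev * t_prev))
        if not np.isfinite(new_loss):
            raise ConvergenceError(f"non-finite loss during inference (eta_S={eta_s:.3g})")
        if new_loss > loss + 1e-12 * max(1.0, abs(loss)):
            rise_count += 1
            if rise_count > 10:
                raise ConvergenceError(
                    f"inference diverging: loss rose {rise_count} consecutive iterations "
                    f"(step sizes eta_S={eta_s:.3g}, eta_C={eta_c:.3g})")
        else:
            rise_count = 0
        converged = abs(loss - new_loss) <= config.inference_tol * max(abs(loss), 1e-30)
        loss = new_loss
        if converged:
            break
    trace.append(loss)
    gamma = [g_s, g_c] if two_layer else [g_s]
    errors = [eps_s, eps_c] if two_layer else [eps_s]
    return ActivityState(gamma=gamma, errors=errors, loss_trace=np.asarray(trace),
                         assignment=asg)


def loss_kernel_gradients(x: np.ndarray, dicts: list[Dictionary], state: ActivityState,
                          pooling: PoolingSpec) -> list[np.ndarray]:
    """Exact gradients of the reconstruction loss w.r.t. each kernel bank, at
    fixed responses: dF/dW_i = -(gamma_i correlated with eps_i)."""
    x = _as_batch(x)
    g_s = state.gamma[0]
    eps_s = x - fft_conv_transpose(g_s, dicts[0].kernels)
    grads = [-fft_kernel_gradient(g_s, eps_s, dicts[0].kernels.shape[-1])]
    if len(state.gamma) > 1 and dicts[1] is not None:
        spec = resolve_pooling(pooling, g_s.shape[-2:])
        pooled, _ = compose_pooling(spec, g_s)
        eps_c = pooled - fft_conv_transpose(state.gamma[1], dicts[1].kernels)
        grads.append(-fft_kernel_gradient(state.gamma[1], eps_c, dicts[1].kernels.shape[-1]))
    return grads


def learning_step(dicts: list[Dictionary], state: ActivityState, x: np.ndarray,
                  pooling: PoolingSpec, omega: float, beta: float,
                  velocity: list[np.ndarray]) -> list[Dictionary]:
    """One dictionary update: W <- W + omega * corr(gamma, eps) with momentum,
    gradient averaged over the batch, then every kernel renormalised to unit
    Euclidean norm.  Kernels whose update collapses to zero norm are kept at
    their previous value (flagged as dead)."""
    x = _as_batch(x)
    b = x.shape[0]
    grads = loss_kernel_gradients(x, dicts, state, pooling)
    out = []
    for i, (d, g) in enumerate(zip(dicts, grads)):
        velocity[i] = beta * velocity[i] - (omega / b) * g
        new = d.kernels + velocity[i]
        norms = np.sqrt((new ** 2).sum(axis=(1, 2, 3)))
        dead = norms < 1e-12
        if np.any(dead):
            warnings.warn(f"layer {i}: {int(dead.sum())} dead kernel(s) kept at previous value")
            new[dead] = d.kernels[dead]
            norms = np.sqrt((new ** 2).sum(axis=(1, 2, 3)))
        out.append(Dictionary(new / norms[:, None, None, None], d.layer_index))
    return out


def compute_receptive_field(config: NetworkConfig) -> list[int]:
    """Composite receptive-field side length (input pixels) of a unit in each
    layer, by the standard recursion r <- r + (k - 1) * jump over convolution
    and spatial-pooling stages.  Feature poolings do not change the spatial RF."""
    rf, jump = 1, 1
    out = []
    for i, layer in enumerate(config.layers):
        rf += (layer.kernel_size - 1) * jump
        jump *= layer.stride
        out.append(rf)
        if i == 0:  # the pooling sits between the two convolutional layers
            for s in config.pooling.stages:
                if s.kind == "spatial_2d":
                    rf += (s.kernel - 1) * jump
                    jump *= s.stride
    return out


@dataclass
class SDPCModel:
    """A trained (or initialised) network: dictionaries + configuration + trace."""

    config: NetworkConfig
    dicts: list[Dictionary]
    trace: TrainingTrace | None = None

    def infer(self, x: np.ndarray, inference_max_iters: int | None = None,
              inference_tol: float | None = None,
              monotone: bool | None = None) -> ActivityState:
        cfg = self.config
        if inference_max_iters is not None or inference_tol is not None:
            cfg = replace(cfg,
                          inference_max_iters=inference_max_iters or cfg.inference_max_iters,
                          inference_tol=inference_tol if inference_tol is not None else cfg.inference_tol)
        return infer(x, self.dicts, cfg, monotone=monotone)

    def save(self, path: str) -> None:
        """Persist kernels, config and trace to a single HDF5 container."""
        import json

        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = 1
            f.attrs["config"] = json.dumps(self.config.to_dict())
            for i, d in enumerate(self.dicts):
                f.create_dataset(f"kernels/layer{i}", data=d.kernels)
            if self.trace is not None and self.trace.loss:
                grp = f.create_group("trace")
                for key, vals in vars(self.trace).items():
                    grp.create_dataset(key, data=np.asarray(vals))

    @classmethod
    def load(cls, path: str) -> "SDPCModel":
        import json

        import h5py

        with h5py.File(path, "r") as f:
            if f.attrs.get("schema_version") != 1:
                raise ValueError(f"unsupported model container schema in {path!r}")
            config = NetworkConfig.from_dict(json.loads(f.attrs["config"]))
            dicts = []
            i = 0
            while f"kernels/layer{i}" in f:
                dicts.append(Dictionary(f[f"kernels/layer{i}"][...], i))
                i += 1
            trace = None
            if "trace" in f:
                trace = TrainingTrace()
                for key in vars(trace):
                    setattr(trace, key, list(f["trace"][key][...]))
        return cls(config, dicts, trace)


def lambda_schedule(config: NetworkConfig, iteration: int) -> tuple[float, ...]:
    """Linear ramp of each layer's sparsity penalty from 0 to its target over
    the first ``lambda_ramp_frac`` of training, then constant."""
    ramp_len = max(1, int(config.lambda_ramp_frac * config.n_iterations))
    frac = min(1.0, iteration / ramp_len)
    return tuple(l.sparsity * frac for l in config.layers)


def train(images: np.ndarray, config: NetworkConfig, whitened: bool = True,
          step_refresh: int = 25, callback=None) -> tuple[list[Dictionary], TrainingTrace]:
    """Train the two-layer model on a stack of images [N, H, W] in [-1, 1].

    Loops minibatches (reshuffled each epoch); per batch runs :func:`infer`
    then :func:`learning_step`; the sparsity penalties ramp linearly to their
    targets.  Fully reproducible given ``config.seed``.
    """
    images = np.asarray(images, dtype=np.float32)  # single precision on the training path
    if images.ndim != 3 or images.shape[0] == 0:
        raise ValueError("expected a non-empty image stack [N, H, W]")
    if not whitened:
        warnings.warn("training images are not flagged as whitened; the model "
                      "assumes inputs with flattened low-frequency spectra in [-1, 1]")
    rng = np.random.default_rng(config.seed)
    n = images.shape[0]
    k1 = config.layers[0].kernel_size
    dicts = [Dictionary.random(config.layers[0].n_units, 1, k1, rng, 0)]
    if len(config.layers) > 1:
        dicts.append(Dictionary.random(config.layers[1].n_units, config.layers[0].n_units,
                                       config.layers[1].kernel_size, rng, 1))
    velocity = [np.zeros_like(d.kernels) for d in dicts]
    trace = TrainingTrace()
    order = rng.permutation(n)
    pos = 0
    steps = None
    for it in range(config.n_iterations):
        if pos + config.batch_size > n:
            order = rng.permutation(n)
            pos = 0
        batch = images[order[pos:pos + config.batch_size]]
        pos += config.batch_size
        lam = lambda_schedule(config, it)
        if steps is None or it % step_refresh == 0:
            hs = batch.shape[-2] - k1 + 1
            ws_ = batch.shape[-1] - k1 + 1
            spec = resolve_pooling(config.pooling, (hs, ws_))
            pooled_shape = spec.output_shape((dicts[0].n_units, hs, ws_))
            if len(dicts) > 1:
                hc = pooled_shape[1] - config.layers[1].kernel_size + 1
                steps = _step_sizes(config, dicts, (hs, ws_), (hc, hc))
            else:
                steps = _step_sizes(config, dicts, (hs, ws_), (hs, ws_))
        state = infer(batch, dicts, config, lambdas=lam, step_sizes=steps, monotone=False)
        dicts = learning_step(dicts, state, batch, config.pooling,
                              config.learning_rate, config.momentum, velocity)
        sp = state.sparsity_fractions()
        trace.append(it, state.loss_trace[-1],
                     float(np.sum(state.errors[0] ** 2)),
                     float(np.sum(state.errors[-1] ** 2)) if len(state.errors) > 1 else 0.0,
                     sp[0], sp[1] if len(sp) > 1 else 0.0,
                     lam[0], lam[1] if len(lam) > 1 else 0.0)
        if callback is not None:
            callback(it, dicts, state)
    return dicts, trace
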