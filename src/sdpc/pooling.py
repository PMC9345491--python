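"""Max-pooling operators with argmax switches, and the unpooling feedback route.

Three pooling families act on a nonnegative response map ``gamma`` of shape
``[..., C, H, W]`` (an optional leading batch axis is supported everywhere):

* ``spatial_2d`` — max over non-overlapping (or strided) spatial windows,
  independently per feature channel.  Models invariance over retinotopic
  position.
* ``feature_1d_circular`` — max over a sliding window of adjacent channels
  arranged on a 1-D ring; spatial encoding untouched.
* ``feature_2d_toroidal`` — channels arranged row-major on a sqrt(C) x sqrt(C)
  torus; max over 2-D windows with wraparound, per spatial location.

Every operator records, for each output element, the flat index (into the
``C*H*W``-flattened, zero-padded input) of the winning element.  ``unpool``
routes a pooled-space signal back through those switches, which is the
transpose of the switch-selection linear map and serves as the derivative
approximation of max-pooling used by the inference feedback path.

Ties are broken deterministically by the first index in row-major scan order
(channel-major for the feature poolings).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

KINDS = ("spatial_2d", "feature_1d_circular", "feature_2d_toroidal", "identity")

#: short aliases accepted when parsing pooling variant names
VARIANT_ALIASES = {
    "identity": [],
    "spatial_2d": [("spatial_2d", 2, 2)],
    "feature_1d": [("feature_1d_circular", 4, 1)],
    "feature_2d": [("feature_2d_toroidal", 2, 1)],
    "spatial_2d+feature_1d": [("spatial_2d", 2, 2), ("feature_1d_circular", 4, 1)],
    "spatial_2d+feature_2d": [("spatial_2d", 2, 2), ("feature_2d_toroidal", 2, 1)],
}


@dataclass(frozen=True)
class PoolStage:
    """One pooling stage: kind, window size, stride and zero padding (spatial only)."""

    kind: str
    kernel: int = 2
    stride: int = 1
    pad: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown pooling kind {self.kind!r}; expected one of {KINDS}")
        if self.kernel < 1 or self.stride < 1 or self.pad < 0:
            raise ValueError("kernel and stride must be >= 1, pad >= 0")
        if self.kind != "spatial_2d" and self.pad != 0:
            raise ValueError("padding is only meaningful for spatial_2d stages")


@dataclass(frozen=True)
class PoolingSpec:
    """Ordered sequence of pooling stages applied to the first-layer response."""

    stages: tuple[PoolStage, ...] = ()

    @classmethod
    def from_name(cls, name: str, spatial_pad: int = 0) -> "PoolingSpec":
        """Build a spec from a variant name such as ``"spatial_2d+feature_1d"``.

        ``spatial_pad`` is the symmetric zero padding inserted before the
        spatial stage (used to align receptive fields between layers).
        """
        key = name.strip().lower()
        if key not in VARIANT_ALIASES:
            raise ValueError(f"unknown pooling variant {name!r}; expected one of {sorted(VARIANT_ALIASES)}")
        stages = []
        for kind, kernel, stride in VARIANT_ALIASES[key]:
            pad = spatial_pad if kind == "spatial_2d" else 0
            stages.append(PoolStage(kind, kernel, stride, pad))
        return cls(tuple(stages))

    @property
    def name(self) -> str:
        if not self.stages:
            return "identity"
        short = {"spatial_2d": "spatial_2d", "feature_1d_circular": "feature_1d",
                 "feature_2d_toroidal": "feature_2d", "identity": "identity"}
        return "+".join(short[s.kind] for s in self.stages)

    @property
    def feature_topology(self) -> str:
        """Topology induced on the feature axis: grid_toroidal, ring_circular or none."""
        for s in self.stages:
            if s.kind == "feature_2d_toroidal":
                return "grid_toroidal"
            if s.kind == "feature_1d_circular":
                return "ring_circular"
        return "none"

    def max_overlap(self) -> int:
        """Worst-case number of output elements a single input can win.

        Bounds the spectral norm of the switch-selection map (it is at most
        sqrt of this value squared, i.e. exactly this value for S^T S), which
        enters the inference step-size rule.
        """
        m = 1
        for s in self.stages:
            per_axis = -(-s.kernel // s.stride)  # ceil(kernel / stride)
            if s.kind in ("spatial_2d", "feature_2d_toroidal"):
                m *= per_axis ** 2
            elif s.kind == "feature_1d_circular":
                m *= per_axis
        return m

    def output_shape(self, shape: tuple[int, int, int]) -> tuple[int, int, int]:
        """Shape [C, H, W] of the pooled map for an input of shape [C, H, W]."""
        c, h, w = shape
        for s in self.stages:
            if s.kind == "spatial_2d":
                h = _out_len(h, s.kernel, s.stride, s.pad)
                w = _out_len(w, s.kernel, s.stride, s.pad)
            elif s.kind == "feature_1d_circular":
                c = _circ_out(c, s.kernel, s.stride)
            elif s.kind == "feature_2d_toroidal":
                g = _grid_side(c)
                c = _circ_out(g, s.kernel, s.stride) ** 2
        return c, h, w

    def to_dict(self) -> list[dict]:
        return [{"kind": s.kind, "kernel": s.kernel, "stride": s.stride, "pad": s.pad}
                for s in self.stages]

    @classmethod
    def from_dict(cls, stages: list[dict]) -> "PoolingSpec":
        return cls(tuple(PoolStage(**s) for s in stages))


@dataclass
class StageAssignment:
    """Argmax switches of one stage: winner flat-indices plus shape bookkeeping."""

    kind: str
    input_shape: tuple[int, ...]        # unpadded [C, H, W]
    padded_shape: tuple[int, ...]       # [C, H+2p, W+2p]
    pad: int
    index: np.ndarray                   # [..., C', H', W'] flat winner index into padded input


@dataclass
class PoolAssignment:
    """Per-stage argmax switches recorded during a forward pooling pass."""

    stages: list[StageAssignment] = field(default_factory=list)

    @property
    def input_shape(self) -> tuple[int, ...]:
        return self.stages[0].input_shape if self.stages else ()


def _out_len(n: int, k: int, s: int, p: int) -> int:
    n = n + 2 * p
    if n < k or (n - k) % s:
        raise ValueError(f"spatial extent {n} incompatible with pooling kernel {k} stride {s}")
    return (n - k) // s + 1


def _circ_out(n: int, k: int, s: int) -> int:
    if k > n:
        raise ValueError(f"feature pooling kernel {k} exceeds channel count {n}")
    if n % s:
        raise ValueError(f"channel count {n} not divisible by feature-pool stride {s}")
    return n // s


def _grid_side(c: int) -> int:
    g = int(round(np.sqrt(c)))
    if g * g != c:
        raise ValueError(f"toroidal feature pooling requires a perfect-square channel count, got {c}")
    return g


def _split_batch(gamma: np.ndarray):
    if gamma.ndim == 3:
        return gamma[None], True
    if gamma.ndim == 4:
        return gamma, False
    raise ValueError(f"expected [C,H,W] or [B,C,H,W] activity map, got ndim={gamma.ndim}")


def max_pool_2ds(gamma: np.ndarray, kernel: int = 2, stride: int = 2, pad: int = 0):
    """Spatial max pooling per channel.  Returns (pooled, StageAssignment)."""
    g, squeeze = _split_batch(gamma)
    b, c, h, w = g.shape
    ho, wo = _out_len(h, kernel, stride, pad), _out_len(w, kernel, stride, pad)
    if pad:
        g = np.pad(g, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = h + 2 * pad, w + 2 * pad
    win = sliding_window_view(g, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    win = win.reshape(b, c, ho, wo, kernel * kernel)
    arg = win.argmax(axis=-1)
    pooled = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
    hi = (np.arange(ho) * stride)[None, None, :, None] + arg // kernel
    wi = (np.arange(wo) * stride)[None, None, None, :] + arg % kernel
    flat = (np.arange(c)[None, :, None, None] * hp + hi) * wp + wi
    asg = StageAssignment("spatial_2d", (c, h, w), (c, hp, wp), pad,
                          flat[0] if squeeze else flat)
    return (pooled[0] if squeeze else pooled), asg


def max_pool_1df(gamma: np.ndarray, kernel: int = 4, stride: int = 1):
    """Circular 1-D max pooling across the channel axis; spatial map untouched."""
    g, squeeze = _split_batch(gamma)
    b, c, h, w = g.shape
    co = _circ_out(c, kernel, stride)
    starts = np.arange(co) * stride
    idx = (starts[:, None] + np.arange(kernel)[None, :]) % c      # [co, kernel]
    win = g[:, idx]                                               # [b, co, kernel, h, w]
    arg = win.argmax(axis=2)
    pooled = np.take_along_axis(win, arg[:, :, None], axis=2)[:, :, 0]
    ch = idx[np.arange(co)[None, :, None, None], arg]             # winner channel
    flat = (ch * h + np.arange(h)[None, None, :, None]) * w + np.arange(w)[None, None, None, :]
    asg = StageAssignment("feature_1d_circular", (c, h, w), (c, h, w), 0,
                          flat[0] if squeeze else flat)
    return (pooled[0] if squeeze else pooled), asg


def max_pool_2df(gamma: np.ndarray, kernel: int = 2, stride: int = 1):
    """Toroidal 2-D max pooling over channels arranged row-major on a square grid."""
    g, squeeze = _split_batch(gamma)
    b, c, h, w = g.shape
    side = _grid_side(c)
    so = _circ_out(side, kernel, stride)
    starts = np.arange(so) * stride
    rr = (starts[:, None] + np.arange(kernel)[None, :]) % side    # [so, kernel]
    # window channel indices, row-major within the window -> first-index tie break
    chan = (rr[:, None, :, None] * side + rr[None, :, None, :]).reshape(so, so, kernel * kernel)
    win = g[:, chan]                                              # [b, so, so, k*k, h, w]
    arg = win.argmax(axis=3)
    pooled = np.take_along_axis(win, arg[:, :, :, None], axis=3)[:, :, :, 0]
    ii = np.arange(so).reshape(1, so, 1, 1, 1)
    jj = np.arange(so).reshape(1, 1, so, 1, 1)
    ch = chan[ii, jj, arg]                                        # winner channel
    flat = (ch * h + np.arange(h)[None, None, None, :, None]) * w + np.arange(w)[None, None, None, None, :]
    pooled = pooled.reshape(b, so * so, h, w)
    flat = flat.reshape(b, so * so, h, w)
    asg = StageAssignment("feature_2d_toroidal", (c, h, w), (c, h, w), 0,
                          flat[0] if squeeze else flat)
    return (pooled[0] if squeeze else pooled), asg


_STAGE_FN = {
    "spatial_2d": lambda g, s: max_pool_2ds(g, s.kernel, s.stride, s.pad),
    "feature_1d_circular": lambda g, s: max_pool_1df(g, s.kernel, s.stride),
    "feature_2d_toroidal": lambda g, s: max_pool_2df(g, s.kernel, s.stride),
}


def compose_pooling(spec: PoolingSpec, gamma: np.ndarray):
    """Apply the stages of ``spec`` in order.  Returns (pooled, PoolAssignment)."""
    out = gamma
    assignment = PoolAssignment()
    for i, stage in enumerate(spec.stages):
        if stage.kind == "identity":
            continue
        try:
            out, asg = _STAGE_FN[stage.kind](out, stage)
        except ValueError as e:
            raise ValueError(f"pooling stage {i} ({stage.kind}): {e}") from e
        assignment.stages.append(asg)
    return out, assignment


def _unpool_stage(u: np.ndarray, asg: StageAssignment) -> np.ndarray:
    squeeze = u.ndim == asg.index.ndim == 3
    uu = u[None] if u.ndim == 3 else u
    idx = asg.index[None] if asg.index.ndim == 3 else asg.index
    if uu.shape != idx.shape:
        raise ValueError(f"stale pooling assignment: signal shape {uu.shape} vs switches {idx.shape}")
    b = uu.shape[0]
    size = int(np.prod(asg.padded_shape))
    offsets = (np.arange(b) * size)[:, None, None, None]
    flat = np.bincount((idx + offsets).ravel(), weights=uu.ravel().astype(np.float64),
                       minlength=b * size)
    out = flat.reshape(b, *asg.padded_shape).astype(uu.dtype, copy=False)
    p = asg.pad
    if p:
        out = out[:, :, p:-p, p:-p]
    out = np.ascontiguousarray(out)
    return out[0] if squeeze else out


def unpool(u: np.ndarray, assignment: PoolAssignment) -> np.ndarray:
    """Route a pooled-space signal back to the recorded argmax winners.

    Contributions from overlapping windows (stride-1 feature pooling) are
    summed at the winner, making this the exact transpose of the fixed-switch
    selection map: <pool_lin(g), u> == <g, unpool(u)>.
    """
    out = u
    for asg in reversed(assignment.stages):
        out = _unpool_stage(out, asg)
    return out
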