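"""Input pipeline: retinal-style whitening, synthetic natural-like images, and
sinusoidal grating stimuli for the drifting / rotating probe protocols.

Natural scenes have an amplitude spectrum falling roughly as 1/f.  The
whitening filter ``f * exp(-(f/f_c)^4)`` flattens that spectrum up to a
cutoff ``f_c`` and suppresses the highest frequencies, mimicking the
transfer function of the retina/LGN.  The synthetic generator produces
"dead-leaves"-style composites of randomly oriented bars over 1/f noise so
that the model can be trained and tested without an external photograph
dataset while preserving the two statistics the model relies on: an
approximately 1/f spectrum and sparse oriented edge structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft


@dataclass
class ImageBatch:
    """A stack of grayscale images [n, H, W] plus preprocessing provenance."""

    images: np.ndarray
    whitened: bool = False
    value_range: tuple[float, float] = (-1.0, 1.0)
    edge_orientations: np.ndarray | None = None   # filled by the synthetic generator

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be [n, H, W]")

    def __len__(self) -> int:
        return self.images.shape[0]


@dataclass(frozen=True)
class GratingSpec:
    """A static sinusoidal grating in a circular aperture.

    orientation/phase in degrees, frequency in cycles per pixel; orientation
    is measured counter-clockwise from the horizontal image axis.
    """

    orientation: float = 0.0
    phase: float = 0.0
    frequency: float = 0.1
    size: int = 24
    mask_diameter: float = 14.0
    contrast: float = 1.0


@dataclass
class StimulusSequence:
    """Frames of a drifting (phase sweep) or rotating (orientation sweep) grating."""

    frames: np.ndarray                  # [T, H, W]
    mode: str                           # "drift" | "rotate"
    stimulus_axis: np.ndarray           # phase (deg) or orientation (deg) per frame
    cycle_degrees: float                # 360 for drift, 180 for rotate
    spec: GratingSpec | None = None

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Knobs of the synthetic natural-like image generator."""

    n_images: int = 200
    size: int = 24
    edges_per_image: float = 8.0        # mean number of oriented bars per image
    noise_weight: float = 0.5           # relative amplitude of the 1/f background
    seed: int = 0


def radial_frequency_grid(h: int, w: int) -> np.ndarray:
    """|f| in cycles/pixel on the rfft2 grid of an h x w image."""
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.rfftfreq(w)[None, :]
    return np.hypot(fy, fx)


def whiten(batch: ImageBatch | np.ndarray, cutoff: float = 0.4,
           scale: str = "per_image") -> ImageBatch:
    """Apply the retina-style whitening filter f * exp(-(f/f_c)^4) per image.

    ``cutoff`` sets f_c as a fraction of the Nyquist frequency (0.5
    cycles/pixel).  The DC component is removed (the filter vanishes at
    f = 0) and the output is rescaled into [-1, 1]: with ``scale="per_image"``
    every image is contrast-normalised to the full range (the training
    convention); with ``scale="batch"`` a single factor is used, preserving
    relative amplitudes across images (used for stimulus sequences, where
    frame-to-frame modulation is the measured quantity).
    """
    images = batch.images if isinstance(batch, ImageBatch) else np.asarray(batch, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    n, h, w = images.shape
    if h < 2 or w < 2:
        raise ValueError("cannot whiten images smaller than 2x2 pixels")
    f = radial_frequency_grid(h, w)
    f_c = cutoff * 0.5
    filt = f * np.exp(-((f / f_c) ** 4))
    out = sfft.irfft2(sfft.rfft2(images) * filt[None], s=(h, w))
    if scale == "per_image":
        peak = np.max(np.abs(out), axis=(1, 2), keepdims=True)
    elif scale == "batch":
        peak = np.max(np.abs(out))
    else:
        raise ValueError("scale must be 'per_image' or 'batch'")
    out = out / np.where(peak > 0, peak, 1.0)
    return ImageBatch(out, whitened=True, value_range=(-1.0, 1.0))


def make_grating(spec: GratingSpec) -> np.ndarray:
    """Render cos(2*pi*f0*(x cos(theta) + y sin(theta)) + phi) * contrast inside a
    circular window, zero outside."""
    if spec.frequency > 0.5:
        raise ValueError(f"grating frequency {spec.frequency} exceeds Nyquist (0.5 cycles/px)")
    if spec.frequency <= 0:
        raise ValueError("grating frequency must be positive")
    n = spec.size
    c = (n - 1) / 2.0
    cols, rows = np.meshgrid(np.arange(n), np.arange(n))
    x = cols - c
    y = c - rows                        # y axis points up: theta is CCW from horizontal
    th = np.deg2rad(spec.orientation)
    u = x * np.cos(th) + y * np.sin(th)
    img = spec.contrast * np.cos(2 * np.pi * spec.frequency * u + np.deg2rad(spec.phase))
    mask = (x ** 2 + y ** 2) <= (spec.mask_diameter / 2.0) ** 2
    return np.where(mask, img, 0.0)


def make_drift_sequence(spec: GratingSpec, samples_per_cycle: int = 32) -> StimulusSequence:
    """Phase sweeps one full 360 degree cycle; all other parameters fixed."""
    phases = spec.phase + np.arange(samples_per_cycle) * 360.0 / samples_per_cycle
    frames = np.stack([make_grating(GratingSpec(spec.orientation, p, spec.frequency,
                                                spec.size, spec.mask_diameter, spec.contrast))
                       for p in phases])
    return StimulusSequence(frames, "drift", phases, 360.0, spec)


def make_rotation_sequence(spec: GratingSpec, samples_per_cycle: int = 32) -> StimulusSequence:
    """Orientation sweeps one 180 degree cycle (orientation is pi-periodic); phase fixed."""
    thetas = spec.orientation + np.arange(samples_per_cycle) * 180.0 / samples_per_cycle
    frames = np.stack([make_grating(GratingSpec(t, spec.phase, spec.frequency,
                                                spec.size, spec.mask_diameter, spec.contrast))
                       for t in thetas])
    return StimulusSequence(frames, "rotate", thetas, 180.0, spec)


def _one_over_f_noise(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    f = radial_frequency_grid(size, size)
    amp = np.zeros_like(f)
    amp[f > 0] = 1.0 / f[f > 0]
    spec = (rng.standard_normal((n, size, size // 2 + 1))
            + 1j * rng.standard_normal((n, size, size // 2 + 1)))
    out = sfft.irfft2(spec * amp[None], s=(size, size))
    return out / out.std(axis=(1, 2), keepdims=True)


def generate_synthetic_images(cfg: SyntheticImageConfig) -> ImageBatch:
    """Dead-leaves-style composites: randomly oriented smooth bars over 1/f noise.

    Deterministic given ``cfg.seed``.  Edge orientations are drawn uniformly
    on [0, 180) and recorded on the returned batch; the radially averaged
    amplitude spectrum falls approximately as 1/f.
    """
    rng = np.random.default_rng(cfg.seed)
    n, size = cfg.n_images, cfg.size
    cols, rows = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float))
    images = np.zeros((n, size, size))
    all_orients = []
    for i in range(n):
        k = rng.poisson(cfg.edges_per_image)
        for _ in range(k):
            theta = rng.uniform(0.0, 180.0)
            all_orients.append(theta)
            th = np.deg2rad(theta)
            cx, cy = rng.uniform(0, size, 2)
            length = rng.uniform(size / 4, size)
            width = rng.uniform(0.6, 1.8)
            amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0)
            # distance along / across a bar oriented at theta
            dx, dy = cols - cx, rows - cy
            along = dx * np.cos(th) - dy * np.sin(th)   # image rows grow downward
            across = dx * np.sin(th) + dy * np.cos(th)
            # hard-edged bar with half-pixel anti-aliasing: step edges keep the
            # amplitude spectrum close to 1/f
            profile = amp * np.clip(width + 0.5 - np.abs(across), 0.0, 1.0)
            envelope = np.clip((length / 2 + 0.5 - np.abs(along)) / 2, 0.0, 1.0)
            images[i] += profile * envelope
        images[i] -= images[i].mean()
    scale = images.std() or 1.0
    images = images / scale + cfg.noise_weight * _one_over_f_noise(rng, n, size)
    images -= images.mean(axis=(1, 2), keepdims=True)
    peak = np.max(np.abs(images))
    if peak > 0:
        images /= peak
    return ImageBatch(images, whitened=False, value_range=(-1.0, 1.0),
                      edge_orientations=np.asarray(all_orients))


def spectral_slope(images: np.ndarray, f_lo: float = 0.03, f_hi: float = 0.4) -> float:
    """Log-log slope of the radially averaged amplitude spectrum of a batch.

    A batch of natural(-like) images should return approximately -1.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    h, w = images.shape[-2:]
    f = radial_frequency_grid(h, w)
    amp = np.abs(sfft.rfft2(images)).mean(axis=0)
    sel = (f >= f_lo) & (f <= f_hi)
    # radial binning
    nb = 12
    edges = np.geomspace(f_lo, f_hi, nb + 1)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = sel & (f >= lo) & (f < hi)
        if m.sum():
            centers.append(np.sqrt(lo * hi))
            means.append(amp[m].mean())
    coef = np.polyfit(np.log(centers), np.log(means), 1)
    return float(coef[0])


def load_image_dataset(path: str, n: int, size: int = 96, seed: int = 0) -> ImageBatch:
    """Read grayscale crops from an STL-10-format binary file (optional input).

    The file is expected in the STL-10 binary layout: uint8, 3 x 96 x 96 per
    image, column-major planes.  Images are converted to grayscale and, when
    ``size`` < 96, randomly cropped (deterministically given ``seed``).
    """
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(
            f"external image dataset not found at {path!r}; use "
            "generate_synthetic_images() to train without external data")
    rng = np.random.default_rng(seed)
    raw = np.fromfile(path, dtype=np.uint8, count=n * 3 * 96 * 96 if n else -1)
    per = 3 * 96 * 96
    n_avail = raw.size // per
    n = n or n_avail
    if n_avail < n:
        raise ValueError(f"dataset holds {n_avail} images, requested {n}")
    imgs = raw[:n * per].reshape(n, 3, 96, 96).transpose(0, 1, 3, 2)  # column-major planes
    gray = imgs.mean(axis=1) / 255.0
    if size < 96:
        out = np.empty((n, size, size))
        for i in range(n):
            r, c = rng.integers(0, 96 - size + 1, 2)
            out[i] = gray[i, r:r + size, c:c + size]
        gray = out
    elif size > 96:
        raise ValueError("requested size exceeds the native 96 px resolution")
    return ImageBatch(gray, whitened=False, value_range=(0.0, 1.0))
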