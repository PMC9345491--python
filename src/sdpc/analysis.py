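"""Characterisation battery for trained networks.

Covers the classical V1 measurements:

* modulation ratio F1/F0 of a stimulus-locked tuning curve — the standard
  simple/complex classifier (simple if F1/F0 > 1);
* the rectification index chi of a half-rectified sinusoid response model
  ``(a cos(phi - phi0) - b)+`` with chi = b/|a|, and the closed-form
  nonlinear mapping between chi and F1/F0;
* log-Gabor receptive-field fits giving preferred orientation, phase,
  spatial frequency and orientation bandwidth (HWHH);
* a ridge-regularised linear back-projection of second-layer units into
  image space (their effective receptive fields through the pooling
  nonlinearity);
* the local homogeneity index (LHI) of orientation maps, pinwheel detection
  and pinwheel density per cortical-column area;
* population summaries: percentages of phase-invariant / orientation-
  unselective cells, chi distributions (median +/- MAD), paired signed-rank
  comparisons, and the LHI-vs-HWHH regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft
from scipy import optimize, stats

from .core import compute_receptive_field
from .stimuli import GratingSpec, StimulusSequence, make_drift_sequence, make_rotation_sequence, whiten

# ---------------------------------------------------------------------------
# tuning curves and the modulation ratio


@dataclass
class TuningCurve:
    """Response of one unit over one stimulus cycle."""

    responses: np.ndarray               # [T] nonnegative
    stimulus_axis: np.ndarray           # deg per frame
    mode: str                           # "drift" | "rotate"
    unit: tuple = ()                    # (layer, channel) identifier

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.responses.ndim != 1 or len(self.responses) != len(self.stimulus_axis):
            raise ValueError("responses and stimulus_axis must be 1-D and equal length")


@dataclass
class ModulationResult:
    f0: float
    f1: float
    f1f0: float
    classification: str                 # "simple" | "complex" | "nonresponsive"


def compute_f1f0(curve: TuningCurve) -> ModulationResult:
    """First harmonic over mean of a single-cycle, uniformly sampled curve.

    F0 is the mean response, F1 twice the modulus of the DFT component at one
    cycle per sweep divided by T.  Simple if F1/F0 > 1, complex otherwise.
    """
    r = curve.responses
    t = len(r)
    f0 = float(r.mean())
    f1 = float(2.0 * np.abs(np.fft.rfft(r)[1]) / t)
    if f0 <= 0:
        return ModulationResult(f0, f1, float("nan"), "nonresponsive")
    ratio = f1 / f0
    return ModulationResult(f0, f1, ratio, "simple" if ratio > 1 else "complex")


def chi_to_f1f0(chi: float) -> float:
    """Closed-form modulation ratio of the half-rectified cosine response model.

    For the response (a cos(phi - phi0) - b)+ with chi = b/|a|:

        F1F0 = (-chi sqrt(1-chi^2) + arccos chi) / (sqrt(1-chi^2) - chi arccos chi)

    on -1 <= chi <= 1 (continuously -> 1 at chi = -1 and -> 2 at chi -> 1),
    and -1/chi for chi < -1 (the curve never clips).  Undefined for chi > 1
    (the response would be identically zero).
    """
    chi = float(chi)
    if chi > 1:
        raise ValueError(f"chi = {chi} > 1: the rectified response is zero, F1F0 undefined")
    if chi < -1:
        return -1.0 / chi
    if chi == 1.0:
        return 2.0
    s = np.sqrt(1.0 - chi * chi)
    ac = np.arccos(chi)
    return float((-chi * s + ac) / (s - chi * ac))


@dataclass
class RectifiedSineFit:
    a: float
    b: float
    phi0: float                         # deg
    chi: float                          # b / |a|
    fit_residual: float

    def predict(self, phi_deg: np.ndarray) -> np.ndarray:
        u = np.deg2rad(np.asarray(phi_deg) - self.phi0)
        return np.maximum(self.a * np.cos(u) - self.b, 0.0)


def fit_rectified_sine(curve: TuningCurve) -> RectifiedSineFit:
    """Least-squares fit of (a cos(phi - phi0) - b)+ to a tuning curve.

    Multi-start over phi0 (the rectification makes the problem non-convex),
    refined by trust-region least squares.  chi = b/|a| is the rectification
    index; chi <= -1 means the curve is never clipped and the fit reduces to
    plain cosine regression.
    """
    r = curve.responses
    if np.all(r == 0):
        raise ValueError("cannot fit an all-zero tuning curve")
    x = np.asarray(curve.stimulus_axis, dtype=np.float64)
    # map the stimulus axis to one full cycle in radians regardless of mode
    cycle = 360.0 if curve.mode == "drift" else 180.0
    phi = (x - x[0]) / cycle * 2 * np.pi

    def resid(p):
        a, b, phi0 = p
        return np.maximum(a * np.cos(phi - phi0) - b, 0.0) - r

    best = None
    a0 = max(r.max() - r.min(), 1e-9)
    peak = phi[int(np.argmax(r))]
    for phi0_start in (peak, peak - np.pi / 4, peak + np.pi / 4, peak + np.pi):
        for b0 in (-0.5 * a0, 0.0, 0.5 * a0):
            sol = optimize.least_squares(resid, [a0, b0, phi0_start], method="lm",
                                         max_nfev=300)
            if best is None or sol.cost < best.cost:
                best = sol
    a, b, phi0 = best.x
    if a < 0:          # (a, b, phi0) and (|a|, b, phi0 + pi) parameterise the same curve
        a, phi0 = -a, phi0 + np.pi
    phi0_axis = float(x[0] + (phi0 % (2 * np.pi)) / (2 * np.pi) * cycle)
    chi = float(b / a) if a != 0 else float("inf")
    return RectifiedSineFit(float(a), float(b), phi0_axis, chi,
                            float(np.sum(resid(best.x) ** 2)))


def curve_from_rectified_sine(a: float, b: float, phi0_deg: float, n: int = 64,
                              mode: str = "drift",
                              rng: np.random.Generator | None = None,
                              noise_sigma: float = 0.0) -> TuningCurve:
    """Synthesise a single-cycle tuning curve from the rectified-sine model."""
    cycle = 360.0 if mode == "drift" else 180.0
    axis = np.arange(n) * cycle / n
    phi = axis / cycle * 2 * np.pi
    r = np.maximum(a * np.cos(phi - np.deg2rad(phi0_deg) * 360.0 / cycle) - b, 0.0)
    if noise_sigma > 0:
        r = np.maximum(r + rng.normal(0, noise_sigma, size=n), 0.0)
    return TuningCurve(r, axis, mode)


# ---------------------------------------------------------------------------
# log-Gabor receptive-field fitting


@dataclass
class LogGaborFit:
    theta: float                        # preferred orientation, deg in [0, 180)
    phi: float                          # preferred phase, deg in [0, 360)
    f0: float                           # preferred frequency, cycles/px
    sigma_theta: float                  # angular bandwidth, rad
    sigma_f: float                      # log-frequency bandwidth
    hwhh: float                         # orientation half-width at half height, deg
    amplitude: float
    residual: float                     # relative residual ||k - fit||^2 / ||k||^2


def log_gabor_quadrature(size: int, theta: float, f0: float,
                         sigma_theta: float, sigma_f: float) -> np.ndarray:
    """Complex spatial filter whose frequency support is a one-sided log-Gabor:
    log-normal radial profile times Gaussian angular profile centred on theta.

    The real part is the even-symmetric (cosine-phase) filter, the imaginary
    part its quadrature pair.  Orientation follows the grating convention:
    counter-clockwise from the horizontal axis, with image rows growing down.
    """
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    alpha = np.arctan2(-fy, fx)          # CCW angle of the frequency vector
    dal = np.angle(np.exp(1j * (alpha - np.deg2rad(theta))))
    with np.errstate(divide="ignore"):
        radial = np.exp(-0.5 * (np.log(np.maximum(f, 1e-12) / f0) / sigma_f) ** 2)
    radial[f == 0] = 0.0
    g = radial * np.exp(-0.5 * (dal / sigma_theta) ** 2)
    h = np.fft.ifft2(g)
    c = size // 2
    return np.roll(h, (c, c), axis=(0, 1))


def _project_quadrature(kernel: np.ndarray, h: np.ndarray):
    """Least-squares coefficients of kernel on the (even, odd) filter pair."""
    basis = np.stack([h.real.ravel(), h.imag.ravel()], axis=1)
    coef, *_ = np.linalg.lstsq(basis, kernel.ravel(), rcond=None)
    fit = basis @ coef
    res = float(np.sum((kernel.ravel() - fit) ** 2) / np.sum(kernel ** 2))
    return coef, res


def fit_log_gabor(kernel: np.ndarray, pad_to: int = 16) -> LogGaborFit:
    """Fit a log-Gabor wavelet to a 2-D kernel.

    Coarse grid over (theta, f0, bandwidths) followed by Nelder-Mead
    refinement; phase and amplitude come from the linear projection onto the
    quadrature pair at each candidate.  The kernel is zero-padded (centred)
    to ``pad_to`` pixels for adequate frequency resolution.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 2:
        raise ValueError("kernel must be 2-D")
    if np.all(kernel == 0):
        raise ValueError("cannot fit an all-zero kernel")
    n = max(pad_to, kernel.shape[0])
    pad = n - kernel.shape[0]
    lo, hi = pad // 2, pad - pad // 2
    kp = np.pad(kernel, ((lo, hi), (lo, hi)))

    def eval_params(p):
        theta, logf0, st, sf = p
        if not (0.01 <= np.exp(logf0) <= 0.5) or st <= 0.05 or sf <= 0.05:
            return None, None, np.inf
        h = log_gabor_quadrature(n, theta, np.exp(logf0), st, sf)
        coef, res = _project_quadrature(kp, h)
        return h, coef, res

    best_p, best_res = None, np.inf
    for theta in np.arange(0, 180, 7.5):
        for f0 in np.geomspace(0.06, 0.42, 8):
            for st in (0.35, 0.6):
                for sf in (0.35, 0.6):
                    _, _, res = eval_params((theta, np.log(f0), st, sf))
                    if res < best_res:
                        best_res, best_p = res, (theta, np.log(f0), st, sf)

    sol = optimize.minimize(lambda p: eval_params(p)[2], best_p, method="Nelder-Mead",
                            options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-10})
    p = sol.x if sol.fun <= best_res else np.asarray(best_p)
    h, coef, res = eval_params(p)
    theta, f0 = p[0] % 180.0, float(np.exp(p[1]))
    phi = float(np.degrees(np.arctan2(coef[1], coef[0])) % 360.0)
    st = float(abs(p[2]))
    hwhh = float(np.degrees(st * np.sqrt(2 * np.log(2))))
    return LogGaborFit(float(theta), phi, f0, st, float(abs(p[3])), hwhh,
                       float(np.hypot(*coef)), res)


# ---------------------------------------------------------------------------
# orientation maps, LHI and pinwheels


@dataclass
class OrientationMap:
    """Per-unit preferred parameters arranged on the feature topology."""

    topology: str                       # "grid_toroidal" | "ring_circular" | "none"
    theta: np.ndarray                   # deg, flat [M]
    phi: np.ndarray | None = None
    hwhh: np.ndarray | None = None
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=np.float64)
        m = self.theta.size
        if self.topology == "grid_toroidal":
            g = int(round(np.sqrt(m)))
            if g * g != m:
                raise ValueError("grid topology requires a perfect-square unit count")
            self.grid_shape = (g, g)


@dataclass
class LHIMap:
    values: np.ndarray                  # same layout as the orientation map (flat)
    topology: str
    grid_shape: tuple[int, int] | None = None


@dataclass
class PinwheelReport:
    positions: list
    count: int
    column_size: float | None = None    # c = (180 / mean HWHH)^2
    density: float | None = None        # rho = count / (M / c)


def compute_lhi(omap: OrientationMap, sigma: float = 1.0) -> LHIMap:
    """Local homogeneity index: modulus of the Gaussian-weighted mean of
    exp(2j theta) over the neighbourhood of each unit, on the declared
    topology (wraparound distances), truncated at 3 sigma.

    1 in iso-orientation domains, near 0 at pinwheel singularities.
    """
    if omap.topology == "none":
        raise ValueError("LHI requires a ring or grid feature topology")
    z = np.exp(2j * np.deg2rad(omap.theta))
    rad = int(np.ceil(3 * sigma))
    offs = np.arange(-rad, rad + 1)
    if omap.topology == "ring_circular":
        m = omap.theta.size
        w = np.exp(-offs ** 2 / (2 * sigma ** 2))
        vals = np.empty(m)
        for i in range(m):
            idx = (i + offs) % m
            vals[i] = np.abs(np.sum(w * z[idx])) / w.sum()
        return LHIMap(vals, omap.topology)
    g = omap.grid_shape[0]
    zz = z.reshape(g, g)
    dr, dc = np.meshgrid(offs, offs, indexing="ij")
    w = np.exp(-(dr ** 2 + dc ** 2) / (2 * sigma ** 2))
    keep = (dr ** 2 + dc ** 2) <= (3 * sigma) ** 2   # circular truncation at 3 sigma
    w = w * keep
    vals = np.empty((g, g))
    for r in range(g):
        for c in range(g):
            idx_r = (r + dr) % g
            idx_c = (c + dc) % g
            vals[r, c] = np.abs(np.sum(w * zz[idx_r, idx_c])) / w.sum()
    return LHIMap(vals.ravel(), omap.topology, (g, g))


def detect_pinwheels(lhi: LHIMap, threshold: float = 0.2) -> PinwheelReport:
    """Strict local minima of the LHI in 3x3 toroidal neighbourhoods, below
    ``threshold``; these are the orientation-map singularities."""
    if lhi.topology != "grid_toroidal":
        raise ValueError("pinwheels are defined only on 2-D (grid) orientation maps")
    g = lhi.grid_shape[0]
    v = lhi.values.reshape(g, g)
    is_min = v < threshold
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            is_min &= v < np.roll(v, (dr, dc), axis=(0, 1))
    pos = [tuple(p) for p in np.argwhere(is_min)]
    return PinwheelReport(positions=pos, count=len(pos))


def pinwheel_density(report: PinwheelReport, m_units: int, mean_hwhh: float,
                     per_column_area: bool = True) -> PinwheelReport:
    """Pinwheel density rho normalised by cortical-column area.

    The column size is c = (180 / mean HWHH)^2 and the density is
    rho = count / (M / c), i.e. pinwheels per column-sized patch of the map.
    ``per_column_area=False`` selects the alternative grouping rho = count / (M c).
    """
    if mean_hwhh <= 0:
        raise ValueError("mean HWHH must be positive")
    c = (180.0 / mean_hwhh) ** 2
    if m_units < c:
        warnings.warn(f"map of {m_units} units is smaller than one column (c = {c:.1f})")
    rho = report.count / (m_units / c) if per_column_area else report.count / (m_units * c)
    return PinwheelReport(report.positions, report.count, c, float(rho))


# ---------------------------------------------------------------------------
# probing a trained model with gratings


def measure_tuning_curve(model, unit: tuple[int, int], sequence: StimulusSequence,
                         whiten_stimuli: bool = True) -> TuningCurve:
    """Present every frame of a stimulus sequence and record one unit's response.

    The response is the inferred steady-state activity of the unit's channel
    at the spatial position of maximal response over the sweep (the position
    is selected once, on the best frame, then held fixed).
    """
    layer, channel = unit
    frames = whiten(sequence.frames, scale="batch").images if whiten_stimuli else sequence.frames
    state = model.infer(frames.astype(np.float32))
    resp = state.gamma[layer][:, channel].astype(np.float64)   # [T, h, w]
    if resp.max() <= 0:
        warnings.warn(f"unit {unit} never active during the sweep; returning a zero curve")
        curve = np.zeros(len(sequence))
    else:
        t, r, c = np.unravel_index(np.argmax(resp), resp.shape)
        curve = resp[:, r, c]
    return TuningCurve(curve, sequence.stimulus_axis, sequence.mode, unit)


def probe_population(model, layer: int, prefs: list[tuple[float, float]],
                     mode: str = "drift", samples_per_cycle: int = 32,
                     probe_size: int | None = None,
                     theta_bins: int = 16, f0_bins: int = 6,
                     probe_iters: int = 60, probe_tol: float = 1e-4) -> list[TuningCurve]:
    """Tuning curves for every unit of a layer, each probed with a grating at
    (close to) its own optimal orientation and frequency.

    ``prefs`` holds (theta, f0) per unit.  Optimal parameters are quantised to
    a small grid so that units sharing a stimulus are probed in one inference
    pass; the f1/f0 statistic is insensitive to the residual quantisation.
    """
    if probe_size is None:
        probe_size = max(compute_receptive_field(model.config)[-1] + 6, 20)
    f0_grid = np.geomspace(0.07, 0.35, f0_bins)
    quant = []
    for theta, f0 in prefs:
        tq = (round(theta / (180.0 / theta_bins)) % theta_bins) * (180.0 / theta_bins)
        fq = float(f0_grid[np.argmin(np.abs(np.log(f0_grid) - np.log(max(f0, 1e-3))))])
        quant.append((tq, fq))
    curves: list[TuningCurve | None] = [None] * len(prefs)
    for key in sorted(set(quant)):
        units = [i for i, q in enumerate(quant) if q == key]
        spec = GratingSpec(orientation=key[0], phase=0.0, frequency=key[1],
                           size=probe_size, mask_diameter=14.0)
        seq = (make_drift_sequence(spec, samples_per_cycle) if mode == "drift"
               else make_rotation_sequence(spec, samples_per_cycle))
        frames = whiten(seq.frames, scale="batch").images.astype(np.float32)
        state = model.infer(frames, inference_max_iters=probe_iters,
                            inference_tol=probe_tol, monotone=False)
        resp_all = state.gamma[layer].astype(np.float64)
        for i in units:
            resp = resp_all[:, i]
            if resp.max() <= 0:
                curve = np.zeros(len(seq))
            else:
                t, r, c = np.unravel_index(np.argmax(resp), resp.shape)
                curve = resp[:, r, c]
            curves[i] = TuningCurve(curve, seq.stimulus_axis, mode, (layer, i))
    return curves


def find_optimal_grating(model, layer: int, theta_step: float = 15.0,
                         f0_grid=(0.08, 0.11, 0.15, 0.21, 0.28),
                         phases: int = 4, probe_size: int | None = None,
                         probe_iters: int = 40, probe_tol: float = 1e-3):
    """Empirical tuning search over a (theta, f0) grating grid.

    Mirrors the experimental procedure of finding each neuron's optimal
    stimulus by search: every grid grating is presented at a few phases, and
    each unit's optimum is the (theta, f0) that maximises its peak response
    anywhere in its map.  Returns (prefs, peak) where ``prefs`` is a list of
    (theta, f0) per unit and ``peak`` the response attained there (0 for
    units silent on the whole battery).
    """
    if probe_size is None:
        probe_size = max(compute_receptive_field(model.config)[-1] + 6, 20)
    thetas = np.arange(0.0, 180.0, theta_step)
    m = model.config.layers[layer].n_units
    best = np.zeros(m)
    prefs = [(0.0, float(f0_grid[0]))] * m
    frames_buf, keys = [], []

    def flush():
        nonlocal frames_buf, keys, best, prefs
        if not frames_buf:
            return
        frames = np.concatenate(frames_buf).astype(np.float32)
        state = model.infer(frames, inference_max_iters=probe_iters,
                            inference_tol=probe_tol, monotone=False)
        resp = state.gamma[layer]
        start = 0
        for (theta, f0, t) in keys:
            peak = resp[start:start + t].max(axis=(0, 2, 3))
            for i in np.nonzero(peak > best)[0]:
                best[i] = peak[i]
                prefs[i] = (float(theta), float(f0))
            start += t
        frames_buf, keys = [], []

    for theta in thetas:
        for f0 in f0_grid:
            seq = make_drift_sequence(GratingSpec(theta, 0.0, f0, probe_size, 14.0), phases)
            # per-sequence whitening, matching the tuning-curve probe conditions
            frames_buf.append(whiten(seq.frames, scale="batch").images)
            keys.append((theta, f0, len(seq)))
            if sum(k[2] for k in keys) >= 32:
                flush()
    flush()
    return prefs, best


def backproject_second_layer(model, images: np.ndarray, ridge: float = 1e-3,
                             tol: float = 1e-5, max_iter: int = 200) -> np.ndarray:
    """Approximate linear receptive fields of second-layer units in image space.

    Solves min_V 1/2 ||x - V^T gamma_C||^2 + ridge/2 ||V||^2 over a batch of
    images, where V^T is a strided transpose convolution whose kernel covers
    the composite receptive field, using conjugate gradients on the normal
    equations.  The inferred gamma_C on the batch are held fixed.
    """
    from scipy.sparse.linalg import LinearOperator, cg

    images = np.asarray(images, dtype=np.float32)
    state = model.infer(images)
    g_c = state.gamma[1].astype(np.float64)
    if g_c.max() <= 0:
        raise ValueError("second layer is silent on the back-projection batch")
    b_, m_c, hc, wc = g_c.shape
    h_img = images.shape[-1]
    rf = compute_receptive_field(model.config)[-1]
    stride = 1
    for s in model.config.pooling.stages:
        if s.kind == "spatial_2d":
            stride *= s.stride
    # upsample gamma_C to image resolution (zeros between samples)
    up_h = (hc - 1) * stride + 1
    g_up = np.zeros((b_, m_c, up_h, up_h))
    g_up[:, :, ::stride, ::stride] = g_c
    k = h_img - up_h + 1                 # kernel size that tiles the image exactly
    if k < rf:
        warnings.warn(f"back-projection kernel {k} px smaller than the composite RF {rf} px")
    x = images.astype(np.float64)[:, None]

    def synth(v):
        fg = sfft.rfft2(g_up, s=(h_img, h_img))
        fk = sfft.rfft2(v, s=(h_img, h_img))
        prod = np.matmul(fg.transpose(2, 3, 0, 1), fk.transpose(2, 3, 0, 1))
        return sfft.irfft2(prod.transpose(2, 3, 0, 1), s=(h_img, h_img))

    def grad_kernel(err):
        fg = np.conj(sfft.rfft2(g_up, s=(h_img, h_img)))
        fe = sfft.rfft2(err, s=(h_img, h_img))
        prod = np.matmul(fg.transpose(2, 3, 1, 0), fe.transpose(2, 3, 0, 1))
        out = sfft.irfft2(prod.transpose(2, 3, 0, 1), s=(h_img, h_img))
        return out[:, :, :k, :k]

    bvec = grad_kernel(x).ravel()

    def matvec(vflat):
        v = vflat.reshape(m_c, 1, k, k)
        return (grad_kernel(synth(v)) + ridge * v).ravel()

    op = LinearOperator((m_c * k * k, m_c * k * k), matvec=matvec)
    sol, info = cg(op, bvec, rtol=tol, maxiter=max_iter)
    if info > 0:
        warnings.warn(f"back-projection CG stopped after {info} iterations before tol")
    return sol.reshape(m_c, k, k)


# ---------------------------------------------------------------------------
# population statistics


@dataclass
class PopulationSummary:
    r_phase: float                      # % complex under drifting gratings
    r_orientation: float                # % orientation-unselective under rotating gratings
    n_responsive: int
    n_nonresponsive: int
    chi_phase_median: float
    chi_phase_mad: float
    chi_orientation_median: float
    chi_orientation_mad: float
    signed_rank_p: float                # one-tailed: chi_phase < chi_orientation
    lhi_hwhh_slope: float | None = None
    lhi_hwhh_intercept: float | None = None
    lhi_hwhh_p: float | None = None


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def population_summary(mods_drift: list[ModulationResult],
                       mods_rotate: list[ModulationResult],
                       chi_drift: list[float] | None = None,
                       chi_rotate: list[float] | None = None,
                       lhi: np.ndarray | None = None,
                       hwhh: np.ndarray | None = None) -> PopulationSummary:
    """Aggregate per-unit modulation results into the population statistics.

    R percentages count units with F1F0 < 1 among responsive units; units that
    never responded are excluded and counted separately.  The chi
    distributions are compared with a paired one-tailed Wilcoxon signed-rank
    test (alternative: chi under drift is lower, i.e. more complex-like).
    The optional regression relates orientation tuning width (HWHH) to map
    position (LHI) by ordinary least squares.
    """
    if not mods_drift:
        raise ValueError("empty population")
    ok = [i for i, (d, r) in enumerate(zip(mods_drift, mods_rotate))
          if d.classification != "nonresponsive" and r.classification != "nonresponsive"]
    n_bad = len(mods_drift) - len(ok)
    if not ok:
        raise ValueError("no responsive units in the population")
    r_phi = 100.0 * np.mean([mods_drift[i].f1f0 < 1 for i in ok])
    r_theta = 100.0 * np.mean([mods_rotate[i].f1f0 < 1 for i in ok])
    summary = dict(r_phase=float(r_phi), r_orientation=float(r_theta),
                   n_responsive=len(ok), n_nonresponsive=n_bad,
                   chi_phase_median=float("nan"), chi_phase_mad=float("nan"),
                   chi_orientation_median=float("nan"), chi_orientation_mad=float("nan"),
                   signed_rank_p=float("nan"))
    if chi_drift is not None and chi_rotate is not None:
        cd = np.asarray([chi_drift[i] for i in ok], dtype=float)
        cr = np.asarray([chi_rotate[i] for i in ok], dtype=float)
        fin = np.isfinite(cd) & np.isfinite(cr)   # units whose curve fits succeeded
        cd, cr = cd[fin], cr[fin]
        if cd.size:
            summary.update(chi_phase_median=float(np.median(cd)), chi_phase_mad=_mad(cd),
                           chi_orientation_median=float(np.median(cr)), chi_orientation_mad=_mad(cr))
            if np.allclose(cd - cr, 0):
                summary["signed_rank_p"] = 0.5    # identical samples: no evidence either way
            else:
                summary["signed_rank_p"] = float(
                    stats.wilcoxon(cd, cr, alternative="less").pvalue)
    out = PopulationSummary(**summary)
    if lhi is not None and hwhh is not None:
        import statsmodels.api as sm

        x = sm.add_constant(np.asarray(lhi, dtype=float))
        fit = sm.OLS(np.asarray(hwhh, dtype=float), x).fit()
        out.lhi_hwhh_intercept = float(fit.params[0])
        out.lhi_hwhh_slope = float(fit.params[1])
        out.lhi_hwhh_p = float(fit.pvalues[1])
    return out
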