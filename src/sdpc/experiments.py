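"""Experiment orchestration: the pooling x size grid, per-run analysis and reports.

A *run* trains one network, probes every unit with drifting and rotating
gratings at its own optimal parameters, and computes the map statistics
(LHI, pinwheels) where the pooling induces a feature topology.  The
``reduced`` scale is sized for a workstation CPU: 36+36 units, 24 px
synthetic natural-like images, ~1200 learning steps; the ``full`` scale
mirrors the reference architecture (96 px natural images, 28125 steps) and
requires an external dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .analysis import (
    OrientationMap,
    PinwheelReport,
    PopulationSummary,
    TuningCurve,
    backproject_second_layer,
    compute_f1f0,
    compute_lhi,
    detect_pinwheels,
    fit_log_gabor,
    find_optimal_grating,
    fit_rectified_sine,
    pinwheel_density,
    population_summary,
    probe_population,
)
from .core import NetworkConfig, SDPCModel, reference_config, train
from .stimuli import SyntheticImageConfig, generate_synthetic_images, whiten

POOLING_VARIANTS = ("spatial_2d", "feature_2d", "spatial_2d+feature_1d", "spatial_2d+feature_2d")
DEFAULT_SIZES = (36, 49, 64, 81, 100, 121)

#: desk-scale defaults: sized to train one network in a few minutes on one CPU.
#: the short lambda ramp leaves most of the run at full sparsity, where the
#: map-organising pooling competition acts
REDUCED_SCALE = dict(image_size=24, n_images=400, batch_size=10, n_iterations=1200,
                     inference_max_iters=20, inference_tol=1e-3, lambda_ramp_frac=0.2)
FULL_SCALE = dict(image_size=96, n_images=100000, batch_size=32, n_iterations=28125,
                  inference_max_iters=200, inference_tol=1e-4, lambda_ramp_frac=0.5)


@dataclass(frozen=True)
class ExperimentGrid:
    """The experiment design: pooling variants x layer sizes, seeded per cell."""

    variants: tuple[str, ...] = POOLING_VARIANTS
    sizes_s: tuple[int, ...] = DEFAULT_SIZES
    sizes_c: tuple[int, ...] = DEFAULT_SIZES
    master_seed: int = 0
    scale: str = "reduced"


def build_experiment_grid(grid: ExperimentGrid) -> list[NetworkConfig]:
    """Cartesian product of sizes for each pooling variant, deterministic order.

    Seeds are assigned by a counter over the enumeration so that every cell is
    independently reproducible from the master seed.
    """
    if not grid.variants or not grid.sizes_s or not grid.sizes_c:
        raise ValueError("variants and size lists must be non-empty")
    scale = REDUCED_SCALE if grid.scale == "reduced" else FULL_SCALE
    configs = []
    counter = 0
    for variant in grid.variants:
        for m_s in grid.sizes_s:
            for m_c in grid.sizes_c:
                if "feature_2d" in variant and int(round(np.sqrt(m_s))) ** 2 != m_s:
                    raise ValueError(
                        f"M_s = {m_s} is not a perfect square, required by {variant}")
                configs.append(reference_config(
                    m_s, m_c, variant,
                    seed=(grid.master_seed * 100003 + counter) % (2 ** 31),
                    n_iterations=scale["n_iterations"], batch_size=scale["batch_size"],
                    inference_max_iters=scale["inference_max_iters"],
                    inference_tol=scale["inference_tol"],
                    lambda_ramp_frac=scale["lambda_ramp_frac"]))
                counter += 1
    return configs


@dataclass
class LayerCharacterization:
    """Per-unit measurements of one layer."""

    theta: np.ndarray
    phi: np.ndarray
    f0: np.ndarray
    hwhh_fit: np.ndarray                # from the log-Gabor angular bandwidth
    hwhh_curve: np.ndarray              # from the rotating-grating tuning curve
    f1f0_drift: np.ndarray
    f1f0_rotate: np.ndarray
    chi_drift: np.ndarray
    chi_rotate: np.ndarray
    responsive: np.ndarray              # bool per unit
    summary: PopulationSummary | None = None
    lhi: np.ndarray | None = None
    pinwheels: PinwheelReport | None = None


@dataclass
class RunReport:
    """Everything a single trained network produced, in serialisable form."""

    config: dict
    pooling_variant: str
    scale: str
    final_loss: float
    sparsity: tuple[float, float]
    layer1: dict
    layer2: dict
    mean_lhi: float | None
    pinwheel_count: int | None
    column_size: float | None
    pinwheel_density: float | None
    failed: bool = False
    failure: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serialisable: {type(o)}")


def hwhh_from_curve(curve: TuningCurve) -> float:
    """Half-width at half of the peak-minus-baseline response of a rotating
    tuning curve, measured circularly around the peak (degrees)."""
    r = curve.responses
    if r.max() <= r.min():
        return float("nan")
    half = r.min() + 0.5 * (r.max() - r.min())
    n = len(r)
    step = curve.stimulus_axis[1] - curve.stimulus_axis[0] if n > 1 else 0.0
    peak = int(np.argmax(r))
    above = 0.5  # the peak sample contributes half a step on each side
    for d in range(1, n // 2 + 1):
        if r[(peak + d) % n] >= half:
            above += 1
        else:
            break
    for d in range(1, n // 2 + 1):
        if r[(peak - d) % n] >= half:
            above += 1
        else:
            break
    return float(above * step / 2.0)   # half of the full width above half height


def characterize_layer(model: SDPCModel, layer: int, prefs, responsive_mask,
                       samples_per_cycle: int = 32) -> LayerCharacterization:
    """Probe every unit of one layer with drifting and rotating gratings and
    collect modulation/chi/tuning-width measurements."""
    m = len(prefs)
    curves_d = probe_population(model, layer, prefs, "drift", samples_per_cycle)
    curves_r = probe_population(model, layer, prefs, "rotate", samples_per_cycle)
    f1f0_d = np.full(m, np.nan)
    f1f0_r = np.full(m, np.nan)
    chi_d = np.full(m, np.nan)
    chi_r = np.full(m, np.nan)
    hwhh_c = np.full(m, np.nan)
    responsive = np.zeros(m, dtype=bool)
    for i in range(m):
        if not responsive_mask[i]:
            continue
        md = compute_f1f0(curves_d[i])
        mr = compute_f1f0(curves_r[i])
        if md.classification == "nonresponsive" or mr.classification == "nonresponsive":
            continue
        responsive[i] = True
        f1f0_d[i], f1f0_r[i] = md.f1f0, mr.f1f0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                chi_d[i] = fit_rectified_sine(curves_d[i]).chi
                chi_r[i] = fit_rectified_sine(curves_r[i]).chi
            except ValueError:
                pass
        hwhh_c[i] = hwhh_from_curve(curves_r[i])
    return LayerCharacterization(
        theta=np.array([p[0] for p in prefs]), phi=np.zeros(m),
        f0=np.array([p[1] for p in prefs]),
        hwhh_fit=np.zeros(m), hwhh_curve=hwhh_c,
        f1f0_drift=f1f0_d, f1f0_rotate=f1f0_r,
        chi_drift=chi_d, chi_rotate=chi_r, responsive=responsive)


def run_experiment(config: NetworkConfig, images: np.ndarray | None = None,
                   scale: str = "reduced", out_dir: str | None = None,
                   samples_per_cycle: int = 32) -> RunReport:
    """Train one network and run the full measurement battery.

    Deterministic given ``config.seed`` (the synthetic dataset is seeded from
    it as well).  Writes the model container, the per-unit CSV and the JSON
    summary under ``out_dir`` when given.
    """
    sc = REDUCED_SCALE if scale == "reduced" else FULL_SCALE
    if images is None:
        images = whiten(generate_synthetic_images(SyntheticImageConfig(
            n_images=sc["n_images"], size=sc["image_size"],
            seed=config.seed % (2 ** 31)))).images
    try:
        dicts, trace = train(images, config)
    except Exception as e:  # divergence and numeric failures become a failed report
        return RunReport(config.to_dict(), config.pooling.name, scale,
                         float("nan"), (float("nan"),) * 2, {}, {}, None, None, None, None,
                         failed=True, failure=str(e))
    model = SDPCModel(config, dicts, trace)

    # --- layer 1: map parameters from the kernels; probe optima by tuning search
    m_s = config.layers[0].n_units
    fits1 = []
    for m in range(m_s):
        k = dicts[0].kernels[m, 0]
        fits1.append(None if np.allclose(k, 0) else fit_log_gabor(k))
    prefs1, peak1 = find_optimal_grating(model, 0)
    layer1 = characterize_layer(model, 0, prefs1, peak1 > 0, samples_per_cycle)
    layer1.theta = np.array([f.theta if f else prefs1[m][0] for m, f in enumerate(fits1)])
    layer1.phi = np.array([f.phi if f else np.nan for f in fits1])
    layer1.hwhh_fit = np.array([f.hwhh if f else np.nan for f in fits1])

    # --- orientation map statistics on the feature topology
    topology = config.pooling.feature_topology
    mean_lhi = pw_count = col_size = pw_density = None
    if topology != "none":
        omap = OrientationMap(topology, layer1.theta)
        lhi = compute_lhi(omap, sigma=1.0)
        layer1.lhi = lhi.values
        mean_lhi = float(np.mean(lhi.values))
        if topology == "grid_toroidal":
            rep = detect_pinwheels(lhi, threshold=0.2)
            hw = layer1.hwhh_curve[np.isfinite(layer1.hwhh_curve)]
            if hw.size and np.nanmean(hw) > 0:
                rep = pinwheel_density(rep, m_s, float(np.nanmean(hw)))
            layer1.pinwheels = rep
            pw_count, col_size, pw_density = rep.count, rep.column_size, rep.density

    # --- layer 2: probe optima by tuning search; back-projection for the
    # image-space receptive-field fits (phase / bandwidth reporting)
    m_c = config.layers[1].n_units
    try:
        vc = backproject_second_layer(model, images[:min(len(images), 120)])
    except ValueError:
        vc = np.zeros((m_c, 1, 1))
    fits2 = []
    for m in range(m_c):
        k = vc[m]
        fits2.append(None if np.allclose(k, 0) else fit_log_gabor(k))
    prefs2, peak2 = find_optimal_grating(model, 1)
    layer2 = characterize_layer(model, 1, prefs2, peak2 > 0, samples_per_cycle)
    layer2.phi = np.array([f.phi if f else np.nan for f in fits2])
    layer2.hwhh_fit = np.array([f.hwhh if f else np.nan for f in fits2])

    layer1.summary = _summarize(layer1)
    layer2.summary = _summarize(layer2)

    report = RunReport(
        config=config.to_dict(), pooling_variant=config.pooling.name, scale=scale,
        final_loss=float(trace.loss[-1]) if trace.loss else float("nan"),
        sparsity=(trace.sparsity_s[-1] if trace.loss else float("nan"),
                  trace.sparsity_c[-1] if trace.loss else float("nan")),
        layer1=_layer_dict(layer1), layer2=_layer_dict(layer2),
        mean_lhi=mean_lhi, pinwheel_count=pw_count, column_size=col_size,
        pinwheel_density=pw_density)
    if out_dir is not None:
        _write_artifacts(report, model, layer1, layer2, out_dir)
    return report


def _summarize(lc: LayerCharacterization) -> PopulationSummary | None:
    from .analysis import ModulationResult

    ok = lc.responsive
    if not ok.any():
        return None
    mods_d = [ModulationResult(1, 1, lc.f1f0_drift[i],
                               "nonresponsive" if not ok[i] else
                               ("simple" if lc.f1f0_drift[i] > 1 else "complex"))
              for i in range(len(ok))]
    mods_r = [ModulationResult(1, 1, lc.f1f0_rotate[i],
                               "nonresponsive" if not ok[i] else
                               ("simple" if lc.f1f0_rotate[i] > 1 else "complex"))
              for i in range(len(ok))]
    chi_ok = np.isfinite(lc.chi_drift) & np.isfinite(lc.chi_rotate)
    kw = {}
    if lc.lhi is not None:
        sel = ok & np.isfinite(lc.hwhh_curve)
        if sel.sum() >= 3:
            kw = dict(lhi=lc.lhi[sel], hwhh=lc.hwhh_curve[sel])
    return population_summary(mods_d, mods_r,
                              chi_drift=np.where(chi_ok, lc.chi_drift, np.nan).tolist(),
                              chi_rotate=np.where(chi_ok, lc.chi_rotate, np.nan).tolist(),
                              **kw)


def _layer_dict(lc: LayerCharacterization) -> dict:
    s = lc.summary
    return dict(
        n_units=len(lc.responsive),
        n_responsive=int(lc.responsive.sum()),
        r_phase=s.r_phase if s else None,
        r_orientation=s.r_orientation if s else None,
        chi_phase_median=s.chi_phase_median if s else None,
        chi_phase_mad=s.chi_phase_mad if s else None,
        chi_orientation_median=s.chi_orientation_median if s else None,
        chi_orientation_mad=s.chi_orientation_mad if s else None,
        signed_rank_p=s.signed_rank_p if s else None,
        lhi_hwhh_slope=s.lhi_hwhh_slope if s else None,
        lhi_hwhh_p=s.lhi_hwhh_p if s else None,
        mean_hwhh_curve=float(np.nanmean(lc.hwhh_curve)) if np.isfinite(lc.hwhh_curve).any() else None,
    )


def _write_artifacts(report: RunReport, model: SDPCModel,
                     layer1: LayerCharacterization, layer2: LayerCharacterization,
                     out_dir: str) -> None:
    import os

    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    model.save(os.path.join(out_dir, "model.h5"))
    rows = []
    for li, lc in ((0, layer1), (1, layer2)):
        for i in range(len(lc.responsive)):
            rows.append(dict(layer=li, unit=i, theta=lc.theta[i], phi=lc.phi[i],
                             f0=lc.f0[i], hwhh_fit=lc.hwhh_fit[i],
                             hwhh_curve=lc.hwhh_curve[i],
                             f1f0_drift=lc.f1f0_drift[i], f1f0_rotate=lc.f1f0_rotate[i],
                             chi_drift=lc.chi_drift[i], chi_rotate=lc.chi_rotate[i],
                             lhi=(lc.lhi[i] if lc.lhi is not None else np.nan),
                             responsive=bool(lc.responsive[i])))
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "units.csv"), index=False)
    with open(os.path.join(out_dir, "summary.json"), "w") as f:
        f.write(report.to_json())


def report_table(reports: list[RunReport]):
    """Aggregate RunReports into tidy tables: one row per run, columns for the
    phase/orientation invariance percentages and the map statistics."""
    import pandas as pd

    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for r in reports:
        rows.append(dict(
            pooling=r.pooling_variant,
            m_s=r.config["layers"][0]["n_units"], m_c=r.config["layers"][1]["n_units"],
            seed=r.config["seed"], failed=r.failed,
            r_phase_l2=r.layer2.get("r_phase"), r_orientation_l2=r.layer2.get("r_orientation"),
            r_phase_l1=r.layer1.get("r_phase"),
            mean_lhi=r.mean_lhi, pinwheel_count=r.pinwheel_count,
            pinwheel_density=r.pinwheel_density, final_loss=r.final_loss))
    return pd.DataFrame(rows)
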