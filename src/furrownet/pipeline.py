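"""Scenario orchestration: simulation -> rendering -> quantification.

Named presets carry the two turnover regimes of the contractile-network
model ((k_on, k_off) = (0.05, 0.001) wild-type-like and (0.003, 0.001)
dunk-mutant-like, 8000 steps) and the two FRAP scenarios whose ground-truth
half-times are set to the measured cortical myosin values (71.2 s wild
type, 70.5 s dunk mutant).  ``run_scenario`` executes the stage chain for a
scenario and writes a reproducible artifact bundle (trajectory JSON,
TIFF movie, metrics CSVs, summary JSON embedding the resolved config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lattice import build_hex_lattice
from .network import (SimParams, SimConfigError, run_sim, simulate,
                      seed_nodes, ablate, rebuild_interfaces,
                      effective_edge_geometry, save_trajectory)
from .imaging import (RenderParams, RenderError, FRAPGroundTruth,
                      render_frames, make_frap_movie)
from .flow import recoil_analysis
from .intensity import (partition_vertex_edge, vertex_edge_ratio,
                        per_edge_mean_intensity,
                        edge_length_intensity_correlation)
from .frap import frap_normalize, estimate_half_time

__all__ = ["ScenarioConfig", "ConfigError", "PRESETS", "validate_config",
           "run_scenario"]

log = logging.getLogger("furrownet")

SCENARIOS = ("wt", "dunk", "frap_wt", "frap_dunk", "ablation", "custom")

#: Named presets; the two turnover regimes and the FRAP half-time anchors.
PRESETS = {
    "wt": {"sim": {"k_on": 0.05, "k_off": 0.001, "n_steps": 8000}},
    "dunk": {"sim": {"k_on": 0.003, "k_off": 0.001, "n_steps": 8000}},
    "frap_wt": {"frap": {"t_half": 71.2}},
    "frap_dunk": {"frap": {"t_half": 70.5}},
    "ablation": {"sim": {"k_on": 0.05, "k_off": 0.001, "n_steps": 2000},
                 "ablation": {}},
    "custom": {},
}

_FRAP_DEFAULTS = {
    "t_half": 71.2,            # s, generator ground truth
    "frame_interval": 2.35,    # s
    "n_z": 6,
    "n_pre": 5,
    "snr": 10.0,
    "cytoplasm_fraction": 0.3,
    "lattice_rows": 1,
    "lattice_cols": 2,
}

_ABLATION_DEFAULTS = {
    "radius": 1.0,             # um
    "edge": None,              # default: most central edge
    "post_steps": 100,
    "render_stride": 10,
}

_ANALYSIS_DEFAULTS = {
    "vertex_radius": 1.2,      # um, R_v
    "line_width": 0.6,         # um, w_s
    "piv_window": 32,          # px
    "piv_spacing": 8,          # px
    "snapshot_stride": 200,    # steps between rendered frames
}

_LATTICE_DEFAULTS = {"rows": 3, "cols": 3, "edge_length": 6.0}


class ConfigError(ValueError):
    """Invalid scenario configuration, with field paths in the message."""


@dataclass
class ScenarioConfig:
    """Fully resolved configuration of one pipeline scenario."""

    scenario: str
    seed: int = 0
    outdir: str = "furrownet_out"
    sim: SimParams = None
    render: RenderParams = None
    lattice: dict = field(default_factory=lambda: dict(_LATTICE_DEFAULTS))
    analysis: dict = field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))
    frap: dict = field(default_factory=lambda: dict(_FRAP_DEFAULTS))
    ablation: dict = field(default_factory=lambda: dict(_ABLATION_DEFAULTS))

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario, "seed": self.seed,
            "outdir": self.outdir, "sim": self.sim.to_dict(),
            "render": self.render.to_dict(), "lattice": dict(self.lattice),
            "analysis": dict(self.analysis), "frap": dict(self.frap),
            "ablation": dict(self.ablation),
        }


def _merge(defaults: dict, user: dict, path: str, errors: list) -> dict:
    out = dict(defaults)
    for k, v in (user or {}).items():
        if k not in defaults:
            errors.append(f"{path}.{k}: unknown key")
        else:
            out[k] = v
    return out


def resolve_config(raw: dict) -> ScenarioConfig:
    """Fill defaults, expand the named preset, and validate every field."""
    raw = dict(raw or {})
    errors: list = []
    scenario = raw.pop("scenario", "custom")
    if scenario not in SCENARIOS:
        raise ConfigError(
            f"scenario: unknown scenario {scenario!r} (one of {SCENARIOS})")
    preset = PRESETS[scenario]

    seed = raw.pop("seed", 0)
    outdir = raw.pop("outdir", "furrownet_out")
    if not isinstance(seed, (int, np.integer)):
        errors.append("seed: must be an integer")

    sim_kwargs = dict(preset.get("sim", {}))
    sim_kwargs.update(raw.pop("sim", {}) or {})
    render_kwargs = raw.pop("render", {}) or {}
    lattice = _merge(_LATTICE_DEFAULTS, raw.pop("lattice", {}),
                     "lattice", errors)
    analysis = _merge(_ANALYSIS_DEFAULTS, raw.pop("analysis", {}),
                      "analysis", errors)
    frap = _merge({**_FRAP_DEFAULTS, **preset.get("frap", {})},
                  raw.pop("frap", {}), "frap", errors)
    abl = _merge({**_ABLATION_DEFAULTS, **preset.get("ablation", {})},
                 raw.pop("ablation", {}), "ablation", errors)
    for k in raw:
        errors.append(f"{k}: unknown key")

    sim = render = None
    valid_sim_fields = {f.name for f in dataclasses.fields(SimParams)}
    for k in list(sim_kwargs):
        if k not in valid_sim_fields:
            errors.append(f"sim.{k}: unknown key")
            sim_kwargs.pop(k)
    try:
        sim = SimParams(seed=seed, **{k: v for k, v in sim_kwargs.items()
                                      if k != "seed"})
    except SimConfigError as e:
        errors.append(f"sim: {e}")
    valid_render = {f.name for f in dataclasses.fields(RenderParams)}
    for k in list(render_kwargs):
        if k not in valid_render:
            errors.append(f"render.{k}: unknown key")
            render_kwargs.pop(k)
    try:
        render = RenderParams(**render_kwargs)
    except RenderError as e:
        errors.append(f"render: {e}")

    if lattice["rows"] < 1 or lattice["cols"] < 1 or lattice["edge_length"] <= 0:
        errors.append("lattice: rows/cols must be >= 1 and edge_length > 0")
    if frap["t_half"] <= 0:
        errors.append("frap.t_half: must be > 0")
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return ScenarioConfig(scenario=scenario, seed=int(seed), outdir=outdir,
                          sim=sim, render=render, lattice=lattice,
                          analysis=analysis, frap=frap, ablation=abl)


def validate_config(path) -> ScenarioConfig:
    """Load a YAML/JSON config file and resolve it against the schema."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    text = p.read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return resolve_config(raw)


# ---------------------------------------------------------------------------
# Stage helpers (shared by run_scenario and the acceptance script)

def quantify_regime(traj, render_params: RenderParams, vertex_radius=1.2,
                    line_width=0.6, effective_vertex_radius=1.5):
    """Render a trajectory and apply the vertex/edge quantification.

    Returns (stack, DataFrame with per-frame vertex/edge means, ratio and
    edge-length/intensity correlation).
    """
    lat = traj.lattice
    stack, _ = render_frames(traj, render_params)
    part = partition_vertex_edge(lat.cell_polygons(), R_v=vertex_radius,
                                 w_s=line_width,
                                 spacing=render_params.pixel_size)
    res = vertex_edge_ratio(part, stack)
    corr = np.full(stack.n_frames, np.nan)
    for f, state in enumerate(traj.snapshots):
        endpoints, lengths = effective_edge_geometry(
            state, vertex_radius=effective_vertex_radius)
        intens = per_edge_mean_intensity(stack.data[f], endpoints, stack,
                                         R_v=vertex_radius, w_s=line_width)
        ok = np.isfinite(lengths) & np.isfinite(intens)
        if ok.sum() >= 3 and np.ptp(lengths[ok]) > 0:
            corr[f] = edge_length_intensity_correlation(lengths[ok],
                                                        intens[ok])
    df = pd.DataFrame({
        "step": traj.steps, "vertex_mean": res["vertex_mean"],
        "edge_mean": res["edge_mean"], "ratio": res["ratio"],
        "length_intensity_r": corr,
    })
    return stack, df


def run_frap_scenario(cfg: ScenarioConfig, outdir: Path = None) -> dict:
    f = cfg.frap
    lat = build_hex_lattice(f["lattice_rows"], f["lattice_cols"],
                            cfg.lattice["edge_length"])
    rng = np.random.default_rng(cfg.seed)
    rp = dataclasses.replace(cfg.render, frame_interval=f["frame_interval"])
    k_ex = np.log(2.0) / f["t_half"]
    # rectangles: left half / right half of the field, central band
    lo_x, lo_y, hi_x, hi_y = lat.bounds()
    ps = rp.pixel_size
    w = int(np.ceil((hi_x - lo_x + 4.0) / ps)) + 1
    h = int(np.ceil((hi_y - lo_y + 4.0) / ps)) + 1
    bleach = (int(0.05 * w), int(0.15 * h), int(0.45 * w), int(0.85 * h))
    control = (int(0.55 * w), int(0.15 * h), int(0.95 * w), int(0.85 * h))
    truth = FRAPGroundTruth(k_ex=k_ex, bleach_frame=f["n_pre"],
                            bleach_rect=bleach, control_rect=control,
                            cytoplasm_fraction=f["cytoplasm_fraction"])
    stack, truth = make_frap_movie(lat, truth, rp, n_pre=f["n_pre"],
                                   n_z=f["n_z"], snr=f["snr"], rng=rng)
    cyt = truth.cytoplasm_fraction * rp.amplitude
    curve = frap_normalize(stack, truth.bleach_rect, truth.control_rect,
                           cytoplasm_level=cyt,
                           bleach_frame=truth.bleach_frame)
    t_half = estimate_half_time(curve)
    summary = {"t_half_s": t_half, "t_half_frame_s": curve.t_half_frame,
               "true_t_half_s": truth.true_t_half, "seed": cfg.seed}
    if outdir is not None:
        stack.save(outdir / "frap_movie.tif")
        pd.DataFrame({"time_s": curve.time, "bleached": curve.bleached,
                      "control": curve.control, "ratio": curve.ratio}
                     ).to_csv(outdir / "frap_curve.csv", index=False)
        (outdir / "frap_truth.json").write_text(
            json.dumps(truth.to_dict(), indent=1))
    return summary


def run_ablation_scenario(cfg: ScenarioConfig, outdir: Path = None) -> dict:
    lat = build_hex_lattice(cfg.lattice["rows"], cfg.lattice["cols"],
                            cfg.lattice["edge_length"])
    rng = np.random.default_rng(cfg.seed)
    state = seed_nodes(lat, cfg.sim, rng)
    pre = simulate(state, cfg.sim, cfg.sim.n_steps, rng,
                   snapshot_stride=max(cfg.sim.n_steps, 1))
    state = pre.snapshots[-1]

    abl = cfg.ablation
    edge_id = abl["edge"]
    if edge_id is None:
        mids = lat.edge_midpoints()
        center = lat.vertices.mean(axis=0)
        edge_id = int(np.linalg.norm(mids - center, axis=1).argmin())
    cut_pos = lat.edge_midpoints()[edge_id]
    edge_axis = lat.edge_unit_vectors()[edge_id]

    state = ablate(state, edge_id, abl["radius"])
    rebuild_interfaces(state, cfg.sim)
    post = simulate(state, cfg.sim, abl["post_steps"], rng,
                    snapshot_stride=abl["render_stride"])
    # movie: last pre-cut frame + post-cut frames
    frames = [pre.snapshots[-1].alive_positions()] + post.node_positions()
    stack, _ = render_frames(frames, cfg.render)
    cut_px = stack.um_to_px(cut_pos)[0]
    half = 3.0 / stack.pixel_size   # analysis boxes within 3 um of the cut
    boxes = [(cut_px[0] - half, cut_px[1] - half,
              cut_px[0] + half, cut_px[1] + half)]
    rec = recoil_analysis(stack, cut_frame=1, cut_position=cut_pos,
                          boxes=boxes, edge_axis=edge_axis,
                          window_size=cfg.analysis["piv_window"],
                          spacing=cfg.analysis["piv_spacing"])
    summary = {"edge": edge_id, "radius_um": abl["radius"],
               "outwardness": rec.outwardness,
               "post_speed_um_s": rec.post_speed,
               "pre_speed_um_s": rec.pre_speed,
               "v_parallel_um_s": rec.v_parallel,
               "v_perpendicular_um_s": rec.v_perpendicular,
               "seed": cfg.seed}
    if outdir is not None:
        stack.save(outdir / "ablation_movie.tif")
    return summary


def run_regime_scenario(cfg: ScenarioConfig, outdir: Path = None) -> dict:
    traj = run_sim(cfg.sim, rows=cfg.lattice["rows"],
                   cols=cfg.lattice["cols"],
                   edge_length=cfg.lattice["edge_length"],
                   snapshot_stride=cfg.analysis["snapshot_stride"],
                   vertex_radius=cfg.analysis["vertex_radius"])
    stack, quant = quantify_regime(
        traj, cfg.render, vertex_radius=cfg.analysis["vertex_radius"],
        line_width=cfg.analysis["line_width"])
    ratio = quant["ratio"].to_numpy()
    m = traj.metrics
    summary = {
        "time_mean_ratio": float(np.nanmean(ratio)),
        "peak_ratio": float(np.nanmax(ratio)),
        "final_frac_intact_edges": float(m["frac_intact_edges"].iloc[-1]),
        "final_n_components": int(m["n_components"].iloc[-1]),
        "late_length_intensity_r": float(
            np.nanmean(quant["length_intensity_r"].to_numpy()[-5:])),
        "seed": cfg.seed,
    }
    if outdir is not None:
        save_trajectory(traj, outdir / "trajectory")
        stack.save(outdir / "movie.tif")
        quant.to_csv(outdir / "quantification.csv", index=False)
    return summary


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Execute the stage chain for a scenario; returns the summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("scenario=%s seed=%d outdir=%s", cfg.scenario, cfg.seed, outdir)
    log.info("resolved config: %s", json.dumps(cfg.to_dict()))

    if cfg.scenario in ("frap_wt", "frap_dunk"):
        summary = run_frap_scenario(cfg, outdir)
        if not np.isfinite(summary["t_half_s"]):
            log.warning("t_half undefined (ratio never reached 0.5)")
    elif cfg.scenario == "ablation":
        summary = run_ablation_scenario(cfg, outdir)
    else:
        summary = run_regime_scenario(cfg, outdir)
        if not np.isfinite(summary["time_mean_ratio"]):
            log.warning("vertex/edge ratio undefined in every frame")

    summary = {"scenario": cfg.scenario, **summary,
               "config": cfg.to_dict()}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
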