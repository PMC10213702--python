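"""End-to-end orchestration: behavioural fitting and network sweeps.

Two entry points mirror the two arms of the analysis:

* :func:`run_behavioral_pipeline` — generate (or load) a plasma curve and
  metric observations, solve the brain pharmacokinetics, grid-search the
  Hill parameters, and validate the fit with a chi-square test.
* :func:`run_grid_pipeline` — sweep the grid-cell network over the
  interaction increment dI, measure periods and activity indices, and fit
  the activity-index Hill law per seed and in aggregate.

Both consume a plain nested-dict configuration (optionally loaded from
YAML), write their tabular outputs as CSV, and return a
:class:`RunReport` that is also serialised to JSON.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PipelineError
from .geometry import PerceptualModulationParams
from .gridcells import (EyeMovementProfile, NetworkConfig, TorusLattice,
                        fit_activity_hill, sweep_activity_index)
from .hillfit import grid_search_fit, predict_metric_component
from .pk import ConcentrationSeries, PlasmaProfile, solve_compartment_ode
from .synthetic import (chlorpromazine_like, psilocybin_like,
                        synth_metric_observations, synth_plasma_profile)

__all__ = ["RunReport", "load_config", "run_behavioral_pipeline", "run_grid_pipeline",
           "read_plasma_csv", "write_concentration_csv"]

log = logging.getLogger("percspace")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

_KNOWN_SECTIONS = {"drug", "pk", "geometry", "fit", "network", "synthetic", "io"}


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    pipeline: str
    config: dict
    outputs: dict = field(default_factory=dict)   # name -> file path
    results: dict = field(default_factory=dict)
    seeds: list = field(default_factory=list)
    version: str = __version__

    def write(self, path) -> Path:
        path = Path(path)
        for name, f in self.outputs.items():
            if not Path(f).exists():
                raise PipelineError("report", f"output {name!r} missing at {f}")
        path.write_text(json.dumps(asdict(self), indent=2, default=_json_default))
        return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def load_config(source) -> dict:
    """Load and validate a configuration mapping (path, YAML text or dict)."""
    if isinstance(source, dict):
        cfg = source
    else:
        p = Path(source)
        cfg = yaml.safe_load(p.read_text()) if p.exists() else yaml.safe_load(str(source))
    if not isinstance(cfg, dict):
        raise ConfigurationError("configuration must be a mapping")
    unknown = sorted(set(cfg) - _KNOWN_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown configuration sections: {unknown}")
    return cfg


def read_plasma_csv(path) -> PlasmaProfile:
    df = pd.read_csv(path)
    return PlasmaProfile(df["time_min"].to_numpy(), df["plasma_conc_pmol_per_ml"].to_numpy())


def write_concentration_csv(series: ConcentrationSeries, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_min": series.times,
                  "brain_conc_pmol_per_cm3": series.concentrations}).to_csv(path, index=False)
    return path


_PRESETS = {"psilocybin": psilocybin_like, "chlorpromazine": chlorpromazine_like}


def run_behavioral_pipeline(config, out_dir) -> RunReport:
    """Synthetic generation -> pharmacokinetics -> Hill fit -> chi-square."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    syn = cfg.get("synthetic", {})
    preset = syn.get("preset", "psilocybin")
    if preset not in _PRESETS:
        raise ConfigurationError(f"synthetic.preset must be one of {sorted(_PRESETS)}")
    seed = int(syn.get("seed", 0))
    noise_sd = float(syn.get("noise_sd", 0.01))
    spec, pk = _PRESETS[preset](noise_sd=noise_sd, seed=seed)
    log.info("behavioural pipeline: preset=%s seed=%d noise_sd=%g", preset, seed, noise_sd)

    table, truth = synth_metric_observations(spec, pk)
    obs_path = out / "observations.csv"
    table.to_csv(obs_path, index=False)

    t_grid = truth["concentration_series"].times
    plasma = truth["plasma"]
    plasma_path = out / "plasma.csv"
    pd.DataFrame({"time_min": plasma.times,
                  "plasma_conc_pmol_per_ml": plasma.concentrations}).to_csv(plasma_path, index=False)
    conc = truth["concentration_series"]
    conc_path = write_concentration_csv(conc, out / "brain_concentration.csv")

    truth_path = out / "synthetic_truth.json"
    truth_path.write_text(json.dumps(
        {k: truth[k] for k in ("n", "k", "mu", "weber_constant", "g_max",
                               "concentrations", "modulation_index", "g_true")},
        indent=2))

    fit_cfg = cfg.get("fit", {})
    n_grid = _maybe_grid(fit_cfg.get("n_grid"))
    k_grid = _maybe_grid(fit_cfg.get("k_grid"))
    mod = spec.mod_truth
    result = grid_search_fit(
        (table["time_min"].to_numpy(), table["g_rr"].to_numpy()),
        conc, mod, n_grid=n_grid, k_grid=k_grid)
    log.info("fit: n=%.3g k=%.4g chi2=%.3g p=%.4g", result.best.n, result.best.k,
             result.chi2, result.chi2_p)

    report = RunReport("behavioral", cfg, seeds=[seed])
    report.outputs = {"observations": str(obs_path), "plasma": str(plasma_path),
                      "brain_concentration": str(conc_path),
                      "synthetic_truth": str(truth_path)}
    report.results = {
        "fitted": {"n": result.best.n, "k": result.best.k},
        "chi2": result.chi2, "chi2_p": result.chi2_p, "dof": result.dof,
        "sse": result.sse, "flags": result.flags,
    }

    predict_times = fit_cfg.get("predict_times")
    if predict_times:
        pt = np.asarray(predict_times, dtype=float)
        sub = ConcentrationSeries(pt, conc.at(pt))
        pred = predict_metric_component(result.best, mod, sub)
        report.results["prediction"] = {"times_min": pt.tolist(), "g": pred.tolist()}

    report.write(out / "report.json")
    return report


def _maybe_grid(spec_item):
    """Grid spec: None, explicit list, or {start, stop, step}."""
    if spec_item is None:
        return None
    if isinstance(spec_item, dict):
        return np.round(np.arange(spec_item["start"],
                                  spec_item["stop"] + 1e-12,
                                  spec_item["step"]), 10)
    return np.asarray(spec_item, dtype=float)


def run_grid_pipeline(config, out_dir) -> RunReport:
    """dI sweep of the attractor network -> activity index -> Hill fit."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    net = cfg.get("network", {})
    mode = net.get("eye_mode", "constant")
    if mode == "fixation":
        raise PipelineError("sweep", "fixation produces constant, not periodic, "
                            "activity; choose constant or random eye movement")
    eyes = EyeMovementProfile(mode=mode,
                              velocity=tuple(net.get("eye_velocity", (0.01, 0.01))))
    ncfg = NetworkConfig(
        interaction_strength=float(net.get("interaction_strength", 0.11)),
        dt=float(net.get("dt", 0.01)), duration=float(net.get("duration", 4.0)))
    lattice = TorusLattice()

    di_max = float(net.get("delta_i_max", 0.30))
    di_step = float(net.get("delta_i_step", 0.01))
    seeds = list(net.get("seeds", [1, 2, 3, 4, 5]))
    delta_is = np.round(np.arange(0.0, di_max + 1e-9, di_step), 10)
    log.info("grid pipeline: %d dI values x %d seeds, I=%g",
             len(delta_is), len(seeds), ncfg.interaction_strength)

    frame = sweep_activity_index(delta_is, seeds, lattice, ncfg, eyes)
    ai_path = out / "ai.csv"
    frame.to_csv(ai_path, index=False)

    per_seed = []
    for seed in seeds:
        sub = frame[(frame.seed == seed) & (frame.delta_I > 0)].dropna()
        if len(sub) < 3:
            raise PipelineError("fit", f"seed {seed}: fewer than 3 usable (dI, AI) points")
        res = fit_activity_hill(sub.delta_I.to_numpy(), sub.AI.to_numpy())
        per_seed.append({"seed": int(seed), "n": res.best.n, "k": res.best.k,
                         "r_squared": res.r_squared})

    med = frame[frame.delta_I > 0].groupby("delta_I")["AI"].median().dropna()
    agg = fit_activity_hill(med.index.to_numpy(), med.to_numpy())

    report = RunReport("grid", cfg, seeds=[int(s) for s in seeds])
    report.outputs = {"ai": str(ai_path)}
    report.results = {
        "per_seed": per_seed,
        "median_n": float(np.median([f["n"] for f in per_seed])),
        "median_k": float(np.median([f["k"] for f in per_seed])),
        "aggregate": {"n": agg.best.n, "k": agg.best.k, "r_squared": agg.r_squared},
    }
    report.write(out / "report.json")
    return report
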