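"""Synthetic study data for every stage of the analysis.

Real studies of drug-modulated visual perception provide (i) a plasma
concentration curve after oral ingestion, (ii) behavioural observations of
the perceived-space metric at a few time points, (iii) rod positions traced
on the perceived frontal plane, and (iv) prism-power series with the area
covered by the test line.  These generators emulate all four from a known
ground truth so that fitting code can be exercised — and its parameter
recovery audited — without any external data.

Plasma curves use the Bateman form of one-compartment oral absorption,

    C_a(t) = dose_scale * ka/(ka - ke) * (exp(-ke t) - exp(-ka t)),

single-peaked and zero at t = 0.  The default specs place the resulting
brain concentrations on both shoulders of the Hill half-effect at the
observation times, which is what makes (n, k) identifiable from a handful
of observations (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .geometry import EllipsoidParams, HillParams, PerceptualModulationParams, modulation_index
from .pk import PKParams, PlasmaProfile, chlorpromazine, psilocybin, solve_compartment_ode

__all__ = [
    "SyntheticSpec",
    "psilocybin_like",
    "chlorpromazine_like",
    "synth_plasma_profile",
    "synth_metric_observations",
    "synth_rod_positions",
    "synth_prism_series",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and sampling plan for one synthetic subject."""

    drug: str                                # "hyper" | "hypo"
    hill_truth: HillParams
    mod_truth: PerceptualModulationParams
    dose_scale: float
    absorption_rate: float                   # ka, 1/min
    elimination_rate: float                  # ke, 1/min
    observation_times: tuple[float, ...]     # minutes
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.drug not in ("hyper", "hypo"):
            raise InvalidInputError("drug must be 'hyper' or 'hypo'")
        if self.absorption_rate <= 0 or self.elimination_rate <= 0:
            raise InvalidInputError("ka and ke must be positive")
        if self.absorption_rate == self.elimination_rate:
            raise InvalidInputError("Bateman form requires ka != ke")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")


def psilocybin_like(noise_sd: float = 0.01, seed: int = 0) -> tuple[SyntheticSpec, PKParams]:
    """Hyperactivation scenario: metric observed at 0/90/180/270 min.

    The dose scale puts the brain concentration at those times on both
    shoulders of the half-effect k = 1.39 pmol/cm^3 (M ~ 0.94 and 0.06),
    as a well-designed dose-response study would.
    """
    spec = SyntheticSpec(
        drug="hyper",
        hill_truth=HillParams(14.8, 1.39),
        mod_truth=PerceptualModulationParams(arousal_coefficient=1),
        dose_scale=30.0, absorption_rate=0.03, elimination_rate=0.006,
        observation_times=(0.0, 90.0, 180.0, 270.0),
        noise_sd=noise_sd, seed=seed,
    )
    return spec, psilocybin()


def chlorpromazine_like(noise_sd: float = 0.01, seed: int = 0) -> tuple[SyntheticSpec, PKParams]:
    """Hypoactivation scenario: metric observed at 0/210/450 min.

    Chlorpromazine eliminates slowly (ke = 4e-4/min, half-life ~29 h), so
    both post-baseline observations sit inside the steep transition band of
    the very sharp Hill law (n = 50.3) around k = 4.96 pmol/cm^3.
    """
    spec = SyntheticSpec(
        drug="hypo",
        hill_truth=HillParams(50.3, 4.96),
        mod_truth=PerceptualModulationParams(arousal_coefficient=-1),
        dose_scale=65.0, absorption_rate=0.02, elimination_rate=4e-4,
        observation_times=(0.0, 210.0, 450.0),
        noise_sd=noise_sd, seed=seed,
    )
    return spec, chlorpromazine()


def synth_plasma_profile(spec: SyntheticSpec, t_grid) -> PlasmaProfile:
    """Bateman plasma curve sampled on ``t_grid`` (minutes)."""
    t = np.asarray(t_grid, dtype=float)
    ka, ke = spec.absorption_rate, spec.elimination_rate
    ca = spec.dose_scale * (ka / (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return PlasmaProfile(t, np.maximum(ca, 0.0))


def _simulation_grid(spec: SyntheticSpec) -> np.ndarray:
    t_end = max(spec.observation_times) + 30.0
    return np.arange(0.0, t_end + 0.5, 0.5)


def synth_metric_observations(spec: SyntheticSpec, pk: PKParams):
    """Noisy metric-component observations plus the sealed truth record.

    Runs plasma -> brain ODE -> modulation index -> perceived metric at the
    observation times and adds seeded Gaussian noise per component.
    Returns ``(table, truth)`` where the table has columns
    ``time_min, g_rr, g_thth, g_phph`` and ``truth`` holds the generating
    parameters and the noiseless values — for post-hoc recovery checks
    only, never as fitting input.
    """
    t_grid = _simulation_grid(spec)
    if max(spec.observation_times) > t_grid[-1]:
        raise InvalidInputError("observation times exceed the simulated window")
    plasma = synth_plasma_profile(spec, t_grid)
    conc = solve_compartment_ode(pk, plasma, t_grid)
    c_obs = conc.at(np.asarray(spec.observation_times))
    m = np.asarray(modulation_index(c_obs, spec.hill_truth))

    mod = spec.mod_truth
    mu, p = mod.arousal_coefficient, mod.weber_constant
    g_true = np.stack([1.0 + mu * m * g / p for g in mod.g_max], axis=1)

    rng = np.random.default_rng(spec.seed)
    g_noisy = g_true + rng.normal(0.0, spec.noise_sd, size=g_true.shape)

    table = pd.DataFrame({
        "time_min": spec.observation_times,
        "g_rr": g_noisy[:, 0],
        "g_thth": g_noisy[:, 1],
        "g_phph": g_noisy[:, 2],
    })
    truth = {
        "n": spec.hill_truth.n,
        "k": spec.hill_truth.k,
        "mu": mu,
        "weber_constant": p,
        "g_max": list(mod.g_max),
        "concentrations": c_obs.tolist(),
        "modulation_index": m.tolist(),
        "g_true": g_true.tolist(),
        "concentration_series": conc,
        "plasma": plasma,
    }
    return table, truth


def synth_rod_positions(ellipse: EllipsoidParams, center=(0.0, 0.0),
                        n_points: int = 12, noise_sd: float = 0.0,
                        seed: int = 0) -> pd.DataFrame:
    """Rod positions near a rotated ellipse (columns ``x_cm, y_cm``).

    Points at uniformly spaced parameter angles plus seeded Gaussian noise.
    """
    if n_points < 5:
        raise InvalidInputError("need at least 5 rod positions")
    t = 2.0 * np.pi * np.arange(n_points) / n_points
    a, b, phi = ellipse.semi_axis_a, ellipse.semi_axis_b, ellipse.rotation_angle
    x0 = a * np.cos(t)
    y0 = b * np.sin(t)
    x = center[0] + x0 * np.cos(phi) - y0 * np.sin(phi)
    y = center[1] + x0 * np.sin(phi) + y0 * np.cos(phi)
    rng = np.random.default_rng(seed)
    x = x + rng.normal(0.0, noise_sd, n_points)
    y = y + rng.normal(0.0, noise_sd, n_points)
    return pd.DataFrame({"x_cm": x, "y_cm": y})


def synth_prism_series(spec: SyntheticSpec, pk: PKParams, times,
                       area_ref: float = 100.0,
                       prism_power_ref: float = 10.0) -> pd.DataFrame:
    """Spatial-distortion-threshold series (``time_min, prism_power,
    line_area``).

    The line area satisfies area(t) = area_ref / g_true(t) so that the
    equal-perceived-area inference inverts it exactly; the minimum prism
    power to perceive distortion is reported as prism_power_ref / g_true(t)
    — hyperactivation (g > 1) lowers the threshold, hypoactivation raises
    it.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise InvalidInputError("times must be non-empty")
    t_grid = np.arange(0.0, float(times.max()) + 30.5, 0.5)
    plasma = synth_plasma_profile(spec, t_grid)
    conc = solve_compartment_ode(pk, plasma, t_grid)
    m = np.asarray(modulation_index(conc.at(times), spec.hill_truth))
    mod = spec.mod_truth
    g_true = 1.0 + mod.arousal_coefficient * m * mod.g_max[0] / mod.weber_constant
    return pd.DataFrame({
        "time_min": times,
        "prism_power": prism_power_ref / g_true,
        "line_area": area_ref / g_true,
    })
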