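"""Grid-search least-squares fitting of Hill parameters.

The observed quantity (a metric-tensor diagonal component, or the network
activity index) is predicted from a Hill law of the driving variable (brain
drug concentration, or interaction increment).  The sum of squared
residuals (SSE) is evaluated exhaustively on an (n, k) grid; the minimiser
is the fit, the full SSE surface is returned for inspection, and a Pearson
chi-square statistic against the best prediction quantifies goodness of
fit.  Ties are broken toward the smallest n, then the smallest k, so the
result is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import expit

from .errors import InvalidInputError
from .geometry import HillParams, PerceptualModulationParams
from .pk import ConcentrationSeries

__all__ = [
    "HillFitResult",
    "predict_metric_component",
    "grid_search_fit",
    "chi_square_gof",
    "default_n_grid",
    "default_k_grid",
]


def default_n_grid() -> np.ndarray:
    """n in [0.1, 100] with step 0.1 — brackets published behavioural fits."""
    return np.round(np.arange(0.1, 100.0 + 1e-9, 0.1), 10)


def default_k_grid(driver_values) -> np.ndarray:
    """500 uniform k values spanning [max(1e-3, 0.01*max), 2*max] of the driver."""
    cmax = float(np.max(driver_values))
    if cmax <= 0:
        raise InvalidInputError("driver values must contain a positive entry")
    return np.linspace(max(1e-3, 0.01 * cmax), 2.0 * cmax, 500)


def _hill(c: np.ndarray, n: float | np.ndarray, k: np.ndarray) -> np.ndarray:
    """Stable Hill evaluation, broadcasting (k grid) x (driver values)."""
    out = np.zeros(np.broadcast_shapes(np.shape(k) + (1,), (1, len(c))))
    pos = c > 0
    with np.errstate(divide="ignore"):
        out[:, pos] = expit(-np.asarray(n) * (np.log(k)[:, None] - np.log(c[pos])[None, :]))
    return out


@dataclass
class HillFitResult:
    """Outcome of a grid search: best parameters, SSE surface and fit
    diagnostics."""

    best: HillParams
    n_grid: np.ndarray
    k_grid: np.ndarray
    sse_surface: np.ndarray  # (len(n_grid), len(k_grid))
    chi2: float
    chi2_p: float
    dof: int
    r_squared: float
    predicted: np.ndarray
    flags: dict = field(default_factory=dict)

    @property
    def sse(self) -> float:
        return float(self.sse_surface.min())


def predict_metric_component(hill: HillParams, mod: PerceptualModulationParams,
                             concentrations: ConcentrationSeries,
                             baseline: float = 1.0, component: int = 0) -> np.ndarray:
    """Model prediction g(t) = baseline + mu * M(C(t)) * g_max / P at the
    fixation point (r = 1, theta = 0)."""
    c = np.asarray(concentrations.concentrations, dtype=float)
    if np.any(c < 0):
        raise InvalidInputError("concentrations must be non-negative")
    m = _hill(c, hill.n, np.array([hill.k]))[0]
    mu = mod.arousal_coefficient
    return baseline + mu * m * mod.g_max[component] / mod.weber_constant


def _sse_over_grid(driver: np.ndarray, observed: np.ndarray,
                   n_grid: np.ndarray, k_grid: np.ndarray,
                   scale: float, baseline: float) -> np.ndarray:
    """SSE of ``baseline + scale * M(driver; n, k)`` against ``observed``.

    Chunked over the n axis to bound memory for long driver series.
    """
    sse = np.empty((len(n_grid), len(k_grid)))
    chunk = max(1, int(4e6 / (len(k_grid) * max(len(driver), 1))))
    logk = np.log(k_grid)
    pos = driver > 0
    logc = np.log(driver[pos])
    for start in range(0, len(n_grid), chunk):
        ns = n_grid[start:start + chunk]
        m = np.zeros((len(ns), len(k_grid), len(driver)))
        m[:, :, pos] = expit(-ns[:, None, None] * (logk[None, :, None] - logc[None, None, :]))
        resid = baseline + scale * m - observed[None, None, :]
        sse[start:start + chunk] = (resid**2).sum(axis=2)
    return sse


def grid_search_fit(observations, concentrations: ConcentrationSeries,
                    mod: PerceptualModulationParams,
                    n_grid=None, k_grid=None,
                    baseline: float = 1.0, component: int = 0,
                    dof_reduction: int = 2) -> HillFitResult:
    """Exhaustive least-squares fit of (n, k) to metric observations.

    ``observations`` is a pair of equal-length sequences ``(times, values)``;
    the concentration at each observation time is obtained by linear
    interpolation of ``concentrations``.
    """
    obs_t = np.asarray(observations[0], dtype=float)
    obs_v = np.asarray(observations[1], dtype=float)
    if len(obs_t) != len(obs_v):
        raise InvalidInputError("observation times and values must have equal length")
    if len(obs_v) < 3:
        raise InvalidInputError("at least 3 observations are required")

    driver = np.asarray(concentrations.at(obs_t), dtype=float)
    n_grid = default_n_grid() if n_grid is None else np.asarray(n_grid, dtype=float)
    k_grid = default_k_grid(driver) if k_grid is None else np.asarray(k_grid, dtype=float)

    scale = mod.arousal_coefficient * mod.g_max[component] / mod.weber_constant
    sse = _sse_over_grid(driver, obs_v, n_grid, k_grid, scale, baseline)

    flags: dict = {}
    if np.ptp(obs_v) == 0:
        flags["flat_surface"] = "all observations identical; SSE surface is degenerate"

    # first flat-order minimum = smallest n, then smallest k
    i, j = np.unravel_index(int(np.argmin(sse)), sse.shape)
    best = HillParams(float(n_grid[i]), float(k_grid[j]))

    m_best = _hill(driver, best.n, np.array([best.k]))[0]
    if m_best.max() < 1e-6:
        flags["uninformative"] = "best fit leaves the modulation index ~0 at all observations"
    predicted = baseline + scale * m_best

    chi2, p, dof = chi_square_gof(obs_v, predicted, dof_reduction)
    ss_tot = float(((obs_v - obs_v.mean()) ** 2).sum())
    r2 = 1.0 - float(sse[i, j]) / ss_tot if ss_tot > 0 else float("nan")
    return HillFitResult(best, n_grid, k_grid, sse, chi2, p, dof, r2, predicted, flags)


def chi_square_gof(observed, predicted, dof_reduction: int = 2):
    """Pearson goodness of fit: chi2 = sum (obs - pred)^2 / pred.

    Returns ``(chi2, p, dof)`` with ``dof = N - dof_reduction`` and p the
    upper-tail chi-square probability.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise InvalidInputError("observed and predicted must have the same shape")
    if np.any(pred <= 0):
        raise InvalidInputError("predicted values must be positive for Pearson chi-square")
    if len(obs) < dof_reduction + 1:
        raise InvalidInputError("need more observations than fitted parameters")
    chi2 = float(((obs - pred) ** 2 / pred).sum())
    dof = len(obs) - dof_reduction
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, p, dof
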