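"""Continuous-attractor grid-cell network on a torus.

Ninety nodes (9 around the minor circle, 10 around the major circle) are
placed on a flat torus with circumferences 0.5 and 0.61.  Connection
weights follow a Gaussian of the wrapped (toroidal) distance between nodes,
offset by the eyeball velocity vector E(t) which implements path
integration of gaze, minus a uniform inhibition T:

    W_ij(t) = (I + dI) * exp(-||z_i - z_j + E(t)||^2 / s^2) - T

where the interaction increment dI >= 0 models the neuromodulating drug
acting uniformly on the network.  Node activities update as

    P_j(t+dt) = (1 - lam) * sum_i P_i W_ij + lam * (sum_i P_i W_ij / sum_i P_i)

with stabilisation strength lam.  ``step_network`` implements this update
literally; ``simulate`` additionally clips negative activities to zero
after each step by default (``NetworkConfig.rectify``), since the update
rule otherwise drives the total activity negative from the prescribed
random initial condition (see docs/methods.md).

Periodic activation of the nodes under constant eye movement is quantified
by the distance L (in time steps) between activations, measured from the
activity autocorrelation; the activity index AI = 1 - L/L_max then maps the
drug effect onto [0, 1], and AI(dI) is fitted with a Hill law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CollapsedActivityError, InvalidInputError, NumericalError, PipelineError
from .geometry import HillParams
from .hillfit import HillFitResult, _sse_over_grid, chi_square_gof, default_n_grid, _hill

__all__ = [
    "TorusLattice",
    "NetworkConfig",
    "EyeMovementProfile",
    "DrugModulation",
    "ActivityRaster",
    "PeriodMeasurement",
    "toroidal_distance",
    "compute_weights",
    "step_network",
    "simulate",
    "measure_period_L",
    "activity_index",
    "fit_activity_hill",
    "sweep_activity_index",
]

_RESCALE_LIMIT = 1e100


@dataclass(frozen=True)
class TorusLattice:
    """Node layout: row-major over (minor, major) indices, so node
    ``m * n_major + j`` sits at minor index m, major index j; coordinates
    wrap modulo the circumferences."""

    n_minor: int = 9
    n_major: int = 10
    circumference_minor: float = 0.5
    circumference_major: float = 0.61

    def __post_init__(self):
        if self.n_minor < 1 or self.n_major < 1:
            raise InvalidInputError("node counts must be positive")
        if self.circumference_minor <= 0 or self.circumference_major <= 0:
            raise InvalidInputError("circumferences must be positive")

    @property
    def n_nodes(self) -> int:
        return self.n_minor * self.n_major

    @property
    def circumferences(self) -> tuple[float, float]:
        return (self.circumference_minor, self.circumference_major)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 2) array of evenly spaced (u, v) torus coordinates."""
        u = self.circumference_minor * np.arange(self.n_minor) / self.n_minor
        v = self.circumference_major * np.arange(self.n_major) / self.n_major
        uu, vv = np.meshgrid(u, v, indexing="ij")
        return np.column_stack([uu.ravel(), vv.ravel()])


@dataclass(frozen=True)
class NetworkConfig:
    """Simulation parameters.

    ``interaction_strength`` (I) is not fixed by the network geometry; the
    default 0.11 is the smallest value at which the patterned attractor
    forms reliably from the random initial condition (see docs/methods.md).
    """

    interaction_strength: float = 0.11
    gaussian_width: float = 0.24
    inhibition_offset: float = 0.05
    stabilization: float = 0.8
    dt: float = 0.01            # seconds
    duration: float = 4.0       # seconds
    seed: int = 0
    rectify: bool = True

    def __post_init__(self):
        if not 0.0 <= self.stabilization <= 1.0:
            raise InvalidInputError("stabilization must lie in [0, 1]")
        if self.gaussian_width <= 0:
            raise InvalidInputError("gaussian_width must be positive")
        if self.dt <= 0 or self.duration <= 0:
            raise InvalidInputError("dt and duration must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class EyeMovementProfile:
    """Eyeball velocity feeding path integration.

    ``fixation`` keeps E = 0; ``constant`` applies ``velocity`` (torus units
    per step) at every step; ``random`` draws a fresh Gaussian velocity of
    scale ``random_step_sd`` each step (seeded)."""

    mode: str = "constant"
    velocity: tuple[float, float] = (0.01, 0.01)
    random_step_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("fixation", "constant", "random"):
            raise InvalidInputError("mode must be fixation, constant or random")

    def offsets(self, n_steps: int) -> np.ndarray:
        """(n_steps, 2) per-step velocity offsets."""
        if self.mode == "fixation":
            return np.zeros((n_steps, 2))
        if self.mode == "constant":
            return np.tile(np.asarray(self.velocity, dtype=float), (n_steps, 1))
        rng = np.random.default_rng(self.seed)
        return rng.normal(0.0, self.random_step_sd, size=(n_steps, 2))


@dataclass(frozen=True)
class DrugModulation:
    """Spatially uniform interaction increment dI, constant or scheduled
    as a (times_s, values) series interpolated per step."""

    delta_i: float = 0.0
    schedule: tuple | None = None  # (times_s, values)

    def __post_init__(self):
        if self.schedule is None and self.delta_i < 0:
            raise InvalidInputError("delta_i must be non-negative")
        if self.schedule is not None:
            t, v = (np.asarray(x, dtype=float) for x in self.schedule)
            if len(t) != len(v) or np.any(v < 0):
                raise InvalidInputError("schedule must be equal-length with dI >= 0")

    def values(self, times_s: np.ndarray) -> np.ndarray:
        if self.schedule is None:
            return np.full(len(times_s), float(self.delta_i))
        t, v = (np.asarray(x, dtype=float) for x in self.schedule)
        return np.interp(times_s, t, v)


@dataclass
class ActivityRaster:
    """Node x time activity matrix P_j(t), node ordering row-major over
    (minor, major)."""

    activities: np.ndarray
    dt: float
    rescaled: bool = False

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.activities.shape[1])

    def top_decile_nodes(self, t_s: float) -> set[int]:
        """Indices of the top 10% most active nodes at time ``t_s``."""
        col = self.activities[:, int(round(t_s / self.dt))]
        n_top = max(1, len(col) // 10)
        return set(np.argsort(col, kind="stable")[::-1][:n_top].tolist())


def toroidal_distance(z_i, z_j, offset=(0.0, 0.0),
                      circumferences=(0.5, 0.61)) -> float:
    """Wrapped Euclidean distance ||z_i - z_j + E|| on the flat torus.

    Each axis difference (after adding the offset) is mapped into
    [-c/2, c/2] for circumference c.
    """
    d = np.asarray(z_i, dtype=float) - np.asarray(z_j, dtype=float) + np.asarray(offset, dtype=float)
    c = np.asarray(circumferences, dtype=float)
    d = (d + c / 2.0) % c - c / 2.0
    return float(np.sqrt((d**2).sum(axis=-1)))


def compute_weights(lattice: TorusLattice, cfg: NetworkConfig,
                    offset=(0.0, 0.0), delta_i: float = 0.0) -> np.ndarray:
    """N x N weight matrix W_ij = (I + dI) exp(-d_ij^2/s^2) - T with
    d_ij = ||z_i - z_j + E||_toroidal."""
    if delta_i < 0:
        raise InvalidInputError("delta_i must be non-negative")
    z = lattice.coordinates
    c = np.asarray(lattice.circumferences)
    d = z[:, None, :] - z[None, :, :] + np.asarray(offset, dtype=float)
    d = (d + c / 2.0) % c - c / 2.0
    d2 = (d**2).sum(axis=-1)
    return ((cfg.interaction_strength + delta_i) * np.exp(-d2 / cfg.gaussian_width**2)
            - cfg.inhibition_offset)


def step_network(activities: np.ndarray, W: np.ndarray, lam: float) -> np.ndarray:
    """One literal update step (no rectification):

    P_j' = (1 - lam) * (P W)_j + lam * (P W)_j / sum(P)
    """
    p = np.asarray(activities, dtype=float)
    s = p.sum()
    if s <= 1e-12:
        raise CollapsedActivityError(-1, "total activity below 1e-12")
    q = p @ W
    return (1.0 - lam) * q + lam * q / s


def simulate(lattice: TorusLattice, cfg: NetworkConfig,
             eyes: EyeMovementProfile, drug: DrugModulation) -> ActivityRaster:
    """Run the network for cfg.duration seconds from the seeded random
    initial condition (uniform in [0, 1/N]).

    Weights are recomputed whenever the eye offset or the scheduled dI
    changes.  With ``cfg.rectify`` (default) negative activities are
    clipped to zero after each step; the positively homogeneous structure
    of the update lets the raster be renormalised if values exceed 1e100
    (flagged on the result), which leaves the activity pattern unchanged.
    """
    n_steps = cfg.n_steps
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(0.0, 1.0 / lattice.n_nodes, size=lattice.n_nodes)

    offsets = eyes.offsets(n_steps)
    dis = drug.values(cfg.dt * np.arange(n_steps))

    raster = np.empty((lattice.n_nodes, n_steps + 1))
    raster[:, 0] = p
    lam = cfg.stabilization
    rescaled = False

    w = None
    last_key = None
    for t in range(n_steps):
        key = (offsets[t, 0], offsets[t, 1], dis[t])
        if key != last_key:
            w = compute_weights(lattice, cfg, offsets[t], dis[t])
            last_key = key
        s = p.sum()
        if s <= 1e-12:
            raise CollapsedActivityError(t)
        q = p @ w
        p = (1.0 - lam) * q + lam * q / s
        if cfg.rectify:
            p = np.maximum(p, 0.0)
        if not np.all(np.isfinite(p)):
            raise NumericalError(f"non-finite activity at step {t + 1}")
        m = np.abs(p).max()
        if cfg.rectify and m > _RESCALE_LIMIT:
            p = p / m
            rescaled = True
        raster[:, t + 1] = p
    return ActivityRaster(raster, cfg.dt, rescaled)


@dataclass(frozen=True)
class PeriodMeasurement:
    """Result of the periodic-activation distance measurement.

    ``status`` is ``"periodic"`` (L set), ``"continuous"`` (activity
    constant over the window: zero distance between activations, L = 0) or
    ``"aperiodic"`` (no autocorrelation peak above threshold, L is None).
    """

    L: float | None
    status: str
    peak_correlation: float = float("nan")


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    """Per-lag Pearson correlation of the signal with its lagged self.

    Each lag correlates only the overlapping samples, so a periodic signal
    scores ~1 at its period regardless of the window length (the raw
    sum-product estimate is biased low by the shrinking overlap).  Lags up
    to half the window are considered.
    """
    n = len(x)
    max_lag = n // 2
    ac = np.empty(max_lag + 1)
    ac[0] = 1.0
    for lag in range(1, max_lag + 1):
        a = x[:-lag]
        b = x[lag:]
        sa = a.std()
        sb = b.std()
        if sa == 0 or sb == 0:
            ac[lag] = 0.0
        else:
            ac[lag] = ((a - a.mean()) * (b - b.mean())).mean() / (sa * sb)
    return ac


def _first_autocorr_peak(x: np.ndarray, threshold: float):
    """Lag and height of the first positive-lag local autocorrelation
    maximum above ``threshold``, or None."""
    if float(((x - x.mean()) ** 2).sum()) <= 0:
        return None
    ac = _autocorrelation(x)
    for lag in range(1, len(ac) - 1):
        if ac[lag] > ac[lag - 1] and ac[lag] >= ac[lag + 1] and ac[lag] > threshold:
            return lag, float(ac[lag])
    return None


def measure_period_L(raster: ActivityRaster, transient_s: float = 1.0,
                     threshold: float = 0.2,
                     flat_tol: float = 1e-8) -> PeriodMeasurement:
    """Distance L (time steps) between periodic activations of the nodes.

    The raster after the transient is split into an activity *pattern*
    (each time step divided by its instantaneous maximum, which removes any
    overall growth) and a common *envelope* (the per-step maximum itself).
    When the pattern varies — a travelling bump — each node's period is the
    lag of the first positive-lag autocorrelation maximum above
    ``threshold``, and L is the median over nodes.  When the pattern is
    static (relative node variance below ``flat_tol``), periodicity can
    only live in the envelope: a flat or monotonically growing envelope
    means the nodes are continuously active, i.e. zero distance between
    activations (L = 0); an oscillating envelope yields L from its own
    autocorrelation.  If no autocorrelation peak clears the threshold the
    signal is reported as aperiodic (L is None), not an exception.
    """
    start = int(round(transient_s / raster.dt))
    r = raster.activities[:, start:]
    if r.shape[1] < 8:
        raise InvalidInputError("raster too short after the transient")
    env = r.max(axis=0)
    col_max = np.where(env > 0, env, 1.0)
    pattern = r / col_max

    lags, peaks, n_flat = [], [], 0
    for sig in pattern:
        x = sig - sig.mean()
        if (x * x).sum() < flat_tol * len(sig) * max(sig.mean() ** 2, 1e-300):
            n_flat += 1
            continue
        hit = _first_autocorr_peak(sig, threshold)
        if hit is not None:
            lags.append(hit[0])
            peaks.append(hit[1])

    if n_flat > pattern.shape[0] // 2:
        # static pattern: look at the common envelope
        e = env - env.mean()
        if (e * e).sum() < flat_tol * len(env) * max(env.mean() ** 2, 1e-300):
            return PeriodMeasurement(0.0, "continuous", 1.0)
        if np.mean(np.diff(env) >= 0) > 0.95:
            return PeriodMeasurement(0.0, "continuous", 1.0)
        hit = _first_autocorr_peak(env, threshold)
        if hit is None:
            return PeriodMeasurement(None, "aperiodic")
        return PeriodMeasurement(float(hit[0]), "periodic", hit[1])

    if not lags:
        return PeriodMeasurement(None, "aperiodic")
    return PeriodMeasurement(float(np.median(lags)), "periodic", float(np.median(peaks)))


def activity_index(L: float, L_max: float) -> float:
    """AI = 1 - L / L_max, in [0, 1]."""
    if L_max <= 0:
        raise InvalidInputError("L_max must be positive")
    if not 0 <= L <= L_max:
        raise InvalidInputError("L must lie in [0, L_max]")
    return 1.0 - L / L_max


def fit_activity_hill(delta_i_values, ai_values,
                      n_grid=None, k_grid=None) -> HillFitResult:
    """Grid-search least-squares fit of AI(dI) = 1 / (1 + (k/dI)^n).

    Same machinery as the behavioural fit, with the interaction increment
    in the role of the concentration and the activity index predicted by
    the bare Hill curve (baseline 0, unit scale).
    """
    di = np.asarray(delta_i_values, dtype=float)
    ai = np.asarray(ai_values, dtype=float)
    if len(di) != len(ai):
        raise InvalidInputError("delta_i and AI series must have equal length")
    if len(di) < 3:
        raise InvalidInputError("at least 3 (delta_i, AI) pairs are required")
    flags: dict = {}
    if not np.any(ai > 0):
        flags["uninformative"] = "all activity indices are zero"

    n_grid = default_n_grid() if n_grid is None else np.asarray(n_grid, dtype=float)
    if k_grid is None:
        dmax = float(di.max())
        k_grid = np.linspace(max(1e-3, 0.01 * dmax), 2.0 * dmax, 500)
    else:
        k_grid = np.asarray(k_grid, dtype=float)

    sse = _sse_over_grid(di, ai, n_grid, k_grid, scale=1.0, baseline=0.0)
    i, j = np.unravel_index(int(np.argmin(sse)), sse.shape)
    best = HillParams(float(n_grid[i]), float(k_grid[j]))
    predicted = _hill(di, best.n, np.array([best.k]))[0]

    ss_tot = float(((ai - ai.mean()) ** 2).sum())
    r2 = 1.0 - float(sse[i, j]) / ss_tot if ss_tot > 0 else float("nan")
    # chi-square only over strictly positive predictions
    pos = predicted > 0
    if pos.sum() > 2:
        chi2, p, dof = chi_square_gof(ai[pos], predicted[pos], 2)
    else:
        chi2, p, dof = float("nan"), float("nan"), 0
    return HillFitResult(best, n_grid, k_grid, sse, chi2, p, dof, r2, predicted, flags)


def sweep_activity_index(delta_is, seeds, lattice: TorusLattice | None = None,
                         cfg: NetworkConfig | None = None,
                         eyes: EyeMovementProfile | None = None,
                         transient_s: float = 1.0) -> pd.DataFrame:
    """Simulate the network over a dI sweep for several seeds.

    Returns a tidy frame with columns ``delta_I, seed, L_steps, AI``.
    L_max is the per-seed baseline period L(dI = 0); a seed whose baseline
    is not periodic raises :class:`PipelineError` (the eye velocity should
    be adjusted).  AI values are clipped into [0, 1]; dI points without a
    measurable period (aperiodic) carry NaN.
    """
    lattice = lattice or TorusLattice()
    cfg = cfg or NetworkConfig()
    eyes = eyes or EyeMovementProfile()
    if eyes.mode == "fixation":
        raise PipelineError("sweep", "periodic activation requires eye movement; "
                            "fixation holds a static activity bump")
    delta_is = np.asarray(delta_is, dtype=float)
    if delta_is[0] != 0.0:
        delta_is = np.concatenate([[0.0], delta_is])

    rows = []
    for seed in seeds:
        run_cfg = NetworkConfig(**{**cfg.__dict__, "seed": int(seed)})
        base = measure_period_L(
            simulate(lattice, run_cfg, eyes, DrugModulation(0.0)), transient_s)
        if base.status != "periodic" or not base.L:
            raise PipelineError(
                "sweep", f"baseline (dI=0, seed {seed}) is not periodic; "
                "adjust the eye velocity")
        l_max = base.L
        for di in delta_is:
            meas = (base if di == 0.0 else measure_period_L(
                simulate(lattice, run_cfg, eyes, DrugModulation(float(di))), transient_s))
            if meas.L is None:
                rows.append((di, seed, np.nan, np.nan))
            else:
                ai = min(1.0, max(0.0, 1.0 - meas.L / l_max))
                rows.append((di, seed, meas.L, ai))
    return pd.DataFrame(rows, columns=["delta_I", "seed", "L_steps", "AI"])
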