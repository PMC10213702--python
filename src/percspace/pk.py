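"""Brain pharmacokinetics of orally ingested neuromodulating drugs.

The brain parenchyma is treated as a porous medium: drug molecules cross the
blood-brain barrier and diffuse through the extracellular space (ECS), where
the effective diffusivity is reduced by the square of the tortuosity and the
accessible volume by the ECS volume fraction.  The governing equation for the
ECS concentration C(x, t) is

    dC/dt = (D / TS^2) * laplacian(C) - (k_pi * C - k_po * C_a(t)) / alpha

with C_a(t) the plasma concentration, k_po the blood->brain and k_pi the
brain->blood transfer coefficient.  For a spatially uniform state the
diffusion term vanishes and the dynamics reduce to a linear one-compartment
ODE, which is the default solver here; the explicit 3-D finite-difference
solver is provided as a verification mode on small grids.

Internal unit system: minutes, centimetres, picomoles.  Tissue density is
taken as 1 g/cm^3 so that k_po (ml per g tissue per minute) acts
dimensionally as 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError, NumericalError

__all__ = [
    "PKParams",
    "PlasmaProfile",
    "ConcentrationSeries",
    "SpatialGrid",
    "psilocybin",
    "chlorpromazine",
    "solve_compartment_ode",
    "solve_pde_3d",
    "interpolate_parameter_by_mw",
    "steady_state_concentration",
]

#: conversion factor m^2/s -> cm^2/min
_M2_PER_S_TO_CM2_PER_MIN = 1.0e4 * 60.0


@dataclass(frozen=True)
class PKParams:
    """Drug- and tissue-specific constants of the ECS transport model.

    Parameters
    ----------
    diffusivity_ecs : float
        Diffusivity of the drug in the extracellular space, cm^2/min.
    tortuosity : float
        Ratio of the actual diffusion path to straight-line displacement
        (dimensionless, >= 1); effective diffusivity is D/TS^2.
    volume_fraction : float
        Extracellular volume fraction alpha, in (0, 1].
    k_pi : float
        Brain -> blood transfer coefficient, 1/min.
    k_po : float
        Blood -> brain transfer coefficient, 1/min (ml/g/min at unit tissue
        density).
    """

    diffusivity_ecs: float
    tortuosity: float
    volume_fraction: float
    k_pi: float
    k_po: float
    drug_name: str = ""
    molecular_weight: float = float("nan")

    def __post_init__(self):
        # zero is admitted for the rates and diffusivity so that pure-diffusion
        # and decoupled-voxel limits can be exercised
        for name in ("diffusivity_ecs", "k_pi", "k_po"):
            if not getattr(self, name) >= 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if not 0 < self.volume_fraction <= 1:
            raise InvalidInputError("volume_fraction must lie in (0, 1]")
        if not self.tortuosity >= 1:
            raise InvalidInputError("tortuosity must be >= 1")

    @property
    def effective_diffusivity(self) -> float:
        """D / TS^2, cm^2/min."""
        return self.diffusivity_ecs / self.tortuosity**2


def psilocybin() -> PKParams:
    """Preset constants for psilocybin.

    ECS diffusivity 3.052e-10 m^2/s (40% of the free-water value at 37 C),
    transfer coefficients interpolated over reference tracers by molecular
    weight; tortuosity 1.6 and ECS volume fraction 0.2 are drug-independent
    averages for normal brain tissue.
    """
    return PKParams(
        diffusivity_ecs=3.052e-10 * _M2_PER_S_TO_CM2_PER_MIN,
        tortuosity=1.6,
        volume_fraction=0.2,
        k_pi=16.38e-3,
        k_po=1.4e-3,
        drug_name="psilocybin",
        molecular_weight=284.25,
    )


def chlorpromazine() -> PKParams:
    """Preset constants for chlorpromazine (same provenance as psilocybin)."""
    return PKParams(
        diffusivity_ecs=2.9e-10 * _M2_PER_S_TO_CM2_PER_MIN,
        tortuosity=1.6,
        volume_fraction=0.2,
        k_pi=16.65e-3,
        k_po=1.43e-3,
        drug_name="chlorpromazine",
        molecular_weight=318.86,
    )


def _validated_series(times, values, value_name: str):
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
        raise InvalidInputError("times and concentrations must be equal-length 1-D series")
    if len(t) >= 2 and not np.all(np.diff(t) > 0):
        raise InvalidInputError("times must be strictly increasing")
    if np.any(v < 0):
        raise InvalidInputError(f"{value_name} must be non-negative")
    return t, v


@dataclass(frozen=True)
class PlasmaProfile:
    """Sampled plasma concentration C_a(t).

    Piecewise-linear between samples, zero before the first and after the
    last sample.  Units: minutes, picomoles/ml.
    """

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        t, v = _validated_series(self.times, self.concentrations, "plasma concentrations")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", v)

    def concentration_at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.concentrations,
                         left=0.0, right=0.0)


@dataclass(frozen=True)
class ConcentrationSeries:
    """Brain ECS concentration C(t); minutes, picomoles/cm^3."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        t, v = _validated_series(self.times, self.concentrations, "concentrations")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", v)

    def at(self, t) -> np.ndarray:
        """Piecewise-linear interpolation (clamped to the end values)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.concentrations)


@dataclass(frozen=True)
class SpatialGrid:
    """Regular voxel grid with zero-flux (reflecting) boundary contract."""

    shape: tuple[int, int, int]
    spacing: float  # cm per voxel edge

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise InvalidInputError("grid shape must be three counts >= 1")
        if not self.spacing > 0:
            raise InvalidInputError("grid spacing must be positive")


def solve_compartment_ode(pk: PKParams, plasma: PlasmaProfile, t_grid,
                          c0: float = 0.0, method: str = "exact") -> ConcentrationSeries:
    """Solve the spatially uniform reduction dC/dt = (k_po*C_a - k_pi*C)/alpha.

    ``method="exact"`` integrates the linear ODE in closed form on each
    interval (the plasma forcing is piecewise linear, so the solution is a
    sum of an exponential and a linear-in-t particular term); this is exact
    to round-off at the sample points.  ``method="euler"`` uses the forward
    Euler steps of ``t_grid`` and matches the time discretisation of
    :func:`solve_pde_3d`.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
        raise InvalidInputError("t_grid must be a strictly increasing 1-D array")
    if method not in ("exact", "euler"):
        raise InvalidInputError(f"unknown method {method!r}")

    b = pk.k_pi / pk.volume_fraction          # 1/min decay rate
    gain = pk.k_po / pk.volume_fraction       # 1/min forcing gain

    if method == "euler":
        dt = np.diff(t)
        dt_max = 2.0 / b
        if np.any(dt > dt_max):
            raise ConfigurationError(
                f"explicit Euler step {dt.max():g} min exceeds the stability bound "
                f"2*alpha/k_pi = {dt_max:g} min")
        c = np.empty_like(t)
        c[0] = c0
        ca = plasma.concentration_at(t)
        for i in range(len(t) - 1):
            c[i + 1] = c[i] + dt[i] * (gain * ca[i] - b * c[i])
        return ConcentrationSeries(t, np.maximum(c, 0.0))

    # exact: integrate over the union of t_grid and plasma knots so every
    # segment has linear forcing
    knots = np.union1d(t, plasma.times[(plasma.times > t[0]) & (plasma.times < t[-1])])
    c_knots = np.empty_like(knots)
    c_knots[0] = c0
    ca = plasma.concentration_at(knots)
    for i in range(len(knots) - 1):
        h = knots[i + 1] - knots[i]
        a0 = gain * ca[i]
        m = (gain * ca[i + 1] - a0) / h
        e = np.exp(-b * h)
        c_knots[i + 1] = (c_knots[i] * e
                          + (a0 / b) * (1.0 - e)
                          + (m / b) * (h - (1.0 - e) / b))
    c = np.interp(t, knots, c_knots)
    return ConcentrationSeries(t, np.maximum(c, 0.0))


def _laplacian_zero_flux(field: np.ndarray, spacing: float) -> np.ndarray:
    """Central-difference Laplacian with mirrored (Neumann) ghost cells."""
    padded = np.pad(field, 1, mode="edge")
    lap = (padded[2:, 1:-1, 1:-1] + padded[:-2, 1:-1, 1:-1]
           + padded[1:-1, 2:, 1:-1] + padded[1:-1, :-2, 1:-1]
           + padded[1:-1, 1:-1, 2:] + padded[1:-1, 1:-1, :-2]
           - 6.0 * field)
    return lap / spacing**2


def solve_pde_3d(pk: PKParams, plasma: PlasmaProfile, grid: SpatialGrid,
                 t_grid, c0_field: np.ndarray) -> np.ndarray:
    """Explicit finite-difference solution of the full reaction-diffusion PDE.

    Forward Euler in time, central differences in space, zero-flux walls.
    Returns an array of shape ``(len(t_grid), *grid.shape)``.  Raises
    :class:`ConfigurationError` when the step violates the explicit
    stability bound dt <= dx^2 * TS^2 / (6 D), and :class:`NumericalError`
    if concentrations drop below -1e-12 (relative to the field scale).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
        raise InvalidInputError("t_grid must be a strictly increasing 1-D array")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-10):
        raise InvalidInputError("solve_pde_3d requires a uniform t_grid")
    c = np.array(c0_field, dtype=float)
    if c.shape != tuple(grid.shape):
        raise InvalidInputError(f"c0_field shape {c.shape} does not match grid {grid.shape}")

    d_eff = pk.effective_diffusivity
    dt_max = grid.spacing**2 / (6.0 * d_eff) if d_eff > 0 else np.inf
    if dt[0] > dt_max:
        raise ConfigurationError(
            f"time step {dt[0]:g} min violates the explicit stability bound "
            f"dx^2*TS^2/(6*D) = {dt_max:g} min")

    b = pk.k_pi / pk.volume_fraction
    gain = pk.k_po / pk.volume_fraction
    ca = plasma.concentration_at(t)

    out = np.empty((len(t),) + c.shape)
    out[0] = c
    scale = max(float(np.abs(c).max()), 1.0)
    for i in range(len(t) - 1):
        c = c + dt[i] * (d_eff * _laplacian_zero_flux(c, grid.spacing)
                         + gain * ca[i] - b * c)
        scale = max(scale, float(np.abs(c).max()))
        if c.min() < -1e-12 * scale:
            raise NumericalError(
                f"negative concentration {c.min():g} at step {i + 1}")
        out[i + 1] = c
    return out


def interpolate_parameter_by_mw(references, query_mw: float,
                                allow_extrapolation: bool = False) -> float:
    """Piecewise-linear interpolation of a parameter over molecular weight.

    ``references`` is a sequence of ``(molecular_weight, value)`` pairs from
    tracer compounds with measured values; the query is interpolated over
    the references sorted by molecular weight.  Queries outside the covered
    range raise unless ``allow_extrapolation`` (linear extension of the
    terminal segment) is requested.
    """
    refs = sorted((float(m), float(v)) for m, v in references)
    if len(refs) < 2:
        raise InvalidInputError("at least two reference compounds are required")
    mws = np.array([m for m, _ in refs])
    vals = np.array([v for _, v in refs])
    dup = np.diff(mws) == 0
    if np.any(dup):
        for i in np.flatnonzero(dup):
            if vals[i] != vals[i + 1]:
                raise InvalidInputError(
                    f"conflicting values for duplicate molecular weight {mws[i]:g}")
    if not mws[0] <= query_mw <= mws[-1]:
        if not allow_extrapolation:
            raise InvalidInputError(
                f"query MW {query_mw:g} outside reference range "
                f"[{mws[0]:g}, {mws[-1]:g}]; pass allow_extrapolation=True to extend")
        lo = 0 if query_mw < mws[0] else -2
        m0, m1 = mws[lo], mws[lo + 1]
        v0, v1 = vals[lo], vals[lo + 1]
        return float(v0 + (query_mw - m0) / (m1 - m0) * (v1 - v0))
    return float(np.interp(query_mw, mws, vals))


def steady_state_concentration(pk: PKParams, ca_const: float) -> float:
    """Fixed point of the uniform dynamics under constant plasma level:
    C* = k_po * C_a / k_pi."""
    if pk.k_pi <= 0:
        raise InvalidInputError("k_pi must be positive for a steady state")
    return pk.k_po * ca_const / pk.k_pi
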