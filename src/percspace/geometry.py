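"""Geometry of the perceived visual space.

Perceived visual space is modelled as a Riemannian manifold whose metric
tensor g deviates from the flat baseline under neuromodulator action.  The
deviation is diagonal (visual space is taken as isotropic, so off-diagonal
components do not change), scaled by a modulation index M in [0, 1] that
follows a Hill function of the brain drug concentration:

    M(C) = 1 / (1 + (k / C)^n)

with Hill coefficient n and half-effect concentration k.  The sign of the
change is set by the arousal coefficient mu (+1 sympathetic hyperactivation,
-1 parasympathetic hypoactivation) and its magnitude by the subject's
personalised Weber constant P and by the peak deviations g_max.

The module also provides the induced surface metric and Gaussian curvature
of the ellipsoid that describes the perceived frontal plane in rod-placement
experiments, a rotated-ellipse least-squares fit for such rod positions, and
the equal-perceived-area inference of the metric from prism-power data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import DegenerateMetricError, FitFailureError, InvalidInputError

__all__ = [
    "HillParams",
    "PerceptualModulationParams",
    "MetricTensor",
    "EllipsoidParams",
    "modulation_index",
    "delta_metric",
    "perceived_metric",
    "ellipsoid_metric",
    "gaussian_curvature_ellipsoid",
    "fit_rotated_ellipse",
    "metric_from_prism_area",
]


@dataclass(frozen=True)
class HillParams:
    """Hill coefficient n and half-effect level k.

    k is a concentration (pmol/cm^3) when the Hill law maps drug
    concentration to the modulation index, and dimensionless when it maps
    the network interaction increment to the activity index.
    """

    n: float
    k: float

    def __post_init__(self):
        if not self.n > 0:
            raise InvalidInputError("Hill coefficient n must be positive")
        if not self.k > 0:
            raise InvalidInputError("half-effect parameter k must be positive")


@dataclass(frozen=True)
class PerceptualModulationParams:
    """Arousal coefficient mu (+1/-1), Weber constant P and peak metric
    deviations (g_rr_max, g_thth_max, g_phph_max) at r=1, theta=0."""

    arousal_coefficient: int = 1
    weber_constant: float = 1.0
    g_max: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.arousal_coefficient not in (1, -1):
            raise InvalidInputError("arousal_coefficient must be +1 or -1")
        if not self.weber_constant > 0:
            raise InvalidInputError("weber_constant must be positive")
        if len(self.g_max) != 3 or any(not g > 0 for g in self.g_max):
            raise InvalidInputError("g_max must be three positive components")


@dataclass(frozen=True)
class MetricTensor:
    """Symmetric metric tensor with named coordinates."""

    components: np.ndarray
    coordinate_labels: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.components, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError("metric components must form a square matrix")
        if m.shape[0] != len(self.coordinate_labels):
            raise InvalidInputError("coordinate labels must match the matrix size")
        if not np.allclose(m, m.T, atol=1e-12):
            raise InvalidInputError("metric tensor must be symmetric (tol 1e-12)")
        object.__setattr__(self, "components", m)

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.components)


@dataclass(frozen=True)
class EllipsoidParams:
    """Semi-axes (a, b) and in-plane rotation angle of a fitted ellipse.

    The same (a, b) parametrise the perceived-space ellipsoid surface
    x = a cos(alpha) cos(beta), y = b cos(alpha) sin(beta), z = a sin(alpha).
    """

    semi_axis_a: float
    semi_axis_b: float
    rotation_angle: float = 0.0

    def __post_init__(self):
        if not (self.semi_axis_a > 0 and self.semi_axis_b > 0):
            raise InvalidInputError("semi-axes must be positive")


def modulation_index(concentration, hill: HillParams):
    """Hill-law modulation index M(C) = 1 / (1 + (k/C)^n).

    Defined as 0 at C = 0 by continuity; strictly increasing in C with
    M(k) = 1/2 and limit 1.  Accepts scalars or arrays.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise InvalidInputError("concentration must be non-negative")
    out = np.zeros_like(c, dtype=float)
    pos = c > 0
    # 1/(1+(k/C)^n) == expit(-n*(log k - log C)), numerically stable for any n
    out[pos] = expit(-hill.n * (np.log(hill.k) - np.log(c[pos])))
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(out)
    return out


def delta_metric(M: float, mod: PerceptualModulationParams,
                 r: float = 1.0, theta: float = 0.0) -> MetricTensor:
    """Drug-induced metric change in spherical coordinates (r, theta, phi).

    Diagonal entries: mu*M*g_rr_max/P, r^2*mu*M*g_thth_max/P and
    r^2*cos^2(theta)*mu*M*g_phph_max/P; off-diagonals are exactly zero.
    """
    if not 0.0 <= M <= 1.0:
        raise InvalidInputError("modulation index M must lie in [0, 1]")
    mu = mod.arousal_coefficient
    p = mod.weber_constant
    grr, gtt, gpp = mod.g_max
    diag = np.array([
        mu * M * grr / p,
        r**2 * mu * M * gtt / p,
        r**2 * np.cos(theta) ** 2 * mu * M * gpp / p,
    ])
    return MetricTensor(np.diag(diag), ("r", "theta", "phi"))


def perceived_metric(baseline: MetricTensor, delta: MetricTensor) -> MetricTensor:
    """Baseline metric plus drug-induced change, with positivity enforced."""
    if baseline.components.shape != delta.components.shape:
        raise InvalidInputError("baseline and delta metrics must share a shape")
    if baseline.coordinate_labels != delta.coordinate_labels:
        raise InvalidInputError("baseline and delta metrics must share coordinates")
    total = baseline.components + delta.components
    if np.any(np.diag(total) < 0):
        raise DegenerateMetricError(
            f"perceived metric has negative diagonal entries: {np.diag(total)}")
    return MetricTensor(total, baseline.coordinate_labels)


def _ellipsoid_point_and_derivatives(a: float, b: float, alpha: float, beta: float):
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    r_a = np.array([-a * sa * cb, -b * sa * sb, a * ca])
    r_b = np.array([-a * ca * sb, b * ca * cb, 0.0])
    r_aa = np.array([-a * ca * cb, -b * ca * sb, -a * sa])
    r_ab = np.array([a * sa * sb, -b * sa * cb, 0.0])
    r_bb = np.array([-a * ca * cb, -b * ca * sb, 0.0])
    return r_a, r_b, r_aa, r_ab, r_bb


def ellipsoid_metric(ell: EllipsoidParams, alpha: float, beta: float) -> MetricTensor:
    """First fundamental form of the perceived-space ellipsoid surface.

    Closed form of the tensor transformation g_ab = J^T J for the
    parametrisation above:

        E1 = a^2 cos^2 a + a^2 cos^2 b sin^2 a + b^2 sin^2 a sin^2 b
        E2 = E3 = (a^2 - b^2) cos a cos b sin a sin b
        E4 = cos^2 a (b^2 cos^2 b + a^2 sin^2 b)
    """
    a, b = ell.semi_axis_a, ell.semi_axis_b
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    e1 = a**2 * ca**2 + a**2 * cb**2 * sa**2 + b**2 * sa**2 * sb**2
    e2 = (a**2 - b**2) * ca * cb * sa * sb
    e4 = ca**2 * (b**2 * cb**2 + a**2 * sb**2)
    return MetricTensor(np.array([[e1, e2], [e2, e4]]), ("alpha", "beta"))


def gaussian_curvature_ellipsoid(ell: EllipsoidParams, alpha: float, beta: float) -> float:
    """Gaussian curvature of the ellipsoid surface at (alpha, beta).

    Computed from the first and second fundamental forms,
    K = (LN - M^2) / (EG - F^2).  For a sphere (a = b = R) this is 1/R^2
    everywhere.
    """
    a, b = ell.semi_axis_a, ell.semi_axis_b
    r_a, r_b, r_aa, r_ab, r_bb = _ellipsoid_point_and_derivatives(a, b, alpha, beta)
    E = r_a @ r_a
    F = r_a @ r_b
    G = r_b @ r_b
    normal = np.cross(r_a, r_b)
    norm = np.linalg.norm(normal)
    if norm == 0:
        raise InvalidInputError(
            "parametrisation is degenerate at this point (cos(alpha) = 0)")
    normal = normal / norm
    L = r_aa @ normal
    Mf = r_ab @ normal
    N = r_bb @ normal
    return float((L * N - Mf**2) / (E * G - F**2))


def fit_rotated_ellipse(points):
    """Least-squares conic fit of 2-D positions, constrained to an ellipse.

    Returns ``(EllipsoidParams, center)`` with semi-axes ordered a >= b and
    the rotation angle of the major axis in (-pi/2, pi/2].  Requires at
    least five non-degenerate points; raises :class:`FitFailureError` for
    collinear input or a non-elliptical conic.
    """
    from skimage.measure import EllipseModel

    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be an (N, 2) array")
    if len(pts) < 5:
        raise InvalidInputError("at least 5 points are required for an ellipse fit")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(pts).max())) < 2:
        raise FitFailureError("points are collinear; no ellipse fits them")

    with np.errstate(invalid="ignore", divide="ignore"):
        model = EllipseModel.from_estimate(pts)
    if not model:
        raise FitFailureError("ellipse estimation failed (degenerate conic)")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise FitFailureError("ellipse estimation failed (degenerate conic)")
    if a <= 0 or b <= 0:
        raise FitFailureError("fitted conic is not an ellipse")
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    # wrap the major-axis angle into (-pi/2, pi/2]
    theta = np.mod(theta + np.pi / 2, np.pi) - np.pi / 2
    if theta <= -np.pi / 2 + 1e-15:
        theta += np.pi
    return EllipsoidParams(a, b, float(theta)), (float(xc), float(yc))


def metric_from_prism_area(area_ref: float, area_obs: float) -> float:
    """Metric diagonal from the equal-perceived-area convention.

    A figure of physical area A is perceived with area sqrt(det g) * A for
    an equal-diagonal 2-D metric (sqrt(det g) = g_diag).  If the same
    perceived area corresponds to physical areas area_ref (baseline) and
    area_obs (under drug), then g_diag = area_ref / area_obs.
    """
    if not (area_ref > 0 and area_obs > 0):
        raise InvalidInputError("areas must be positive")
    return area_ref / area_obs
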