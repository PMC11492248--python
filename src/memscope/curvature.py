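"""Membrane curvature from a fitted height surface.

The upper-leaflet phosphate (PO4) bead cloud of each frame is fitted
with a smooth Monge-patch height function ``z(x, y)`` by
Levenberg-Marquardt least squares.  Normal curvatures along the box
axes are evaluated from the analytic derivatives of the fitted form,

    kappa_x = z_xx / (1 + z_x^2)^(3/2)
    kappa_y = z_yy / (1 + z_y^2)^(3/2)

and each bead is assigned the unsigned Gaussian curvature
``|K| = |kappa_x * kappa_y|``; the per-frame observable is the
arithmetic mean of ``|K|`` over the analyzed beads.

The default surface family is a tilted plane plus one anisotropic
Gaussian dimple,

    z = c0 + c1*x + c2*y + A * exp(-((x-x0)^2/(2*sx^2) + (y-y0)^2/(2*sy^2)))

which captures a roughly planar bilayer patch with a single
capsid-induced depression.  Alternative families (pure plane,
biquadratic polynomial, separable cosine) are registry entries and can
be selected by ``form_id``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .frame import BeadFrame, PO4_BEAD_NAMES, SelectionSpec

__all__ = [
    "SurfaceForm",
    "FittedSurface",
    "CurvatureTable",
    "FORMS",
    "register_form",
    "fit_surface",
    "bead_curvatures",
    "curvature_series",
]


class ConvergenceError(RuntimeError):
    """Raised when the least-squares optimizer exhausts its iteration
    budget; carries the last iterate in ``last_params``."""

    def __init__(self, message: str, last_params: np.ndarray):
        super().__init__(message)
        self.last_params = np.asarray(last_params)


@dataclass(frozen=True)
class SurfaceForm:
    """A parametric height-function family z(x, y; p).

    ``height``, ``gradient`` and ``hessian_diag`` take a parameter
    vector and arrays x, y; ``gradient`` returns (z_x, z_y) and
    ``hessian_diag`` returns (z_xx, z_yy).  ``initial_guess`` builds a
    deterministic starting point from the data.  ``canonicalize`` maps a
    fitted vector onto the family's canonical parameter domain (e.g.
    positive Gaussian widths).
    """

    form_id: str
    param_names: tuple[str, ...]
    height: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray, np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
    hessian_diag: Callable[[np.ndarray, np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
    initial_guess: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    canonicalize: Callable[[np.ndarray], np.ndarray] = staticmethod(lambda p: p)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


FORMS: dict[str, SurfaceForm] = {}


def register_form(form: SurfaceForm) -> SurfaceForm:
    FORMS[form.form_id] = form
    return form


# --------------------------------------------------------------------------
# plane:  z = c0 + c1 x + c2 y


def _plane_height(p, x, y):
    return p[0] + p[1] * x + p[2] * y


def _plane_grad(p, x, y):
    ones = np.ones_like(x)
    return p[1] * ones, p[2] * ones


def _plane_hess(p, x, y):
    z = np.zeros_like(x)
    return z, z


def _plane_init(x, y, z):
    return np.array([float(np.mean(z)), 0.0, 0.0])


register_form(SurfaceForm(
    "plane", ("c0", "c1", "c2"),
    _plane_height, _plane_grad, _plane_hess, _plane_init,
))


# --------------------------------------------------------------------------
# plane + anisotropic Gaussian dimple (default)


def _pg_parts(p, x, y):
    c0, c1, c2, A, x0, y0, sx, sy = p
    u = x - x0
    v = y - y0
    g = np.exp(-(u * u / (2.0 * sx * sx) + v * v / (2.0 * sy * sy)))
    return u, v, g


def _pg_height(p, x, y):
    c0, c1, c2, A = p[0], p[1], p[2], p[3]
    _, _, g = _pg_parts(p, x, y)
    return c0 + c1 * x + c2 * y + A * g


def _pg_grad(p, x, y):
    c1, c2, A, sx, sy = p[1], p[2], p[3], p[6], p[7]
    u, v, g = _pg_parts(p, x, y)
    zx = c1 + A * g * (-u / (sx * sx))
    zy = c2 + A * g * (-v / (sy * sy))
    return zx, zy


def _pg_hess(p, x, y):
    A, sx, sy = p[3], p[6], p[7]
    u, v, g = _pg_parts(p, x, y)
    sx2 = sx * sx
    sy2 = sy * sy
    zxx = A * g * (u * u / (sx2 * sx2) - 1.0 / sx2)
    zyy = A * g * (v * v / (sy2 * sy2) - 1.0 / sy2)
    return zxx, zyy


def _pg_init(x, y, z):
    # Deterministic, basin-reasonable start: flat plane at the mean height,
    # dimple seeded at the lowest bead with the observed depth, widths at
    # one sixth of the patch extent.
    c0 = float(np.mean(z))
    imin = int(np.argmin(z))
    extent = max(float(np.ptp(x)), float(np.ptp(y)), 1.0)
    return np.array([
        c0, 0.0, 0.0,
        float(z[imin] - c0),
        float(x[imin]), float(y[imin]),
        extent / 6.0, extent / 6.0,
    ])


def _pg_canon(p):
    q = np.array(p, dtype=float)
    q[6] = abs(q[6])
    q[7] = abs(q[7])
    return q


register_form(SurfaceForm(
    "plane_gaussian",
    ("c0", "c1", "c2", "A", "x0", "y0", "sx", "sy"),
    _pg_height, _pg_grad, _pg_hess, _pg_init, _pg_canon,
))


# --------------------------------------------------------------------------
# biquadratic polynomial: degree <= 2 in each of x and y (9 terms)

_BIQ_POWERS = [(i, j) for i in range(3) for j in range(3)]


def _biq_height(p, x, y):
    out = np.zeros_like(np.asarray(x, dtype=float))
    for c, (i, j) in zip(p, _BIQ_POWERS):
        out = out + c * x**i * y**j
    return out


def _biq_grad(p, x, y):
    zx = np.zeros_like(np.asarray(x, dtype=float))
    zy = np.zeros_like(zx)
    for c, (i, j) in zip(p, _BIQ_POWERS):
        if i:
            zx = zx + c * i * x**(i - 1) * y**j
        if j:
            zy = zy + c * j * x**i * y**(j - 1)
    return zx, zy


def _biq_hess(p, x, y):
    zxx = np.zeros_like(np.asarray(x, dtype=float))
    zyy = np.zeros_like(zxx)
    for c, (i, j) in zip(p, _BIQ_POWERS):
        if i >= 2:
            zxx = zxx + c * i * (i - 1) * x**(i - 2) * y**j
        if j >= 2:
            zyy = zyy + c * j * (j - 1) * x**i * y**(j - 2)
    return zxx, zyy


def _biq_init(x, y, z):
    p = np.zeros(9)
    p[0] = float(np.mean(z))
    return p


register_form(SurfaceForm(
    "biquadratic",
    tuple(f"a{i}{j}" for i, j in _BIQ_POWERS),
    _biq_height, _biq_grad, _biq_hess, _biq_init,
))


# --------------------------------------------------------------------------
# separable cosine bump: z = c0 + A cos(pi (x-x0) / (2 wx)) cos(pi (y-y0) / (2 wy))


def _cos_height(p, x, y):
    c0, A, x0, y0, wx, wy = p
    return c0 + A * np.cos(np.pi * (x - x0) / (2 * wx)) * np.cos(np.pi * (y - y0) / (2 * wy))


def _cos_grad(p, x, y):
    c0, A, x0, y0, wx, wy = p
    ax = np.pi / (2 * wx)
    ay = np.pi / (2 * wy)
    u = (x - x0) * ax
    v = (y - y0) * ay
    return -A * ax * np.sin(u) * np.cos(v), -A * ay * np.cos(u) * np.sin(v)


def _cos_hess(p, x, y):
    c0, A, x0, y0, wx, wy = p
    ax = np.pi / (2 * wx)
    ay = np.pi / (2 * wy)
    u = (x - x0) * ax
    v = (y - y0) * ay
    return -A * ax * ax * np.cos(u) * np.cos(v), -A * ay * ay * np.cos(u) * np.cos(v)


def _cos_init(x, y, z):
    c0 = float(np.mean(z))
    imin = int(np.argmin(z))
    extent = max(float(np.ptp(x)), float(np.ptp(y)), 1.0)
    return np.array([c0, float(z[imin] - c0), float(x[imin]), float(y[imin]),
                     extent / 3.0, extent / 3.0])


register_form(SurfaceForm(
    "cosine", ("c0", "A", "x0", "y0", "wx", "wy"),
    _cos_height, _cos_grad, _cos_hess, _cos_init,
    canonicalize=lambda p: np.array([p[0], p[1], p[2], p[3], abs(p[4]), abs(p[5])]),
))


# --------------------------------------------------------------------------


@dataclass
class FittedSurface:
    """A fitted height function with its coefficients and RMS residual (A)."""

    form_id: str
    params: np.ndarray
    rms_residual: float
    frame_index: int | None = None

    @property
    def form(self) -> SurfaceForm:
        return FORMS[self.form_id]

    @property
    def coefficients(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.form.param_names, self.params)}

    def height(self, x, y):
        return self.form.height(self.params, np.asarray(x, float), np.asarray(y, float))

    def gradient(self, x, y):
        return self.form.gradient(self.params, np.asarray(x, float), np.asarray(y, float))

    def hessian_diag(self, x, y):
        return self.form.hessian_diag(self.params, np.asarray(x, float), np.asarray(y, float))


@dataclass
class CurvatureTable:
    """Per-bead curvature records for one frame."""

    x: np.ndarray
    y: np.ndarray
    kappa_x: np.ndarray  # 1/A
    kappa_y: np.ndarray  # 1/A
    abs_gaussian: np.ndarray  # 1/A^2

    @property
    def mean_abs_gaussian(self) -> float:
        return float(np.mean(self.abs_gaussian))


def fit_surface(points: np.ndarray, form_id: str = "plane_gaussian",
                init: Sequence[float] | None = None,
                max_iter: int = 10_000, tol: float = 1e-12) -> FittedSurface:
    """Least-squares fit of z on (x, y) for ``points`` (M x 3, angstrom).

    Uses the Levenberg-Marquardt algorithm starting from the form's
    deterministic initial guess (or ``init`` when supplied).  Raises
    ``ValueError`` if fewer points than parameters are given or the
    planar coordinates are collinear, and :class:`ConvergenceError`
    (carrying the last iterate) if the iteration budget is exhausted.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (M, 3) array")
    form = FORMS[form_id]
    m = len(pts)
    if m < form.n_params:
        raise ValueError(
            f"{m} points cannot constrain the {form.n_params}-parameter "
            f"form '{form_id}'")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    # collinearity in the (x, y) plane leaves the height field unconstrained
    design = np.column_stack([np.ones(m), x, y])
    if np.linalg.matrix_rank(design, tol=1e-8) < 3:
        raise ValueError("planar (x, y) coordinates are collinear; "
                         "cannot fit a surface")
    p0 = np.asarray(init, dtype=float) if init is not None else form.initial_guess(x, y, z)
    if len(p0) != form.n_params:
        raise ValueError("initial guess has wrong length for form "
                         f"'{form_id}'")

    def residuals(p):
        return form.height(p, x, y) - z

    res = least_squares(residuals, p0, method="lm",
                        ftol=tol, xtol=tol, gtol=tol, max_nfev=max_iter)
    if res.status == 0:
        raise ConvergenceError(
            f"surface fit did not converge within {max_iter} evaluations",
            res.x)
    params = form.canonicalize(res.x)
    rms = float(np.sqrt(np.mean((form.height(params, x, y) - z) ** 2)))
    return FittedSurface(form_id, params, rms)


def bead_curvatures(surface: FittedSurface, xy: np.ndarray) -> CurvatureTable:
    """Normal curvatures along x and y, and unsigned Gaussian curvature,
    at the planar positions ``xy`` (M x 2, angstrom)."""
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be an (M, 2) array")
    x, y = xy[:, 0], xy[:, 1]
    zx, zy = surface.gradient(x, y)
    zxx, zyy = surface.hessian_diag(x, y)
    kx = zxx / (1.0 + zx * zx) ** 1.5
    ky = zyy / (1.0 + zy * zy) ** 1.5
    return CurvatureTable(x, y, kx, ky, np.abs(kx * ky))


def shape_operator_curvatures(surface: FittedSurface, xy: np.ndarray) -> CurvatureTable:
    """Principal curvatures from the full Monge-patch shape operator.

    Offered as an alternative to the axis-aligned normal curvatures; the
    two coincide when the box axes are the principal directions.  Note
    the mixed derivative is obtained by finite differences of the
    analytic gradient, since forms only declare pure second derivatives.
    """
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    zx, zy = surface.gradient(x, y)
    zxx, zyy = surface.hessian_diag(x, y)
    h = 1e-4
    zxp, _ = surface.gradient(x, y + h)
    zxm, _ = surface.gradient(x, y - h)
    zxy = (zxp - zxm) / (2 * h)
    # first/second fundamental forms of the Monge patch
    denom = np.sqrt(1 + zx**2 + zy**2)
    E = 1 + zx**2
    F = zx * zy
    G = 1 + zy**2
    L = zxx / denom
    M = zxy / denom
    N = zyy / denom
    # shape operator eigenvalues from det/trace of II * I^-1
    detI = E * G - F * F
    K = (L * N - M * M) / detI
    H = (E * N - 2 * F * M + G * L) / (2 * detI)
    disc = np.sqrt(np.maximum(H * H - K, 0.0))
    k1 = H + disc
    k2 = H - disc
    return CurvatureTable(x, y, k1, k2, np.abs(k1 * k2))


def curvature_series(frames: Iterable[BeadFrame],
                     leaflet_map: Mapping[int, str] | None = None,
                     form_id: str = "plane_gaussian",
                     po4_names: Sequence[str] = PO4_BEAD_NAMES,
                     warm_start: bool = False) -> pd.DataFrame:
    """Per-frame surface fit and mean unsigned Gaussian curvature.

    The fitted point cloud is the upper-leaflet phosphate beads of each
    frame; the leaflet assignment is taken from ``leaflet_map`` (frozen
    at the first frame when not supplied).  Returns a DataFrame with one
    row per frame: ``frame``, ``time_ps``, ``mean_abs_gaussian_A2``,
    ``rms_residual_A`` and the fitted coefficients.

    Each frame is fitted independently from the deterministic initial
    guess; ``warm_start`` seeds each fit with the previous frame's
    coefficients instead.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    if leaflet_map is None:
        from .clusters import assign_leaflets
        leaflet_map = assign_leaflets(frames[0])
    sel = SelectionSpec(names=list(po4_names), leaflet="upper")
    rows = []
    prev_params: np.ndarray | None = None
    for fr in frames:
        idx = sel.resolve(fr, leaflet_map)
        if len(idx) == 0:
            raise ValueError(f"frame {fr.index}: no upper-leaflet PO4 beads "
                             "selected")
        pts = fr.coordinates[idx]
        init = prev_params if (warm_start and prev_params is not None) else None
        surf = fit_surface(pts, form_id, init=init)
        surf.frame_index = fr.index
        table = bead_curvatures(surf, pts[:, :2])
        row = {
            "frame": fr.index,
            "time_ps": fr.time,
            "mean_abs_gaussian_A2": table.mean_abs_gaussian,
            "rms_residual_A": surf.rms_residual,
        }
        row.update(surf.coefficients)
        rows.append(row)
        prev_params = surf.params
    return pd.DataFrame(rows)
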