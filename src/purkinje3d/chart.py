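"""Curvilinear chart induced by the normal-average vector field of a closed curve.

Given the closed approximating curve ``C`` with outward normals ``N(s)``,
the vector field

    V(x) = ( integral_0^L N(s) / d(x, C(s)) ds ) / ( integral_0^L 1 / d(x, C(s)) ds )

is the inverse-distance-weighted average of the curve normals (``d`` the
Euclidean distance).  Because both integrals diverge as ``x`` approaches the
curve, ``V`` converges to ``N`` on ``C``.  Trajectories of ``dx/dt = V(x)``
seeded at ``C(s)`` leave the curve normally and foliate an annular
neighbourhood of ``C``, inducing curvilinear coordinates ``(s, t)``: ``s``
labels the seeding arc length and ``t`` the (signed path-length) position
along the trajectory, negative inside the curve, positive outside.  On a
circle of radius R the chart reduces exactly to polar coordinates
(``s = R * theta``, radial trajectories), which serves as the analytic
oracle throughout the test-suite.

Quadrature is the periodic trapezoid rule (spectrally accurate on smooth
closed curves); trajectories use classical fixed-step RK4 on the unit-
normalized field, so the step parameter is path length — a pure
reparameterization of the artificial time variable that leaves the traced
paths unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .curves import ClosedCurve, curve_normal, curve_point

logger = logging.getLogger(__name__)

__all__ = [
    "NormalAverageField",
    "CurvilinearChart",
    "normal_average",
    "precompute_field_grid",
    "field_at",
    "integrate_trajectory",
    "build_chart",
    "to_curvilinear",
    "from_curvilinear",
]


def normal_average(curve: ClosedCurve, points, quadrature_n: int = 512) -> np.ndarray:
    """Direct quadrature evaluation of the normal-average field at ``points``.

    Periodic trapezoid rule over ``quadrature_n`` evenly spaced curve nodes.
    Points closer to the curve than 1e-9 L take the limit value ``N(s)`` of
    the nearest node.  Shape: (k, 2) for (k, 2) input, (2,) for a single point.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    s_nodes = np.linspace(0.0, curve.L, quadrature_n, endpoint=False)
    c = curve_point(curve, s_nodes)
    n = curve_normal(curve, s_nodes)

    out = np.empty_like(pts)
    eps = 1e-9 * curve.L
    chunk = max(1, int(4e6) // quadrature_n)
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]
        d = np.linalg.norm(p[:, None, :] - c[None, :, :], axis=2)
        on_curve = d.min(axis=1) < eps
        d = np.maximum(d, eps)
        w = 1.0 / d
        num = w @ n
        den = w.sum(axis=1)
        v = num / den[:, None]
        if np.any(on_curve):
            v[on_curve] = n[d[on_curve].argmin(axis=1)]
        out[lo : lo + chunk] = v
    return out[0] if np.ndim(points) == 1 else out


@dataclass
class NormalAverageField:
    """The field V precomputed on a regular planar grid, bilinearly interpolated."""

    curve: ClosedCurve
    grid_bounds: tuple  # ((xmin, xmax), (ymin, ymax))
    grid_spacing: float
    xs: np.ndarray
    ys: np.ndarray
    values: np.ndarray  # (nx, ny, 2)
    quadrature_n: int
    _interp: RegularGridInterpolator = field(default=None, repr=False)
    _curve_tree: cKDTree = field(default=None, repr=False)

    def __post_init__(self):
        self._interp = RegularGridInterpolator(
            (self.xs, self.ys), self.values, method="linear",
            bounds_error=False, fill_value=np.nan,
        )
        self._curve_tree = cKDTree(self.curve.dense_points())


def precompute_field_grid(
    curve: ClosedCurve, bounds, spacing: float, quadrature_n: int = 512
) -> NormalAverageField:
    """Sample the normal-average field on a regular grid enclosing the curve.

    ``bounds = ((xmin, xmax), (ymin, ymax))`` must enclose the curve with a
    margin at least the largest planar extent of interest; queries between
    nodes use bilinear interpolation.  Grid nodes falling exactly on the
    curve store the limit value ``N(s)`` (logged).
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    (xmin, xmax), (ymin, ymax) = bounds
    xy = curve.dense_points()
    if not (
        xmin <= xy[:, 0].min() and xy[:, 0].max() <= xmax
        and ymin <= xy[:, 1].min() and xy[:, 1].max() <= ymax
    ):
        raise ValueError(f"bounds {bounds} do not enclose the curve")

    xs = np.arange(xmin, xmax + 0.5 * spacing, spacing)
    ys = np.arange(ymin, ymax + 0.5 * spacing, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    vals = normal_average(curve, pts, quadrature_n).reshape(len(xs), len(ys), 2)
    n_sing = int(np.sum(~np.isfinite(vals)))
    if n_sing:
        logger.info("replaced %d singular grid entries with the limit N(s)", n_sing)
        bad = ~np.isfinite(vals).all(axis=2)
        bi, bj = np.nonzero(bad)
        for i, j in zip(bi, bj):
            _, idx = cKDTree(curve.dense_points()).query([xs[i], ys[j]])
            s = curve.dense_s[idx]
            vals[i, j] = curve_normal(curve, s)
    return NormalAverageField(
        curve=curve, grid_bounds=bounds, grid_spacing=spacing,
        xs=xs, ys=ys, values=vals, quadrature_n=quadrature_n,
    )


def field_at(fld: NormalAverageField, point) -> np.ndarray:
    """Field value at a point via bilinear interpolation of the grid.

    Points within 1e-6 L of the curve return the limit ``N(nearest s)``.
    Raises ``ValueError`` for points outside the grid bounds.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    v = fld._interp(p)
    if np.any(~np.isfinite(v)):
        raise ValueError(f"point outside field grid bounds {fld.grid_bounds}")
    d, idx = fld._curve_tree.query(p)
    near = d < 1e-6 * fld.curve.L
    if np.any(near):
        v[near] = curve_normal(fld.curve, fld.curve.dense_s[idx[near]])
    return v[0] if single else v


def _unit_field(fld: NormalAverageField, p: np.ndarray) -> np.ndarray:
    """Normalized field for path-length RK4; NaN outside bounds, 0 at stagnation."""
    v = fld._interp(p)
    mag = np.linalg.norm(v, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(mag > 1e-10, v / mag, 0.0)
    return u


def _march(fld, start: np.ndarray, step: float, max_extent: float, sign: float):
    """RK4 march of a batch of points along ``sign * V / |V|``.

    Returns per-seed lists of positions (excluding the start) and a
    stagnation flag per seed.  Marching stops per seed at ``max_extent``
    path length, at the grid boundary, or on stagnation (displacement below
    1e-6 step for 100 consecutive steps, e.g. at the center of a circle).
    """
    n = len(start)
    pos = start.copy()
    alive = np.ones(n, dtype=bool)
    stagnant_count = np.zeros(n, dtype=int)
    stagnated = np.zeros(n, dtype=bool)
    paths = [[] for _ in range(n)]
    n_steps = int(np.ceil(max_extent / step))
    for _ in range(n_steps):
        if not alive.any():
            break
        p = pos[alive]
        k1 = sign * _unit_field(fld, p)
        k2 = sign * _unit_field(fld, p + 0.5 * step * k1)
        k3 = sign * _unit_field(fld, p + 0.5 * step * k2)
        k4 = sign * _unit_field(fld, p + step * k3)
        disp = (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        newp = p + disp
        bad = ~np.isfinite(newp).all(axis=1)
        small = np.linalg.norm(disp, axis=1) < 1e-6 * step
        idx = np.nonzero(alive)[0]
        stagnant_count[idx[small]] += 1
        stagnant_count[idx[~small]] = 0
        stop_stag = stagnant_count[idx] >= 100
        stagnated[idx[stop_stag]] = True
        keep = ~bad & ~stop_stag
        for k, i in enumerate(idx):
            if keep[k]:
                paths[i].append(newp[k])
        pos[idx[keep]] = newp[keep]
        newly_dead = idx[~keep]
        alive[newly_dead] = False
    return paths, stagnated


@dataclass
class Trajectory:
    """One chart trajectory: points ordered by increasing t (path length).

    ``t < 0`` is the inward (backward-time) branch, ``t = 0`` the seed point
    ``C(s0)``, ``t > 0`` the outward branch.
    """

    s0: float
    t: np.ndarray
    xy: np.ndarray
    stagnated: bool

    def at(self, t):
        """Position at path length t by linear interpolation (clamped to range)."""
        x = np.interp(t, self.t, self.xy[:, 0])
        y = np.interp(t, self.t, self.xy[:, 1])
        return np.array([x, y])


def integrate_trajectory(
    fld: NormalAverageField, s0: float, step: float, max_extent: float
) -> Trajectory:
    """Trace the trajectory through ``C(s0)`` inward and outward."""
    return _integrate_batch(fld, np.array([s0]), step, max_extent)[0]


def _integrate_batch(fld, s0s: np.ndarray, step: float, max_extent: float):
    starts = curve_point(fld.curve, s0s)
    fwd, _ = _march(fld, starts, step, max_extent, +1.0)
    bwd, stag = _march(fld, starts, step, max_extent, -1.0)
    out = []
    for i, s0 in enumerate(s0s):
        nb, nf = len(bwd[i]), len(fwd[i])
        t = np.concatenate([
            -step * np.arange(nb, 0, -1.0), [0.0], step * np.arange(1.0, nf + 1)
        ])
        pts = [p for p in reversed(bwd[i])] + [starts[i]] + fwd[i]
        out.append(Trajectory(s0=float(s0), t=t, xy=np.array(pts), stagnated=bool(stag[i])))
    return out


@dataclass
class CurvilinearChart:
    """Gridded inverse of the trajectory family: (x, y) -> (s, t).

    ``s`` is stored on the unit circle (cos 2 pi s / L, sin 2 pi s / L) so
    that interpolation is seamless across the s = 0/L branch cut; queries
    recover ``s`` through atan2.
    """

    curve: ClosedCurve
    trajectories: list
    n_seeds: int
    step: float
    max_extent: float
    xs: np.ndarray
    ys: np.ndarray
    cos_map: np.ndarray
    sin_map: np.ndarray
    t_map: np.ndarray
    wrap_length: float
    n_gap_cells: int
    _interp: RegularGridInterpolator = field(default=None, repr=False)

    def __post_init__(self):
        stack = np.stack([self.cos_map, self.sin_map, self.t_map], axis=-1)
        self._interp = RegularGridInterpolator(
            (self.xs, self.ys), stack, method="linear",
            bounds_error=False, fill_value=np.nan,
        )

    @property
    def s_map(self) -> np.ndarray:
        """Gridded s in [0, L); NaN where uncharted."""
        s = np.arctan2(self.sin_map, self.cos_map) / (2 * np.pi) * self.wrap_length
        return np.mod(s, self.wrap_length)

    @property
    def seed_spacing(self) -> float:
        return self.wrap_length / self.n_seeds


def build_chart(
    fld: NormalAverageField,
    n_seeds: int = 256,
    step: float | None = None,
    max_extent: float = 1.0,
) -> CurvilinearChart:
    """Construct the (s, t) chart from ``n_seeds`` evenly spaced trajectories.

    The s- and t-maps are built on the field's own grid by inverse-distance
    weighting over the k = 4 nearest trajectory points (s through the
    cos/sin embedding).  Grid cells with no trajectory point within 2 cells
    are left uncharted (NaN) and counted in ``n_gap_cells``.
    """
    if n_seeds < 16:
        raise ValueError("n_seeds must be >= 16")
    if step is None:
        step = fld.grid_spacing
    L = fld.curve.L
    s0s = np.arange(n_seeds) * L / n_seeds
    trajs = _integrate_batch(fld, s0s, step, max_extent)

    pts, cos_v, sin_v, t_v = [], [], [], []
    for tr in trajs:
        pts.append(tr.xy)
        ang = 2 * np.pi * tr.s0 / L
        cos_v.append(np.full(len(tr.t), np.cos(ang)))
        sin_v.append(np.full(len(tr.t), np.sin(ang)))
        t_v.append(tr.t)
    pts = np.vstack(pts)
    cos_v = np.concatenate(cos_v)
    sin_v = np.concatenate(sin_v)
    t_v = np.concatenate(t_v)

    tree = cKDTree(pts)
    gx, gy = np.meshgrid(fld.xs, fld.ys, indexing="ij")
    q = np.column_stack([gx.ravel(), gy.ravel()])
    k = min(4, len(pts))
    d, idx = tree.query(q, k=k)
    d = np.atleast_2d(d.T).T if k == 1 else d
    idx = np.atleast_2d(idx.T).T if k == 1 else idx
    w = 1.0 / np.maximum(d, 1e-12)
    exact = d[:, 0] < 1e-12
    w[exact] = 0.0
    w[exact, 0] = 1.0
    wsum = w.sum(axis=1)
    cos_g = (w * cos_v[idx]).sum(axis=1) / wsum
    sin_g = (w * sin_v[idx]).sum(axis=1) / wsum
    t_g = (w * t_v[idx]).sum(axis=1) / wsum
    uncovered = d[:, 0] > 2.0 * fld.grid_spacing
    cos_g[uncovered] = np.nan
    sin_g[uncovered] = np.nan
    t_g[uncovered] = np.nan
    n_gap = int(uncovered.sum())
    if n_gap:
        logger.info("chart coverage gaps: %d grid cells beyond 2 cells of any trajectory", n_gap)

    shape = (len(fld.xs), len(fld.ys))
    return CurvilinearChart(
        curve=fld.curve, trajectories=trajs, n_seeds=n_seeds, step=step,
        max_extent=max_extent, xs=fld.xs, ys=fld.ys,
        cos_map=cos_g.reshape(shape), sin_map=sin_g.reshape(shape),
        t_map=t_g.reshape(shape), wrap_length=L, n_gap_cells=n_gap,
    )


def to_curvilinear(chart: CurvilinearChart, point):
    """Curvilinear coordinates (s, t) of planar point(s).

    ``s in [0, L)``; ``t`` is signed path length (negative inside the
    curve).  Raises ``ValueError`` for points outside the charted region.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    vals = chart._interp(np.atleast_2d(p))
    if np.any(~np.isfinite(vals)):
        raise ValueError(
            f"point outside charted region (max_extent={chart.max_extent})"
        )
    s = np.mod(
        np.arctan2(vals[:, 1], vals[:, 0]) / (2 * np.pi) * chart.wrap_length,
        chart.wrap_length,
    )
    t = vals[:, 2]
    return (float(s[0]), float(t[0])) if single else (s, t)


def to_curvilinear_grid(chart: CurvilinearChart, points: np.ndarray):
    """Vectorized (s, t) lookup returning NaN for uncharted points (no raise)."""
    vals = chart._interp(np.atleast_2d(points))
    s = np.mod(
        np.arctan2(vals[:, 1], vals[:, 0]) / (2 * np.pi) * chart.wrap_length,
        chart.wrap_length,
    )
    return s, vals[:, 2]


def from_curvilinear(chart: CurvilinearChart, s: float, t: float) -> np.ndarray:
    """Planar point at chart coordinates (s, t).

    Linear blend of the two seed trajectories bracketing ``s``, each
    evaluated at path length ``t``; accurate to within one seed spacing.
    """
    L = chart.wrap_length
    s = float(np.mod(s, L))
    ds = chart.seed_spacing
    k0 = int(np.floor(s / ds)) % chart.n_seeds
    k1 = (k0 + 1) % chart.n_seeds
    frac = (s - k0 * ds) / ds
    p0 = chart.trajectories[k0].at(t)
    p1 = chart.trajectories[k1].at(t)
    return (1.0 - frac) * p0 + frac * p1
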