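"""Closed planar Bezier splines parameterized by arc length.

The approximating curve ``C : [0, L] -> R^2`` is the base of the right
cylinder used to carry the flat Purkinje-network texture.  It is represented
as a closed piecewise-cubic Bezier spline interpolating user-supplied
control points, reparameterized by arc length through a dense chordal
sampling (closed-form Bezier arc length does not exist).  The outward unit
normal is the 90-degree clockwise rotation of the unit tangent,

    N(s) = [[0, 1], [-1, 0]] C'(s),

which points outward for a counterclockwise-oriented curve.  Orientation is
auto-corrected: clockwise input is silently reversed (and logged) because
the downstream chart construction requires counterclockwise orientation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

logger = logging.getLogger(__name__)

__all__ = ["ClosedCurve", "fit_closed_spline", "curve_point", "curve_normal", "load_curve"]


@dataclass
class ClosedCurve:
    """A closed, counterclockwise, arc-length-parameterized Bezier spline.

    Attributes
    ----------
    control_points : (n, 2) float array
        Interpolated points, counterclockwise order (after auto-correction).
    bezier : (n_seg, 4, 2) float array
        Cubic Bezier control polygons of each segment; segment ``i`` runs
        from ``control_points[i]`` to ``control_points[i + 1 mod n]``.
    dense_u : (m,) float array
        Global spline parameter of the dense sampling (in ``[0, n_seg]``).
    dense_s : (m,) float array
        Cumulative chordal arc length at each dense sample; strictly
        increasing, ``dense_s[-1] == L``.
    L : float
        Total arc length (cm), the cumulative chordal length of the dense
        sampling.
    """

    control_points: np.ndarray
    bezier: np.ndarray
    dense_u: np.ndarray
    dense_s: np.ndarray
    L: float
    axis: int = 2
    _dense_xy: np.ndarray = field(default=None, repr=False)

    @property
    def arclength_table(self) -> np.ndarray:
        """(m, 2) lookup table: column 0 arc length, column 1 spline parameter."""
        return np.column_stack([self.dense_s, self.dense_u])

    def dense_points(self) -> np.ndarray:
        """The dense polygonal sampling, shape (m, 2)."""
        return self._dense_xy

    def point(self, s):
        return curve_point(self, s)

    def normal(self, s):
        return curve_normal(self, s)


def _catmull_rom_to_bezier(points: np.ndarray) -> np.ndarray:
    """Closed C1 cubic Bezier spline through ``points`` (Catmull-Rom handles)."""
    p = np.asarray(points, dtype=float)
    n = len(p)
    prev = np.roll(p, 1, axis=0)
    nxt = np.roll(p, -1, axis=0)
    nxt2 = np.roll(p, -2, axis=0)
    b0 = p
    b1 = p + (nxt - prev) / 6.0
    b2 = nxt - (nxt2 - p) / 6.0
    b3 = nxt
    return np.stack([b0, b1, b2, b3], axis=1)


def _eval_bezier(bez: np.ndarray, u: np.ndarray):
    """Evaluate the spline (position, derivative d/du) at global parameter u.

    ``u`` lives in [0, n_seg]; integer part selects the segment, fractional
    part the local Bernstein parameter.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    n_seg = bez.shape[0]
    seg = np.clip(np.floor(u).astype(int), 0, n_seg - 1)
    t = (u - seg)[:, None]
    p0, p1, p2, p3 = (bez[seg, i, :] for i in range(4))
    omt = 1.0 - t
    pos = (omt**3) * p0 + 3 * (omt**2) * t * p1 + 3 * omt * (t**2) * p2 + (t**3) * p3
    der = 3 * (omt**2) * (p1 - p0) + 6 * omt * t * (p2 - p1) + 3 * (t**2) * (p3 - p2)
    return pos, der


def _signed_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def fit_closed_spline(
    control_points, samples_per_segment: int = 200, axis: int = 2
) -> ClosedCurve:
    """Fit a closed cubic Bezier spline through ordered 2D control points.

    Parameters
    ----------
    control_points : (n, 2) array-like, n >= 3
        Ordered points in physical units (cm).  Either orientation is
        accepted; clockwise input is reversed to counterclockwise.
    samples_per_segment : int
        Dense-sampling resolution per Bezier segment used for the chordal
        arc-length table.
    axis : int
        Principal grid axis playing the role of the cylinder axis.

    Raises
    ------
    ValueError
        Fewer than 3 control points, or a self-intersecting curve (the
        offending parameter range is reported).
    """
    cp = np.asarray(control_points, dtype=float)
    if cp.ndim != 2 or cp.shape[1] != 2 or cp.shape[0] < 3:
        raise ValueError("fit_closed_spline requires >= 3 two-dimensional control points")

    if _signed_area(cp) < 0:
        logger.info("control points are clockwise; reversing to counterclockwise")
        cp = cp[::-1].copy()

    bez = _catmull_rom_to_bezier(cp)
    n_seg = bez.shape[0]
    u = np.linspace(0.0, n_seg, n_seg * samples_per_segment + 1)
    xy, _ = _eval_bezier(bez, u)

    ring = LineString(np.vstack([xy, xy[:1]]))
    if not ring.is_simple:
        # locate the first offending pair of polygon segments for the message
        bad = _first_self_intersection(xy)
        raise ValueError(
            "self-intersecting curve near spline parameters "
            f"u in [{u[bad[0]]:.3f}, {u[bad[0] + 1]:.3f}] and "
            f"[{u[bad[1]]:.3f}, {u[bad[1] + 1]:.3f}]"
        )

    seglen = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    # guard against duplicate dense points producing a non-monotone table
    keep = np.concatenate([[True], np.diff(s) > 0])
    return ClosedCurve(
        control_points=cp,
        bezier=bez,
        dense_u=u[keep],
        dense_s=s[keep],
        L=float(s[-1]),
        axis=axis,
        _dense_xy=xy[keep],
    )


def _first_self_intersection(xy: np.ndarray):
    """Brute-force segment-pair intersection on the closed polygon."""
    pts = np.vstack([xy, xy[:1]])
    a = pts[:-1]
    b = pts[1:]
    n = len(a)
    for i in range(n):
        # vectorized orientation test of segment i against all j > i + 1
        j0 = i + 2
        j1 = n if i > 0 else n - 1  # skip wrap-adjacent pair for i == 0
        if j0 >= j1:
            continue
        p, r = a[i], b[i] - a[i]
        q = a[j0:j1]
        s_ = b[j0:j1] - q
        cross2 = lambda u, v: u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
        denom = cross2(r, s_)
        qp = q - p
        with np.errstate(divide="ignore", invalid="ignore"):
            t = cross2(qp, s_) / denom
            w = cross2(qp, r) / denom
        hit = (np.abs(denom) > 1e-14) & (t > 0) & (t < 1) & (w > 0) & (w < 1)
        if np.any(hit):
            return i, j0 + int(np.argmax(hit))
    return 0, 0


def _s_to_u(curve: ClosedCurve, s) -> np.ndarray:
    s = np.atleast_1d(np.asarray(s, dtype=float))
    s = np.mod(s, curve.L)
    return np.interp(s, curve.dense_s, curve.dense_u)


def curve_point(curve: ClosedCurve, s):
    """Point on the curve at arc length ``s`` (wrapped modulo L).

    Accepts a scalar or an array of arc lengths; returns shape (2,) or (k, 2).
    """
    scalar = np.isscalar(s) or np.ndim(s) == 0
    pos, _ = _eval_bezier(curve.bezier, _s_to_u(curve, s))
    return pos[0] if scalar else pos


def curve_normal(curve: ClosedCurve, s):
    """Outward unit normal ``N(s)``: 90-degree clockwise rotation of the unit tangent."""
    scalar = np.isscalar(s) or np.ndim(s) == 0
    _, der = _eval_bezier(curve.bezier, _s_to_u(curve, s))
    tang = der / np.linalg.norm(der, axis=1, keepdims=True)
    normal = np.column_stack([tang[:, 1], -tang[:, 0]])
    return normal[0] if scalar else normal


def load_curve(path) -> ClosedCurve:
    """Read control points from a JSON file.

    Expected layout::

        {"control_points": [[x, y], ...], "axis": 2}

    ``axis`` names the principal grid axis serving as the cylinder axis and
    may also be given as "x", "y" or "z".
    """
    with open(path) as fh:
        doc = json.load(fh)
    axis = doc.get("axis", 2)
    if isinstance(axis, str):
        axis = {"x": 0, "y": 1, "z": 2}[axis.lower()]
    return fit_closed_spline(doc["control_points"], axis=axis)
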