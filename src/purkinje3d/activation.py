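"""Activation maps and model-to-model activation-time comparison.

An activation map holds, per node, the first time the membrane potential
crossed the activation threshold (0.5 by default), linearly interpolated
between the bracketing time steps; never-activated nodes carry +inf.

Two maps (3D-3D minus 3D-2D, by convention) are compared after applying an
offset ``c`` to the pointwise differences ``d(x) = A3(x) - A2(x) + c``
under one of three schemes:

    stimulus_start    c = 0 (both runs share the stimulus clock),
    first_activation  c = -(f3 - f2) (clocks re-zeroed at each model's
                      earliest activation),
    min_rms           c minimizing sum_x (A3 - A2 + c)^2, whose closed form
                      is the negated mean difference.

Offsets shift but never reshape the difference distribution, so the
standard deviation and the min-max range width are scheme-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ActivationMap",
    "DiffMetrics",
    "first_crossing_times",
    "compute_activation",
    "compare_maps",
    "compare_all",
    "NEVER",
]

NEVER = np.inf  # sentinel for never-activated nodes
SCHEMES = ("stimulus_start", "first_activation", "min_rms")


@dataclass
class ActivationMap:
    """Per-node first-activation times (ms); +inf marks never-activated."""

    times: np.ndarray
    threshold: float = 0.5
    stim_start: float = 0.0

    @property
    def f(self) -> float:
        """Earliest finite activation time."""
        finite = self.times[np.isfinite(self.times)]
        return float(finite.min()) if finite.size else NEVER

    @property
    def activated_fraction(self) -> float:
        return float(np.isfinite(self.times).mean())


@dataclass
class DiffMetrics:
    """Difference statistics of one comparison scheme (Table-style row)."""

    scheme: str
    c: float
    rms: float
    std: float
    min: float
    max: float
    n_common: int
    n_excluded: int


def first_crossing_times(ts, vs, threshold: float = 0.5) -> np.ndarray:
    """First upward threshold crossings of recorded traces.

    ``ts`` is (n_steps,), ``vs`` is (n_steps, n_nodes); crossings are
    linearly interpolated between the bracketing samples.  Nodes that never
    cross return +inf.
    """
    ts = np.asarray(ts, dtype=float)
    vs = np.atleast_2d(np.asarray(vs, dtype=float))
    n_nodes = vs.shape[1]
    out = np.full(n_nodes, NEVER)
    below = vs[:-1] < threshold
    above = vs[1:] >= threshold
    for j in range(n_nodes):
        hits = np.nonzero(below[:, j] & above[:, j])[0]
        if hits.size:
            i = hits[0]
            frac = (threshold - vs[i, j]) / (vs[i + 1, j] - vs[i, j])
            out[j] = ts[i] + frac * (ts[i + 1] - ts[i])
    return out


def compute_activation(
    times, threshold: float = 0.5, stim_start: float = 0.0
) -> ActivationMap:
    """Build an ActivationMap from recorded crossing times.

    Negative and NaN entries (the solver's not-yet-activated sentinel)
    become +inf.
    """
    t = np.array(times, dtype=float)
    t[~np.isfinite(t) | (t < 0)] = NEVER
    return ActivationMap(times=t, threshold=threshold, stim_start=stim_start)


def compare_maps(A3: ActivationMap, A2: ActivationMap, scheme: str) -> DiffMetrics:
    """Difference statistics between two congruent activation maps.

    Only nodes finite in both maps enter the statistics; the number of
    excluded nodes is reported.  Differences are 3D-3D minus 3D-2D plus the
    scheme offset ``c``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    t3 = np.asarray(A3.times, dtype=float).ravel()
    t2 = np.asarray(A2.times, dtype=float).ravel()
    if t3.shape != t2.shape:
        raise ValueError("activation maps are not congruent")
    common = np.isfinite(t3) & np.isfinite(t2)
    n_common = int(common.sum())
    if n_common == 0:
        raise ValueError("no nodes are finite in both maps")
    d0 = t3[common] - t2[common]
    if scheme == "stimulus_start":
        c = 0.0
    elif scheme == "first_activation":
        c = -(A3.f - A2.f)
    else:  # min_rms: d/dc sum (d0 + c)^2 = 0  =>  c = -mean(d0)
        c = -float(d0.mean())
    d = d0 + c
    return DiffMetrics(
        scheme=scheme,
        c=float(c),
        rms=float(np.sqrt(np.mean(d**2))),
        std=float(np.std(d)),
        min=float(d.min()),
        max=float(d.max()),
        n_common=n_common,
        n_excluded=int(t3.size - n_common),
    )


def compare_all(A3: ActivationMap, A2: ActivationMap) -> pd.DataFrame:
    """All three schemes as one table (one row per scheme)."""
    rows = [vars(compare_maps(A3, A2, s)) for s in SCHEMES]
    return pd.DataFrame(rows)
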