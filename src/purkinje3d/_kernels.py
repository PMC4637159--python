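"""Inner time-stepping kernels for the monodomain solver.

One explicit forward-Euler step over the flattened list of active nodes:
phase-field-weighted graph Laplacian (gathered through precomputed neighbor
index/weight tables), two-variable membrane reaction, exact-exponential
gate update, and first-crossing activation recording.  A numba-compiled
version is used when numba imports; the numpy gather version is the
reference implementation and fallback.  Both orderings are deterministic.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


def step_numpy(
    v, h, act, neigh_idx, neigh_w, inv_phi, stim, dt, t_now,
    tau_in, tau_out, e_open, e_close, v_gate, v_thr, react_on,
):
    """Reference numpy step; mutates v, h, act in place."""
    vn = v[np.maximum(neigh_idx, 0)]
    lap = np.einsum("nm,nm->n", neigh_w, vn - v[:, None]) * inv_phi
    v_old = v.copy()
    if react_on:
        dv = h * v_old * v_old * (1.0 - v_old) / tau_in - v_old / tau_out
    else:
        dv = 0.0
    v += dt * (dv + stim + lap)
    if react_on:
        below = v_old < v_gate
        h[below] = 1.0 - (1.0 - h[below]) * e_open
        h[~below] = h[~below] * e_close
    crossed = (act < 0.0) & (v_old < v_thr) & (v >= v_thr)
    if crossed.any():
        act[crossed] = t_now + dt * (v_thr - v_old[crossed]) / (v[crossed] - v_old[crossed])


@njit(cache=True)
def _step_numba(
    v, h, act, neigh_idx, neigh_w, inv_phi, stim, dt, t_now,
    tau_in, tau_out, e_open, e_close, v_gate, v_thr, react_on,
):  # pragma: no cover - compiled
    n = v.shape[0]
    m = neigh_idx.shape[1]
    lap = np.empty(n)
    for i in range(n):
        acc = 0.0
        for k in range(m):
            j = neigh_idx[i, k]
            if j >= 0:
                acc += neigh_w[i, k] * (v[j] - v[i])
        lap[i] = acc * inv_phi[i]
    for i in range(n):
        v_old = v[i]
        if react_on:
            dv = h[i] * v_old * v_old * (1.0 - v_old) / tau_in - v_old / tau_out
        else:
            dv = 0.0
        v_new = v_old + dt * (dv + stim[i] + lap[i])
        v[i] = v_new
        if react_on:
            if v_old < v_gate:
                h[i] = 1.0 - (1.0 - h[i]) * e_open
            else:
                h[i] = h[i] * e_close
        if act[i] < 0.0 and v_old < v_thr <= v_new:
            act[i] = t_now + dt * (v_thr - v_old) / (v_new - v_old)


step = _step_numba if HAVE_NUMBA else step_numpy
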