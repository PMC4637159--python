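"""Coupled ventricle-Purkinje models (3D-3D and 3D-2D).

Both models pair a 3D monodomain ventricle with a fast-conducting Purkinje
domain and exchange current at discrete coupling sites (the projected
coupling-site voxels).  In the 3D-3D model the Purkinje network is the
projected voxel structure solved on the same grid as the ventricles; in
the 3D-2D model the Purkinje network is solved directly on its flat pixel
raster (one node per pixel, physical spacing induced by the placement
rectangle) and coupled through an explicit site-pixel-to-shell-voxel list.

Coupling is a symmetric resistive exchange applied in a second phase after
both domains have advanced one step: each coupled pair relaxes toward its
common mean at rate g_c,

    dv_v/dt = g_c (v_p - v_v),    dv_p/dt = g_c (v_v - v_p),

advanced by the exact exponential solution of this pairwise ODE,

    delta = (1 - exp(-2 g_c dt)) (v_p - v_v) / 2,
    v_v <- v_v + delta,           v_p <- v_p - delta,

evaluated on the freshly updated (phase-1) values.  The update equals the
forward-Euler exchange ``dt g_c (v_p - v_v)`` to first order but is
unconditionally stable for any g_c; the exchange is antisymmetric, so the
pairwise sum v_v + v_p is conserved by phase 2, and in the large-g_c limit
the two potentials clamp to their common mean.  A site voxel is a small
current source for the surrounding myocardium, so the default g_c is large
(100/ms): the junction must hold its voxel near the Purkinje plateau long
enough to nucleate a ventricular wave against the 3D diffusive sink.  The
physiological behaviour this reproduces: a stimulus delivered only at the
His-bundle entry of the Purkinje network propagates through the fast
network, hands over at the coupling sites (the first ventricular nodes to
depolarize), and from there activates the full ventricular wall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .activation import ActivationMap, compute_activation
from .chart import CurvilinearChart
from .ep import (
    DEFAULT_D0,
    DEFAULT_PURKINJE_RATIO,
    MembraneParams,
    StimulusProtocol,
    TissueDomain,
    apply_stimulus_protocol,
    grid_spacing_2d,
    monodomain_step,
    stimulus_vector,
)
from .geometry import TISSUE_THRESHOLD, PhaseField, VoxelMask
from .network_texture import (
    NetworkImage,
    PlacementRect,
    ProjectedNetwork,
    map_pixels_to_voxels,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EPConfig",
    "Coupled3D3D",
    "Coupled3D2D",
    "SimulationResult",
    "build_3d3d",
    "build_3d2d",
    "coupled_step",
    "run_simulation",
]


@dataclass
class EPConfig:
    """Electrophysiology and coupling parameters shared by both models."""

    membrane: MembraneParams = field(default_factory=MembraneParams)
    D0: float = DEFAULT_D0  # ventricular diffusivity, cm^2/ms
    ratio: float = DEFAULT_PURKINJE_RATIO  # Purkinje/ventricle diffusivity ratio
    g_c: float = 100.0  # coupling exchange rate, 1/ms
    dt: float = 0.005  # ms
    v_threshold: float = 0.5
    # Stimulus current in normalized-voltage units per ms.  The His-bundle
    # node sits inside the fast-diffusing network (sink ~ 2*dim*D_P/h^2,
    # roughly 200/ms at default resolution), so the amplitude must be large
    # enough to lift the node past the excitation gate against that sink.
    stim_amplitude: float = 50.0
    stim_duration: float = 2.0  # ms
    stim_start: float = 0.0  # ms
    t_end: float = 120.0  # ms


@dataclass
class Coupled3D3D:
    """Ventricle and projected Purkinje network on one shared voxel grid."""

    ventricle: TissueDomain
    purkinje: TissueDomain
    pairs: np.ndarray  # (n, 2): column 0 purkinje node, column 1 ventricle node
    g_c: float
    config: EPConfig
    bundle_nodes: np.ndarray = None  # purkinje-domain node indices of the His entry
    site_voxels: dict = None


@dataclass
class Coupled3D2D:
    """3D ventricle coupled to the Purkinje network on its flat 2D raster."""

    ventricle: TissueDomain
    purkinje: TissueDomain
    pairs: np.ndarray
    g_c: float
    config: EPConfig
    bundle_nodes: np.ndarray = None
    site_pixels: dict = None
    site_voxels: dict = None


@dataclass
class SimulationResult:
    """Activation maps of both domains plus summary numbers."""

    ventricle_map: ActivationMap
    purkinje_map: ActivationMap
    activated_fraction: float
    t_end: float
    snapshots: list = field(default_factory=list)


def build_3d3d(
    phase: PhaseField,
    shell: VoxelMask,
    projected: ProjectedNetwork,
    config: EPConfig | None = None,
) -> Coupled3D3D:
    """Assemble the shared-grid model from a projected network."""
    config = config or EPConfig()
    if projected.voxels.count == 0:
        raise ValueError("projected network is empty")
    if not projected.site_voxels:
        raise ValueError("no mapped coupling sites: the ventricles could not activate")
    tissue = phase.values >= TISSUE_THRESHOLD
    vent = TissueDomain(
        mask=tissue, spacing=phase.spacing, diffusivity=config.D0,
        phase=phase.values, params=config.membrane,
    )
    purk = TissueDomain(
        mask=projected.voxels.flags, spacing=phase.spacing,
        diffusivity=config.ratio * config.D0, phase=phase.values,
        params=config.membrane,
    )
    pairs = np.array(
        [[purk.node_of(vox), vent.node_of(vox)] for vox in projected.site_voxels.values()],
        dtype=np.int64,
    )
    bundle = None
    if projected.bundle_voxel is not None:
        bundle = np.array([purk.node_of(projected.bundle_voxel)], dtype=np.int64)
    return Coupled3D3D(
        ventricle=vent, purkinje=purk, pairs=pairs, g_c=config.g_c,
        config=config, bundle_nodes=bundle, site_voxels=dict(projected.site_voxels),
    )


def build_3d2d(
    phase: PhaseField,
    shell: VoxelMask,
    chart: CurvilinearChart,
    rect: PlacementRect,
    network: NetworkImage,
    config: EPConfig | None = None,
) -> Coupled3D2D:
    """Assemble the split-grid model: 2D network raster vs 3D ventricles.

    Site-to-voxel correspondence uses the same trajectory-intersection rule
    as the 3D projection, so the two models couple at identical shell
    voxels.
    """
    config = config or EPConfig()
    if not network.mask.any():
        raise ValueError("empty network raster")
    tissue = phase.values >= TISSUE_THRESHOLD
    vent = TissueDomain(
        mask=tissue, spacing=phase.spacing, diffusivity=config.D0,
        phase=phase.values, params=config.membrane,
    )
    dpx, dpy = grid_spacing_2d(rect, network.W, network.H, phase.spacing)
    purk = TissueDomain(
        mask=network.mask, spacing=(dpx, dpy),
        diffusivity=config.ratio * config.D0, params=config.membrane,
    )

    fiber = np.argwhere(network.mask).astype(float)
    tree = cKDTree(fiber)

    def pixel_node(uv):
        d, j = tree.query(np.asarray(uv, dtype=float))
        if d > 1.5:
            return None
        return purk.node_of(fiber[j].astype(int))

    mapped = map_pixels_to_voxels(chart, rect, network, shell, phase, network.sites)
    pairs, site_pixels, site_voxels = [], {}, {}
    for i, vox in enumerate(mapped):
        if vox is None:
            continue
        pnode = pixel_node(network.sites[i])
        if pnode is None:
            continue
        pairs.append([pnode, vent.node_of(vox)])
        site_pixels[i] = tuple(int(v) for v in np.floor(network.sites[i]))
        site_voxels[i] = vox
    if not pairs:
        raise ValueError("all coupling sites unmapped: cannot couple the models")
    bundle = None
    if network.bundle_branch is not None:
        bnode = pixel_node(network.bundle_branch)
        if bnode is not None:
            bundle = np.array([bnode], dtype=np.int64)
    return Coupled3D2D(
        ventricle=vent, purkinje=purk, pairs=np.asarray(pairs, dtype=np.int64),
        g_c=config.g_c, config=config, bundle_nodes=bundle,
        site_pixels=site_pixels, site_voxels=site_voxels,
    )


def coupled_step(model, state_v, state_p, dt, stim_v=None, stim_p=None):
    """One step of the two-phase scheme (both states advanced in place).

    Phase 1 advances each domain independently; phase 2 applies the
    symmetric exchange at the coupled pairs using phase-1 values.  Nodes
    pushed across the activation threshold by the exchange itself are
    time-stamped at the end of the step.
    """
    monodomain_step(state_v, model.ventricle, dt, stim_v,
                    v_threshold=model.config.v_threshold)
    monodomain_step(state_p, model.purkinje, dt, stim_p,
                    v_threshold=model.config.v_threshold)
    if len(model.pairs) and model.g_c != 0.0:
        pi = model.pairs[:, 0]
        vi = model.pairs[:, 1]
        vv_old = state_v.v[vi]
        vp_old = state_p.v[pi]
        delta = 0.5 * (1.0 - np.exp(-2.0 * model.g_c * dt)) * (vp_old - vv_old)
        # accumulate: distinct sites may share a voxel
        np.add.at(state_v.v, vi, delta)
        np.add.at(state_p.v, pi, -delta)
        thr = model.config.v_threshold
        t_now = state_v.time
        for st, nodes, old in ((state_v, vi, vv_old), (state_p, pi, vp_old)):
            new = st.v[nodes]
            hit = (st.activation[nodes] < 0) & (old < thr) & (new >= thr)
            if hit.any():
                st.activation[nodes[hit]] = t_now
    return state_v, state_p


def run_simulation(
    model,
    protocol: StimulusProtocol | None = None,
    t_end: float | None = None,
    record: str = "activation",
    snapshot_every: int | None = None,
):
    """Run a coupled model from rest under a Purkinje-only stimulus.

    ``protocol`` targets Purkinje-domain nodes (defaults to the model's
    bundle-branch nodes with the config amplitude/duration); activation
    maps record the first 0.5-crossing per node, shaped like each domain's
    grid.  Warns if the run ends before any ventricular activation.
    """
    cfg = model.config
    t_end = cfg.t_end if t_end is None else float(t_end)
    dt = min(cfg.dt, 0.9 * model.ventricle.dt_max, 0.9 * model.purkinje.dt_max)
    if dt < cfg.dt:
        logger.info("dt reduced from %g to %g ms to satisfy stability", cfg.dt, dt)
    if protocol is None:
        if model.bundle_nodes is None:
            raise ValueError("no bundle-branch nodes available for the default protocol")
        protocol = apply_stimulus_protocol(
            model.purkinje, model.bundle_nodes, cfg.stim_amplitude,
            cfg.stim_duration, cfg.stim_start,
        )
    state_v = model.ventricle.rest_state()
    state_p = model.purkinje.rest_state()
    n_steps = int(np.round(t_end / dt))
    zeros_v = np.zeros(model.ventricle.n_nodes)
    snapshots = []
    for k in range(n_steps):
        t = state_p.time
        stim_p = stimulus_vector([protocol], t, model.purkinje.n_nodes)
        coupled_step(model, state_v, state_p, dt, zeros_v, stim_p)
        if snapshot_every and (k + 1) % snapshot_every == 0:
            snapshots.append((state_v.time, state_v.v.copy(), state_p.v.copy()))

    vent_map = _grid_map(model.ventricle, state_v, cfg)
    purk_map = _grid_map(model.purkinje, state_p, cfg)
    frac = float(np.isfinite(vent_map.times[model.ventricle.mask]).mean())
    if frac == 0.0:
        logger.warning("run ended at t=%.1f ms before any ventricular activation", t_end)
    return SimulationResult(
        ventricle_map=vent_map, purkinje_map=purk_map,
        activated_fraction=frac, t_end=t_end, snapshots=snapshots,
    )


def _grid_map(domain: TissueDomain, state, cfg: EPConfig) -> ActivationMap:
    flat = compute_activation(state.activation, cfg.v_threshold, cfg.stim_start)
    times = np.full(domain.mask.shape, np.inf)
    times[tuple(domain.node_coords.T)] = flat.times
    return ActivationMap(times=times, threshold=cfg.v_threshold, stim_start=cfg.stim_start)
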