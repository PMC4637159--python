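"""End-to-end assembly: phase field + network image -> coupled models.

Convenience layer used by the command-line interface, the test-suite and
the reproduction script; every step is the corresponding public function
of the underlying modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chart import CurvilinearChart, build_chart, precompute_field_grid
from .coupled import Coupled3D2D, Coupled3D3D, EPConfig, build_3d2d, build_3d3d
from .curves import ClosedCurve, fit_closed_spline
from .fixtures import synth_curve_for
from .geometry import PhaseField, VoxelMask, extract_shell, isolate_chamber
from .network_texture import (
    NetworkImage,
    PlacementRect,
    ProjectedNetwork,
    project_network,
)

logger = logging.getLogger(__name__)

__all__ = ["MappedGeometry", "map_network", "build_models"]


@dataclass
class MappedGeometry:
    """All intermediate artifacts of the structural-mapping stage."""

    phase: PhaseField
    chamber: VoxelMask
    shell: VoxelMask
    curve: ClosedCurve
    chart: CurvilinearChart
    rect: PlacementRect
    network: NetworkImage
    projected: ProjectedNetwork


def map_network(
    phase: PhaseField,
    chamber_seed,
    network: NetworkImage,
    curve_points=None,
    rect: PlacementRect | None = None,
    kernel_radius: float = 3.0,
    threshold: float = 0.5,
    n_seeds: int = 256,
    quadrature_n: int = 512,
    max_extent: float = 0.8,
) -> MappedGeometry:
    """Run the structural pipeline: chamber, shell, curve, chart, projection.

    ``curve_points`` defaults to the auto-fitted chamber cross-section
    outline; ``rect`` defaults to a full wrap of the curve over the shell's
    axial extent.
    """
    chamber = isolate_chamber(phase, chamber_seed, threshold)
    shell = extract_shell(phase, chamber, kernel_radius, threshold)
    if curve_points is None:
        curve_points = synth_curve_for(phase, chamber)
    curve = fit_closed_spline(curve_points, axis=phase.axis)

    sp = phase.spacing
    planar = phase.planar_axes()
    margin = max_extent + 2 * sp
    xy = curve.dense_points()
    bounds = (
        (xy[:, 0].min() - margin, xy[:, 0].max() + margin),
        (xy[:, 1].min() - margin, xy[:, 1].max() + margin),
    )
    fld = precompute_field_grid(curve, bounds, sp, quadrature_n)
    chart = build_chart(fld, n_seeds, max_extent=max_extent)

    if rect is None:
        idx = shell.indices()
        ax = phase.axis
        zlo = idx[:, ax].min() * sp
        zhi = idx[:, ax].max() * sp
        rect = PlacementRect(0.0, curve.L, zlo, zhi)
    projected = project_network(chart, rect, network, shell, phase)
    logger.info(
        "mapped network: %d voxels, %d/%d sites",
        projected.voxels.count, len(projected.site_voxels), network.n_sites,
    )
    return MappedGeometry(
        phase=phase, chamber=chamber, shell=shell, curve=curve,
        chart=chart, rect=rect, network=network, projected=projected,
    )


def build_models(mapped: MappedGeometry, config: EPConfig | None = None):
    """Both coupled models over one mapped geometry: (3D-3D, 3D-2D)."""
    config = config or EPConfig()
    m33 = build_3d3d(mapped.phase, mapped.shell, mapped.projected, config)
    m32 = build_3d2d(
        mapped.phase, mapped.shell, mapped.chart, mapped.rect,
        mapped.network, config,
    )
    return m33, m32
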