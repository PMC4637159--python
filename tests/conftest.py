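"""Shared fixtures: analytic circle chart, cylinder and ellipsoid pipelines.

Heavy objects (field grids, charts, coupled simulations) are session-scoped
so the analytic-oracle tests and the end-to-end tests share one build.
"""

import numpy as np
import pytest
from hypothesis import settings

from purkinje3d.chart import build_chart, precompute_field_grid
from purkinje3d.coupled import EPConfig, run_simulation
from purkinje3d.curves import fit_closed_spline
from purkinje3d.fixtures import reference_fixture, synth_network_image
from purkinje3d.geometry import synth_ventricles
from purkinje3d.pipeline import build_models, map_network

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")

CIRCLE_R = 1.0


@pytest.fixture(scope="session")
def circle_curve():
    """Closed spline through 24 points on the unit circle."""
    th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    return fit_closed_spline(np.column_stack([np.cos(th), np.sin(th)]))


@pytest.fixture(scope="session")
def circle_field(circle_curve):
    return precompute_field_grid(circle_curve, ((-2, 2), (-2, 2)), 0.025, 512)


@pytest.fixture(scope="session")
def circle_chart(circle_field):
    return build_chart(circle_field, n_seeds=256, max_extent=0.9)


@pytest.fixture(scope="session")
def ellipse_curve():
    th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    return fit_closed_spline(np.column_stack([1.5 * np.cos(th), 0.8 * np.sin(th)]))


@pytest.fixture(scope="session")
def reference_bundle():
    return reference_fixture(seed=7)


@pytest.fixture(scope="session")
def cylinder_mapped(reference_bundle):
    """Exact-cylinder geometry with the depth-4 network projected onto it.

    The approximating curve is the exact cavity circle, so the cylindrical
    approximation has zero distortion and analytic-wrap oracles apply.
    """
    b = reference_bundle
    phase = b.phase_cylinder
    sp = phase.spacing
    center = (np.array(phase.shape[:2]) - 1) / 2 * sp
    th = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    radius = 14 * sp  # the generator's cavity radius
    circle = center + radius * np.column_stack([np.cos(th), np.sin(th)])
    with np.errstate(all="ignore"):
        return map_network(
            phase, b.seeds_cylinder[0], b.network,
            curve_points=circle, max_extent=0.5,
        )


@pytest.fixture(scope="session")
def ellipsoid_mapped(reference_bundle):
    b = reference_bundle
    return map_network(
        b.phase_ellipsoid, b.seeds_ellipsoid[0], b.network,
        curve_points=b.curve_points_ellipsoid, max_extent=0.8,
    )


@pytest.fixture(scope="session")
def cylinder_runs(cylinder_mapped):
    """Both coupled models run to full activation on the exact cylinder."""
    m33, m32 = build_models(cylinder_mapped, EPConfig())
    return {
        "m33": m33, "m32": m32,
        "r33": run_simulation(m33), "r32": run_simulation(m32),
    }


@pytest.fixture(scope="session")
def reference_runs(ellipsoid_mapped):
    """Both coupled models run to full activation on the reference ellipsoid pair."""
    m33, m32 = build_models(ellipsoid_mapped, EPConfig())
    return {
        "m33": m33, "m32": m32,
        "r33": run_simulation(m33), "r32": run_simulation(m32),
    }


@pytest.fixture(scope="session")
def small_mapped():
    """A fast, small cylinder pipeline for coupling-behaviour tests."""
    phase, seeds = synth_ventricles(
        "cylinder", {"shape": (40, 40, 28), "inner_radius": 9, "outer_radius": 16}
    )
    net = synth_network_image(48, 48, 2, seed=3)
    return map_network(phase, seeds[0], net, max_extent=0.4)
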