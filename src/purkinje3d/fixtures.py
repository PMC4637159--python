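"""Deterministic synthetic inputs: toy networks, auto-fitted curves, reference bundle.

No anatomical data ship with this package, so every pipeline stage is
exercised on synthetic stand-ins: phase-field ventricles from
:func:`purkinje3d.geometry.synth_ventricles`, binary branching-tree network
images emulating a digitized Purkinje branch (a His-bundle origin at the
top, recursive bifurcation, one coupling site at each terminal fiber tip),
and closed curves fitted automatically to a chamber cross-section.  All
outputs are bit-reproducible from their parameters and seed; the reference
bundle's checksums are frozen in ``data/reference_manifest.json`` and
regression-tested.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from skimage.draw import line as draw_line

from .curves import fit_closed_spline
from .geometry import PhaseField, VoxelMask, isolate_chamber, synth_ventricles
from .network_texture import NetworkImage

__all__ = [
    "synth_network_image",
    "synth_curve_for",
    "reference_fixture",
    "ReferenceBundle",
    "bundle_checksums",
    "frozen_manifest",
]


def synth_network_image(
    W: int, H: int, depth: int, seed: int = 0, jitter: float = 0.06
) -> NetworkImage:
    """Binary branching-tree network raster with terminal coupling sites.

    A trunk starts at the image-center top (the bundle-branch entry, flagged
    separately) and bifurcates ``depth`` times into 1-pixel-wide strokes,
    giving ``2**depth`` leaf coupling sites.  ``jitter`` (radians) adds a
    seeded perturbation to the branching angles so different seeds give
    different trees.  Raises if the tree would leave the raster.
    """
    if depth < 1:
        raise ValueError("branching depth must be >= 1")
    rng = np.random.default_rng(seed)
    mask = np.zeros((W, H), dtype=bool)
    root = np.array([W / 2.0, H - 2.0])
    trunk_len = H / 6.0
    seg0 = 0.16 * H
    spread0 = 0.55  # radians, shrinking by 0.62 per level

    def stroke(p, q):
        p = np.round(p).astype(int)
        q = np.round(q).astype(int)
        for r in (p, q):
            if not (0 <= r[0] < W and 0 <= r[1] < H):
                raise ValueError(f"tree exceeds the {W}x{H} raster at pixel {tuple(r)}")
        rr, cc = draw_line(p[0], p[1], q[0], q[1])
        mask[rr, cc] = True
        # make the stroke 4-connected: fill one elbow pixel per diagonal step,
        # so the raster itself is a valid domain for a 4-neighbor stencil
        for k in range(len(rr) - 1):
            if rr[k] != rr[k + 1] and cc[k] != cc[k + 1]:
                mask[rr[k + 1], cc[k]] = True

    sites = []
    down = -np.pi / 2  # u2 decreases toward the image bottom

    def grow(pos, angle, level):
        if level == depth:
            sites.append(pos.copy())
            return
        for sign in (-1.0, +1.0):
            ang = angle + sign * spread0 * 0.62**level + jitter * rng.standard_normal()
            length = seg0 * 0.72**level
            end = pos + length * np.array([np.cos(ang), np.sin(ang)])
            stroke(pos, end)
            grow(np.round(end), ang, level + 1)

    trunk_end = root + trunk_len * np.array([np.cos(down), np.sin(down)])
    stroke(root, trunk_end)
    grow(np.round(trunk_end), down, 0)

    return NetworkImage(
        mask=mask,
        sites=np.array(sites, dtype=float),
        bundle_branch=root.copy(),
    )


def synth_curve_for(phase: PhaseField, chamber: VoxelMask, n_angles: int = 16):
    """Closed-curve control points approximating a chamber cross-section.

    Takes the mid-axis slice of the chamber, casts ``n_angles`` rays from
    its centroid, and places one control point at the outermost chamber
    pixel of each angular bin (counterclockwise order, physical cm).  This
    automates what is otherwise a manual curve choice.
    """
    if chamber.count == 0:
        raise ValueError("empty chamber")
    axis = phase.axis
    planar = phase.planar_axes()
    idx = chamber.indices()
    lo, hi = idx[:, axis].min(), idx[:, axis].max()
    mid = (lo + hi) // 2
    sl = idx[idx[:, axis] == mid]
    if len(sl) < n_angles:
        raise ValueError("degenerate chamber cross-section at the mid-axis slice")
    pts = sl[:, [planar[0], planar[1]]].astype(float) * phase.spacing
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    ang = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    rad = np.linalg.norm(rel, axis=1)
    bins = (ang / (2 * np.pi) * n_angles).astype(int) % n_angles
    control = []
    for k in range(n_angles):
        in_bin = bins == k
        if not in_bin.any():
            raise ValueError(f"degenerate cross-section: empty angular bin {k}")
        r = rad[in_bin].max()
        theta = 2 * np.pi * (k + 0.5) / n_angles
        control.append(centroid + r * np.array([np.cos(theta), np.sin(theta)]))
    return np.array(control)


@dataclass
class ReferenceBundle:
    """The frozen end-to-end fixture: geometries, network, curves, config."""

    phase_ellipsoid: PhaseField
    seeds_ellipsoid: list
    phase_cylinder: PhaseField
    seeds_cylinder: list
    network: NetworkImage
    curve_points_ellipsoid: np.ndarray
    curve_points_cylinder: np.ndarray
    config: dict = field(default_factory=dict)


# Study-scale defaults: grid spacing 0.025 cm everywhere; the ellipsoid pair
# stands in for a two-chamber ventricular anatomy at ~80^3 desk scale.
REFERENCE_PARAMS = {
    "ellipsoid": {
        "shape": (80, 80, 80), "spacing": 0.025,
        "outer_semiaxes": (34, 26, 34), "cavity_semiaxes": (12, 16, 24),
        "cavity_offset": 16, "bump_amplitude": 0.5,
    },
    "cylinder": {
        "shape": (64, 64, 48), "spacing": 0.025,
        "inner_radius": 14, "outer_radius": 24, "axis": 2,
    },
    "network": {"W": 96, "H": 96, "depth": 4},
}


def reference_fixture(seed: int = 7, out_dir=None) -> ReferenceBundle:
    """Generate the reference input bundle (optionally writing it to disk).

    Contents: an ellipsoid-pair phase field (80^3, 0.025 cm spacing), an
    exact-cylinder phase field, a depth-4 network image with coupling sites
    and a bundle-branch flag, auto-fitted curves for both geometries, and a
    run configuration.  Deterministic per seed; see
    :func:`bundle_checksums`.
    """
    p = REFERENCE_PARAMS
    phase_e, seeds_e = synth_ventricles("ellipsoid_pair", p["ellipsoid"], seed=seed)
    phase_c, seeds_c = synth_ventricles("cylinder", p["cylinder"], seed=seed)
    net = synth_network_image(p["network"]["W"], p["network"]["H"],
                              p["network"]["depth"], seed=seed)
    ch_e = isolate_chamber(phase_e, seeds_e[0])
    ch_c = isolate_chamber(phase_c, seeds_c[0])
    cp_e = synth_curve_for(phase_e, ch_e)
    cp_c = synth_curve_for(phase_c, ch_c)
    config = {
        "seed": seed,
        "chart": {"n_seeds": 256, "quadrature_n": 512, "max_extent": 0.8},
        "shell": {"kernel_radius": 3, "tissue_threshold": 0.5},
        "ep": {"D0": 0.001, "ratio": 20.0, "g_c": 100.0, "dt": 0.005,
               "stim_amplitude": 50.0, "stim_duration": 2.0, "t_end": 120.0},
    }
    bundle = ReferenceBundle(
        phase_ellipsoid=phase_e, seeds_ellipsoid=seeds_e,
        phase_cylinder=phase_c, seeds_cylinder=seeds_c,
        network=net, curve_points_ellipsoid=cp_e, curve_points_cylinder=cp_c,
        config=config,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: ReferenceBundle, out: Path):
    import pandas as pd
    import yaml
    from PIL import Image

    from .io import write_volume

    out.mkdir(parents=True, exist_ok=True)
    write_volume(bundle.phase_ellipsoid, out / "ellipsoid_phase.nii")
    write_volume(bundle.phase_cylinder, out / "cylinder_phase.nii")
    # raster files use a top-left origin; flip back from mask[u1, u2]
    img = (bundle.network.mask.T[::-1, :] * 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(out / "network.png")
    rows = [
        {"site_id": sid, "u1": u1, "u2": u2, "kind": "coupling"}
        for sid, (u1, u2) in zip(bundle.network.site_ids, bundle.network.sites)
    ]
    bb = bundle.network.bundle_branch
    rows.append({"site_id": "bb0", "u1": bb[0], "u2": bb[1], "kind": "bundle_branch"})
    pd.DataFrame(rows).to_csv(out / "sites.csv", index=False)
    for name, cp in (
        ("curve_ellipsoid.json", bundle.curve_points_ellipsoid),
        ("curve_cylinder.json", bundle.curve_points_cylinder),
    ):
        with open(out / name, "w") as fh:
            json.dump({"control_points": cp.tolist(), "axis": 2}, fh, indent=1)
    with open(out / "run.yaml", "w") as fh:
        yaml.safe_dump(bundle.config, fh, sort_keys=True)
    with open(out / "chamber_seeds.json", "w") as fh:
        json.dump({"ellipsoid": [list(s) for s in bundle.seeds_ellipsoid],
                   "cylinder": [list(s) for s in bundle.seeds_cylinder]}, fh)


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def bundle_checksums(bundle: ReferenceBundle) -> dict:
    """SHA-256 digests of the bundle's canonical array contents."""
    return {
        "ellipsoid_phase": _digest(bundle.phase_ellipsoid.values),
        "cylinder_phase": _digest(bundle.phase_cylinder.values),
        "network_mask": _digest(bundle.network.mask.astype(np.uint8)),
        "network_sites": _digest(bundle.network.sites),
        "curve_ellipsoid": _digest(bundle.curve_points_ellipsoid),
        "curve_cylinder": _digest(bundle.curve_points_cylinder),
    }


def frozen_manifest() -> dict:
    """The checksums the shipped reference bundle (seed 7) must reproduce."""
    ref = resources.files("purkinje3d") / "data" / "reference_manifest.json"
    return json.loads(ref.read_text())
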