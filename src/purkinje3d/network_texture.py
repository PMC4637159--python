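"""Flat Purkinje-network textures and their projection onto endocardial shells.

The digitized network is a binary texture ``T : [0, W] x [0, H] -> {0, 1}``
with a list of coupling-site pixel coordinates marking the apparent fiber
ends (Purkinje-myocardial junctions).  A placement rectangle
``[a, b] x [c, d]`` positions the texture on the approximating cylinder:
pixel ``(u1, u2)`` lands at cylinder coordinates

    s = a + (u1 / W) (b - a),      z = c + (u2 / H) (d - c),

and the curvilinear chart extends the texture value along trajectories of
constant ``(s, z)`` into all of space,

    F(x, y, z) = T( (s - a) / (b - a) W,  (z - c) / (d - c) H ),

with ``s`` read off the chart at the planar point ``(x, y)``.  Evaluating F
inside the thin endocardial shell yields the voxelized three-dimensional
network.

Pixel convention: origin at the lower-left of the image, ``u1`` rightward
(increasing ``s``), ``u2`` upward (increasing ``z``); raster files with a
top-left origin are flipped on read.  Binary texture lookups use the
nearest pixel (no interpolation of a binary palette).  Aspect-ratio
distortion between the pixel and cylinder rectangles is permitted and
logged, since covering the endocardium realistically usually requires it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import cKDTree

from .chart import CurvilinearChart, from_curvilinear, to_curvilinear_grid
from .geometry import PhaseField, VoxelMask

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkImage",
    "PlacementRect",
    "ProjectedNetwork",
    "read_network",
    "pixel_to_cylinder",
    "evaluate_F",
    "project_network",
]


@dataclass
class NetworkImage:
    """Binary W x H network raster with coupling sites.

    ``mask[u1, u2]`` is 1 on fiber pixels; the first index runs along the
    image width.  ``sites`` holds coupling-site pixel coordinates (float,
    (n, 2)); ``bundle_branch`` optionally marks the His-bundle entry pixel
    where the stimulus is delivered.
    """

    mask: np.ndarray
    sites: np.ndarray
    site_ids: list = None
    bundle_branch: np.ndarray | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        if self.sites.size == 0:
            self.sites = np.zeros((0, 2))
        if self.site_ids is None:
            self.site_ids = list(range(len(self.sites)))
        W, H = self.mask.shape
        if len(self.sites) and (
            self.sites.min() < 0
            or self.sites[:, 0].max() > W
            or self.sites[:, 1].max() > H
        ):
            bad = [
                i for i, (u1, u2) in enumerate(self.sites)
                if not (0 <= u1 <= W and 0 <= u2 <= H)
            ]
            raise ValueError(f"coupling sites outside the raster: indices {bad}")

    @property
    def W(self) -> int:
        return self.mask.shape[0]

    @property
    def H(self) -> int:
        return self.mask.shape[1]

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class PlacementRect:
    """Cylinder-coordinate rectangle [a, b] x [c, d] carrying the texture.

    ``a, b`` are arc-length bounds (cm) along the approximating curve,
    ``b - a = L`` meaning a full wrap; ``c, d`` bound the axial extent (cm).
    """

    a: float
    b: float
    c: float
    d: float
    preserve_aspect: bool = False

    def __post_init__(self):
        if not (self.a < self.b and self.c < self.d):
            raise ValueError("placement rectangle requires a < b and c < d")

    def check_aspect(self, W: int, H: int):
        if self.preserve_aspect:
            ratio = (self.b - self.a) / (self.d - self.c)
            if abs(ratio - W / H) / (W / H) > 1e-6:
                raise ValueError(
                    f"preserve_aspect set but rect ratio {ratio:.6g} != W/H {W / H:.6g}"
                )


@dataclass
class ProjectedNetwork:
    """The network voxelized inside the shell, with site correspondences.

    ``site_voxels`` maps site index -> 3D voxel index (i, j, k);
    ``unmapped_sites`` lists site indices with no shell voxel within the
    mapping tolerance.  ``src_pixels`` records, for each network voxel, the
    texture pixel it samples (used by connectivity repair and round-trip
    diagnostics).
    """

    voxels: VoxelMask
    site_voxels: dict
    unmapped_sites: list
    bundle_voxel: tuple | None = None
    src_pixels: dict = field(default_factory=dict)


def read_network(image_file, sites_file) -> NetworkImage:
    """Read a network PNG plus a coupling-site CSV.

    The image is converted to a single channel and binarized at 50%
    intensity; top-left-origin rasters are flipped so that ``mask[u1, u2]``
    has the origin at the lower-left.  The CSV needs columns
    ``site_id, u1, u2`` and may carry a ``kind`` column; rows with
    ``kind == "bundle_branch"`` mark the stimulus entry pixel and are kept
    out of the coupling-site list.
    """
    img = Image.open(image_file).convert("L")
    arr = np.asarray(img)  # (rows, cols) top-left origin
    mask = (arr[::-1, :].T > 127).astype(bool)  # -> mask[u1, u2], lower-left origin
    W, H = mask.shape
    if not mask.any():
        logger.warning("network image %s has an empty fiber mask", image_file)

    df = pd.read_csv(sites_file)
    for col in ("site_id", "u1", "u2"):
        if col not in df.columns:
            raise ValueError(f"sites file missing column {col!r}")
    kind = df["kind"] if "kind" in df.columns else pd.Series("coupling", index=df.index)
    is_bb = kind.astype(str).str.strip() == "bundle_branch"
    bb = None
    if is_bb.any():
        row = df[is_bb].iloc[0]
        bb = np.array([float(row["u1"]), float(row["u2"])])
    sdf = df[~is_bb]
    sites = sdf[["u1", "u2"]].to_numpy(dtype=float)
    ids = sdf["site_id"].tolist()

    net = NetworkImage(mask=mask, sites=sites, site_ids=ids, bundle_branch=bb)
    # sites should sit at fiber ends: warn if any site is > 1 px from a fiber pixel
    if len(sites) and mask.any():
        fiber = np.argwhere(mask).astype(float)
        tree = cKDTree(fiber)
        d, _ = tree.query(sites)
        off = np.nonzero(d > 1.5)[0]
        for i in off:
            logger.warning(
                "site %s at (%g, %g) lies %.2f px from the nearest fiber pixel",
                ids[i], sites[i, 0], sites[i, 1], d[i],
            )
    return net


def pixel_to_cylinder(rect: PlacementRect, W: int, H: int, pixel, wrap_length=None):
    """Cylinder coordinates (s, z) of a texture pixel (u1, u2).

    Inverse of the texture-placement assignment; ``s`` is wrapped into
    ``[0, L)`` when ``wrap_length`` is given.
    """
    u1, u2 = float(pixel[0]), float(pixel[1])
    if not (0 <= u1 <= W and 0 <= u2 <= H):
        raise ValueError(f"pixel ({u1}, {u2}) outside [0, {W}] x [0, {H}]")
    s = rect.a + (u1 / W) * (rect.b - rect.a)
    z = rect.c + (u2 / H) * (rect.d - rect.c)
    if wrap_length is not None:
        s = float(np.mod(s, wrap_length))
    return s, z


def _texture_lookup(network: NetworkImage, u1, u2):
    """Nearest-pixel lookup on the binary mask; 0 outside [0, W] x [0, H]."""
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    W, H = network.mask.shape
    inside = (u1 >= 0) & (u1 <= W) & (u2 >= 0) & (u2 <= H)
    i = np.clip(np.floor(u1).astype(int), 0, W - 1)
    j = np.clip(np.floor(u2).astype(int), 0, H - 1)
    return np.where(inside, network.mask[i, j], False)


def _cylinder_to_pixels(chart, rect, network, s, z):
    """(u1, u2) texture coordinates of cylinder points; NaN outside the rect."""
    L = chart.wrap_length
    span = rect.b - rect.a
    ds = np.mod(np.asarray(s, dtype=float) - rect.a, L)
    u1 = np.where(ds <= span, ds / span * network.W, np.nan)
    z = np.asarray(z, dtype=float)
    zin = (z >= rect.c) & (z <= rect.d)
    u2 = np.where(zin, (z - rect.c) / (rect.d - rect.c) * network.H, np.nan)
    return u1, u2


def evaluate_F(chart: CurvilinearChart, rect: PlacementRect, network: NetworkImage, point):
    """Extended texture value F(x, y, z) at a 3D point.

    ``point`` is ``(p1, p2, z)`` with the planar pair first and the cylinder
    axis coordinate last (physical cm).  Returns 0 outside the placement
    rectangle; raises for planar points outside the charted region.
    """
    p = np.asarray(point, dtype=float)
    s, _ = to_curvilinear_grid(chart, p[:2][None, :])
    if not np.isfinite(s[0]):
        raise ValueError("planar point outside the charted region")
    u1, u2 = _cylinder_to_pixels(chart, rect, network, s, np.array([p[2]]))
    if not (np.isfinite(u1[0]) and np.isfinite(u2[0])):
        return 0
    return int(_texture_lookup(network, u1, u2)[0])


def _site_trajectory_points(chart, s, z, n_samples: int = 96):
    """3D sample points of the (s, z) trajectory, for shell intersection."""
    ts = np.linspace(-chart.max_extent, chart.max_extent, n_samples)
    ds = chart.seed_spacing
    L = chart.wrap_length
    s = float(np.mod(s, L))
    k0 = int(np.floor(s / ds)) % chart.n_seeds
    k1 = (k0 + 1) % chart.n_seeds
    frac = (s - k0 * ds) / ds
    tr0, tr1 = chart.trajectories[k0], chart.trajectories[k1]
    x0 = np.interp(ts, tr0.t, tr0.xy[:, 0])
    y0 = np.interp(ts, tr0.t, tr0.xy[:, 1])
    x1 = np.interp(ts, tr1.t, tr1.xy[:, 0])
    y1 = np.interp(ts, tr1.t, tr1.xy[:, 1])
    x = (1 - frac) * x0 + frac * x1
    y = (1 - frac) * y0 + frac * y1
    return np.column_stack([x, y, np.full_like(x, z)])


def map_pixels_to_voxels(
    chart: CurvilinearChart,
    rect: PlacementRect,
    network: NetworkImage,
    shell: VoxelMask,
    phase: PhaseField,
    pixels: np.ndarray,
    max_dist_vox: float = 3.0,
):
    """Map texture pixels to shell voxels via their (s, z) trajectories.

    For each pixel the trajectory through its ``(s, z)`` cylinder point is
    sampled and the shell voxel nearest (3D Euclidean) to the sampled
    polyline is taken; pixels whose nearest shell voxel is farther than
    ``max_dist_vox`` voxels are reported as unmapped (index -1).  Ties
    within 1e-9 cm resolve to the lowest linear voxel index.
    """
    sp = phase.spacing
    axis = phase.axis
    planar = phase.planar_axes()
    idx = shell.indices()
    if len(idx) == 0:
        return [None] * len(pixels)
    centers = np.column_stack([
        idx[:, planar[0]] * sp, idx[:, planar[1]] * sp, idx[:, axis] * sp
    ])
    lin = np.ravel_multi_index(idx.T, shell.flags.shape)
    tree = cKDTree(centers)
    out = []
    for u1, u2 in np.atleast_2d(pixels):
        s, z = pixel_to_cylinder(rect, network.W, network.H, (u1, u2), chart.wrap_length)
        pts = _site_trajectory_points(chart, s, z)
        d, j = tree.query(pts)
        dmin = d.min()
        if dmin > max_dist_vox * sp:
            out.append(None)
            continue
        cand = j[d <= dmin + 1e-9]
        best = cand[np.argmin(lin[cand])]
        out.append(tuple(int(v) for v in idx[best]))
    return out


def project_network(
    chart: CurvilinearChart,
    rect: PlacementRect,
    network: NetworkImage,
    shell: VoxelMask,
    phase: PhaseField,
) -> ProjectedNetwork:
    """Voxelize the network texture inside the endocardial shell.

    Network voxels are the shell voxels where F evaluates to 1 at the voxel
    center, augmented by the trajectory image of every fiber pixel (thin
    1-pixel fibers otherwise slip between voxel centers), followed by one
    pass of connectivity repair: any two network voxels whose source pixels
    are 8-adjacent but whose voxels are not 26-adjacent are joined by a
    straight bridging chord constrained to the shell (fine texture detail
    on a comparatively coarse voxel grid otherwise breaks fibers apart).
    Each coupling site is assigned the shell voxel nearest its (s, z)
    trajectory; sites beyond 3 voxels are reported unmapped.
    """
    rect.check_aspect(network.W, network.H)
    ratio = ((rect.b - rect.a) / (rect.d - rect.c)) / (network.W / network.H)
    if abs(ratio - 1) > 1e-6:
        logger.info("aspect ratio distorted by factor %.3f during placement", ratio)

    sp = phase.spacing
    axis = phase.axis
    planar = phase.planar_axes()
    idx = shell.indices()
    planar_pts = np.column_stack([idx[:, planar[0]] * sp, idx[:, planar[1]] * sp])
    s, _t = to_curvilinear_grid(chart, planar_pts)
    bad = ~np.isfinite(s)
    if bad.any():
        raise ValueError(
            f"chart does not cover the shell footprint: {int(bad.sum())} of "
            f"{len(idx)} shell voxels are uncharted (increase max_extent/bounds)"
        )
    z = idx[:, axis] * sp
    u1, u2 = _cylinder_to_pixels(chart, rect, network, s, z)
    inside = np.isfinite(u1) & np.isfinite(u2)
    vals = np.zeros(len(idx), dtype=bool)
    vals[inside] = _texture_lookup(network, u1[inside], u2[inside])

    flags = np.zeros(shell.flags.shape, dtype=bool)
    net_idx = idx[vals]
    flags[tuple(net_idx.T)] = True
    src_pixels = {
        tuple(int(v) for v in ijk): (
            int(np.clip(np.floor(a), 0, network.W - 1)),
            int(np.clip(np.floor(b), 0, network.H - 1)),
        )
        for ijk, a, b in zip(net_idx, u1[vals], u2[vals])
    }

    # forward pass: every fiber pixel contributes its nearest shell voxel
    fiber_px = np.argwhere(network.mask)
    fwd = map_pixels_to_voxels(
        chart, rect, network, shell, phase, fiber_px.astype(float) + 0.5
    )
    pix2vox = {}
    for px, vox in zip(map(tuple, fiber_px), fwd):
        if vox is None:
            continue
        pix2vox[px] = vox
        if not flags[vox]:
            flags[vox] = True
            src_pixels.setdefault(vox, px)
    # site assignment (before repair, so site voxels join the repaired network)
    site_voxels, unmapped = {}, []
    mapped = map_pixels_to_voxels(chart, rect, network, shell, phase, network.sites)
    for i, vox in enumerate(mapped):
        if vox is None:
            unmapped.append(i)
        else:
            site_voxels[i] = vox
            flags[vox] = True  # a site voxel is part of the network
    bundle_voxel = None
    if network.bundle_branch is not None:
        bb = map_pixels_to_voxels(
            chart, rect, network, shell, phase, network.bundle_branch[None, :]
        )[0]
        bundle_voxel = bb
        if bb is not None:
            flags[bb] = True
    if unmapped:
        logger.warning("%d coupling sites had no shell voxel within range", len(unmapped))

    n_bridge = _repair_connectivity(flags, shell.flags, src_pixels, pix2vox)
    n_bridge += _merge_components(flags, shell.flags)
    if n_bridge:
        logger.info("connectivity repair added %d bridging voxels", n_bridge)
    return ProjectedNetwork(
        voxels=VoxelMask(flags=flags, role="network"),
        site_voxels=site_voxels,
        unmapped_sites=unmapped,
        bundle_voxel=bundle_voxel,
        src_pixels=src_pixels,
    )


def _staircase(a: np.ndarray, b: np.ndarray):
    """Face-connected voxel path from a to b (endpoints excluded), axis by axis."""
    path = []
    cur = a.copy()
    for ax in range(len(a)):
        step = 1 if b[ax] > cur[ax] else -1
        while cur[ax] != b[ax]:
            cur[ax] += step
            path.append(cur.copy())
    return path[:-1] if path else []


def _merge_components(flags: np.ndarray, shell: np.ndarray) -> int:
    """Join remaining face-connectivity components along shell geodesics.

    The diffusion stencil is face-neighbor, so an electrically usable
    network must be a single 6-connected component.  Residual fragments
    (after pixel-level repair) are merged by breadth-first search through
    the shell: the shortest face-step path inside the shell from the main
    component to the nearest other fragment is added, repeatedly, until one
    component remains (or no path exists within the shell).
    """
    from scipy import ndimage as _ndi

    structure = _ndi.generate_binary_structure(flags.ndim, 1)
    shape = flags.shape
    strides = np.array([int(np.prod(shape[a + 1:])) for a in range(len(shape))])
    added = 0
    for _ in range(256):
        labels, n = _ndi.label(flags, structure=structure)
        if n <= 1:
            break
        sizes = _ndi.sum_labels(flags, labels, index=np.arange(1, n + 1))
        main = 1 + int(np.argmax(sizes))
        # multi-source BFS over shell voxels from the main component
        lab_flat = labels.ravel()
        shell_flat = shell.ravel()
        parent = {}
        frontier = [int(i) for i in np.flatnonzero(lab_flat == main)]
        seen = set(frontier)
        target = None
        while frontier and target is None:
            nxt = []
            for u in frontier:
                coord = np.unravel_index(u, shape)
                for a in range(len(shape)):
                    for sgn in (-1, 1):
                        if not 0 <= coord[a] + sgn < shape[a]:
                            continue
                        w = u + sgn * strides[a]
                        if w in seen or not shell_flat[w]:
                            continue
                        seen.add(w)
                        parent[w] = u
                        if lab_flat[w] > 0 and lab_flat[w] != main:
                            target = w
                            break
                        nxt.append(w)
                    if target is not None:
                        break
                if target is not None:
                    break
            frontier = nxt
        if target is None:
            break  # fragment unreachable within the shell
        u = parent.get(target)
        fl = flags.ravel()
        while u is not None and not fl[u]:
            fl[u] = True
            added += 1
            u = parent.get(u)
    return added


def _repair_connectivity(
    flags: np.ndarray, shell: np.ndarray, src_pixels: dict, pix2vox: dict | None = None
) -> int:
    """Make pixel-adjacent network voxels face-connected.

    Diffusion uses a face-neighbor stencil, so merely corner- or
    edge-adjacent voxels carry no flux; every voxel pair whose source
    pixels are 8-adjacent (or identical, for radial stacks) is joined by a
    staircase of face steps constrained to the shell.
    """
    by_pixel: dict = {}
    for vox, px in src_pixels.items():
        by_pixel.setdefault(px, []).append(np.array(vox))
    for px, vox in (pix2vox or {}).items():
        voxs = by_pixel.setdefault(px, [])
        if not any(tuple(v) == vox for v in voxs):
            voxs.append(np.array(vox))
    added = 0
    offs = [(di, dj) for di in (0, 1) for dj in (-1, 0, 1) if (di, dj) > (0, -1)]
    for px, voxs in sorted(by_pixel.items()):
        for di, dj in [(0, 0)] + offs:
            q = (px[0] + di, px[1] + dj)
            if q not in by_pixel:
                continue
            qvoxs = by_pixel[q] if q != px else voxs
            pairs = [
                (a, b) for a in voxs for b in qvoxs
                if np.abs(a - b).max() > 0
            ]
            if not pairs:
                continue
            if any(np.abs(a - b).sum() <= 1 for a, b in pairs):
                continue  # already face-adjacent somewhere
            a, b = min(pairs, key=lambda ab: int(np.sum((ab[0] - ab[1]) ** 2)))
            for v in _staircase(a, b):
                v = tuple(int(x) for x in v)
                if shell[v] and not flags[v]:
                    flags[v] = True
                    added += 1
    return added
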