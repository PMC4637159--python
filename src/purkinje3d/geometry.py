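"""Phase-field ventricular geometry: chambers, endocardial shells, synthetic fixtures.

Ventricles are carried as a phase field ``phi`` on a uniform voxel grid:
``phi ~ 1`` inside tissue, ``phi ~ 0`` outside, with a smooth (tanh)
transition a couple of voxels wide.  The phase field both defines the
anatomy and, in the electrophysiology solver, imposes no-flux boundary
conditions on the regular grid without a boundary-fitted mesh.

The endocardial layer is isolated in three steps: flood-fill the chamber
cavity (``phi`` below a threshold, 6-connected), expand it by convolving the
chamber indicator with a spherical kernel and keeping entries strictly
greater than 1, and intersect the expansion with the tissue
(``phi >= tissue threshold``).  The resulting thin shell overlaps the wall
by roughly the kernel radius.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseField",
    "VoxelMask",
    "isolate_chamber",
    "extract_shell",
    "synth_ventricles",
]

TISSUE_THRESHOLD = 0.5


@dataclass
class PhaseField:
    """Scalar tissue indicator in [0, 1] on a uniform voxel grid.

    ``axis`` names the principal grid axis playing the role of the
    approximating-cylinder axis (0, 1 or 2); the remaining two axes, in
    order, span the chart plane.  ``spacing`` is the voxel edge length in cm.
    """

    values: np.ndarray
    spacing: float
    axis: int = 2

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.axis not in (0, 1, 2):
            raise ValueError("axis must be one of 0, 1, 2")
        v = self.values
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("phase-field values must lie in [0, 1]")

    @property
    def shape(self):
        return self.values.shape

    def tissue_mask(self, threshold: float = TISSUE_THRESHOLD) -> "VoxelMask":
        return VoxelMask(flags=self.values >= threshold, role="tissue")

    def planar_axes(self) -> tuple:
        return tuple(a for a in range(3) if a != self.axis)


@dataclass
class VoxelMask:
    """Boolean voxel mask congruent with a PhaseField; role documents intent."""

    flags: np.ndarray
    role: str  # chamber | shell | tissue | network

    def __post_init__(self):
        if self.role not in {"chamber", "shell", "tissue", "network"}:
            raise ValueError(f"unknown mask role {self.role!r}")
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.flags.sum())

    def indices(self) -> np.ndarray:
        """(n, ndim) integer voxel indices of set flags, C-order."""
        return np.argwhere(self.flags)


def isolate_chamber(phase: PhaseField, seed_voxel, threshold: float = 0.5) -> VoxelMask:
    """Flood-fill the cavity containing ``seed_voxel``.

    Returns the 6-connected component of ``{phi < threshold}`` containing the
    seed.  Raises ``ValueError`` if the seed lies in tissue; warns if the
    component touches the array boundary (the cavity may be open).
    """
    seed_voxel = tuple(int(i) for i in seed_voxel)
    if phase.values[seed_voxel] >= threshold:
        raise ValueError(
            f"seed voxel {seed_voxel} has phi={phase.values[seed_voxel]:.3f} "
            f">= threshold {threshold}; it must lie inside the cavity"
        )
    below = phase.values < threshold
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(below, structure=structure)
    comp = labels == labels[seed_voxel]
    if (
        comp[0].any() or comp[-1].any()
        or comp[:, 0].any() or comp[:, -1].any()
        or comp[:, :, 0].any() or comp[:, :, -1].any()
    ):
        warnings.warn("chamber component touches the array boundary; cavity may be open")
    return VoxelMask(flags=comp, role="chamber")


def _ball_kernel(radius_vox: float) -> np.ndarray:
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return (gx**2 + gy**2 + gz**2 <= radius_vox**2 + 1e-9).astype(np.int32)


def extract_shell(
    phase: PhaseField,
    chamber: VoxelMask,
    kernel_radius: float = 3.0,
    tissue_threshold: float = TISSUE_THRESHOLD,
) -> VoxelMask:
    """Thin endocardial shell around a chamber.

    Convolves the chamber indicator with the voxelized ball of
    ``kernel_radius`` (in voxels), keeps counts strictly greater than 1, and
    intersects with ``{phi >= tissue_threshold}``.  The shell overlaps the
    wall by about the kernel radius.
    """
    if kernel_radius < 1:
        raise ValueError("kernel_radius must be at least 1 voxel")
    if chamber.count == 0:
        warnings.warn("empty chamber mask: shell is empty")
        return VoxelMask(flags=np.zeros(phase.shape, dtype=bool), role="shell")
    kernel = _ball_kernel(kernel_radius)
    counts = ndimage.convolve(
        chamber.flags.astype(np.int32), kernel, mode="constant", cval=0
    )
    expanded = counts > 1
    shell = expanded & (phase.values >= tissue_threshold)
    # warn when the kernel reaches through the whole wall
    tissue = phase.values >= tissue_threshold
    reach = ndimage.binary_dilation(
        chamber.flags, structure=ndimage.generate_binary_structure(3, 3),
        iterations=int(np.ceil(kernel_radius)) + 1,
    )
    if np.array_equal(shell | ~reach, tissue | ~reach) and (tissue & reach).any():
        warnings.warn("kernel radius exceeds wall thickness: shell spans the full wall")
    return VoxelMask(flags=shell, role="shell")


def _smooth_indicator(signed_dist_vox: np.ndarray, width_vox: float = 1.0) -> np.ndarray:
    """tanh profile: 1 deep inside (negative distance), 0 outside."""
    return 0.5 * (1.0 - np.tanh(signed_dist_vox / width_vox))


def synth_ventricles(kind: str, params: dict | None = None, seed: int = 0):
    """Deterministic synthetic phase-field ventricles.

    Parameters
    ----------
    kind : {"ellipsoid_pair", "cylinder", "hollow_sphere"}
        ``ellipsoid_pair`` — two ellipsoidal cavities sharing a septal wall
        inside one tissue ellipsoid (a two-chamber topology); ``cylinder`` —
        a cavity that is an exact right circular cylinder, so the
        approximating-cylinder chart has zero distortion; ``hollow_sphere``
        — a spherical cavity in a spherical wall.
    params : dict
        Geometric parameters in voxels (see defaults in the source); all
        kinds accept ``shape`` and ``spacing``; the ellipsoid pair accepts
        ``bump_amplitude`` (voxels) controlling a seeded low-order angular
        perturbation of the cavity walls emulating anatomical irregularity.
    seed : int
        RNG seed for the perturbation; same (kind, params, seed) gives
        bit-identical volumes.

    Returns
    -------
    (PhaseField, list of chamber seed voxels)
    """
    params = dict(params or {})
    kind_fns = {
        "ellipsoid_pair": _synth_ellipsoid_pair,
        "cylinder": _synth_cylinder,
        "hollow_sphere": _synth_hollow_sphere,
    }
    if kind not in kind_fns:
        raise ValueError(f"unknown geometry kind {kind!r}")
    return kind_fns[kind](params, seed)


def _grid(shape):
    return np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")


def _synth_hollow_sphere(params, seed):
    shape = tuple(params.get("shape", (64, 64, 64)))
    spacing = float(params.get("spacing", 0.025))
    r_in = float(params.get("inner_radius", 10))
    r_out = float(params.get("outer_radius", 18))
    if not 0 < r_in < r_out:
        raise ValueError("need 0 < inner_radius < outer_radius")
    gx, gy, gz = _grid(shape)
    c = [(n - 1) / 2.0 for n in shape]
    r = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2)
    phi = _smooth_indicator(r - r_out) * (1.0 - _smooth_indicator(r - r_in))
    seeds = [tuple(int(round(ci)) for ci in c)]
    return PhaseField(values=np.clip(phi, 0, 1), spacing=spacing, axis=2), seeds


def _synth_cylinder(params, seed):
    shape = tuple(params.get("shape", (64, 64, 48)))
    spacing = float(params.get("spacing", 0.025))
    axis = int(params.get("axis", 2))
    r_in = float(params.get("inner_radius", 14))
    r_out = float(params.get("outer_radius", 24))
    if not 0 < r_in < r_out:
        raise ValueError("need 0 < inner_radius < outer_radius")
    grids = _grid(shape)
    planar = [a for a in range(3) if a != axis]
    c = [(shape[a] - 1) / 2.0 for a in range(3)]
    r = np.sqrt(sum((grids[a] - c[a]) ** 2 for a in planar))
    phi = _smooth_indicator(r - r_out) * (1.0 - _smooth_indicator(r - r_in))
    seeds = [tuple(int(round(ci)) for ci in c)]
    return PhaseField(values=np.clip(phi, 0, 1), spacing=spacing, axis=axis), seeds


def _synth_ellipsoid_pair(params, seed):
    shape = tuple(params.get("shape", (80, 80, 80)))
    spacing = float(params.get("spacing", 0.025))
    outer = np.asarray(params.get("outer_semiaxes", (34, 26, 34)), dtype=float)
    cav = np.asarray(params.get("cavity_semiaxes", (12, 16, 24)), dtype=float)
    offset = float(params.get("cavity_offset", 16))
    bump = float(params.get("bump_amplitude", 0.5))
    if np.any(cav <= 0) or np.any(outer <= 0) or offset + cav[0] >= outer[0]:
        raise ValueError("degenerate radii: cavities must fit inside the outer ellipsoid")
    gx, gy, gz = _grid(shape)
    c = [(n - 1) / 2.0 for n in shape]

    def ell(center, semi, rho_pert=None):
        rho = np.sqrt(
            ((gx - center[0]) / semi[0]) ** 2
            + ((gy - center[1]) / semi[1]) ** 2
            + ((gz - center[2]) / semi[2]) ** 2
        )
        dist = (rho - 1.0) * semi.min()
        if rho_pert is not None:
            dist = dist + rho_pert
        return _smooth_indicator(dist)

    rng = np.random.default_rng(seed)
    theta = np.arctan2(gy - c[1], gx - c[0])

    def angular_bumps():
        if bump == 0:
            return None
        amps = rng.normal(0, bump / 2.0, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        pert = np.zeros_like(theta)
        for m, (a, ph) in enumerate(zip(amps, phases), start=2):
            pert += a * np.cos(m * theta + ph)
        return pert

    tissue = ell(c, outer)
    cav_a = ell([c[0] - offset, c[1], c[2]], cav, angular_bumps())
    cav_b = ell([c[0] + offset, c[1], c[2]], cav, angular_bumps())
    phi = tissue * (1.0 - cav_a) * (1.0 - cav_b)
    seeds = [
        (int(round(c[0] - offset)), int(round(c[1])), int(round(c[2]))),
        (int(round(c[0] + offset)), int(round(c[1])), int(round(c[2]))),
    ]
    return PhaseField(values=np.clip(phi, 0, 1), spacing=spacing, axis=2), seeds
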