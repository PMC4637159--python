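"""Volume, mask, activation-map and chart persistence (NIfTI dialect).

Volumes travel as uncompressed NIfTI-1 with the voxel spacing in the
affine/zooms and package metadata (object kind, mask role, cylinder axis)
packed into the header ``descrip`` field, e.g. ``purkinje3d:kind=phase;axis=2``.
Round trips are bit-exact: phase fields and activation maps are stored as
float64, masks as uint8.  Files without spacing metadata are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .activation import ActivationMap
from .geometry import PhaseField, VoxelMask

__all__ = ["write_volume", "read_volume", "write_chart", "read_chart_arrays"]


def _make_img(data: np.ndarray, spacing: float, descrip: str) -> nib.Nifti1Image:
    if data.ndim == 2:
        data = data[:, :, None]
    affine = np.diag([spacing, spacing, spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    # NIfTI zooms are float32; carry the exact spacing in the descrip field
    img.header["descrip"] = f"{descrip};sp={spacing!r}".encode()
    img.header.set_zooms((spacing,) * 3)
    return img


def write_volume(obj, path, spacing: float | None = None, axis: int | None = None):
    """Write a PhaseField, VoxelMask, ActivationMap or raw array to NIfTI."""
    path = str(path)
    if isinstance(obj, PhaseField):
        img = _make_img(obj.values.astype(np.float64),
                        obj.spacing, f"purkinje3d:kind=phase;axis={obj.axis}")
    elif isinstance(obj, VoxelMask):
        if spacing is None:
            raise ValueError("writing a mask requires the voxel spacing")
        img = _make_img(obj.flags.astype(np.uint8), spacing,
                        f"purkinje3d:kind=mask;role={obj.role};axis={axis or 0}")
    elif isinstance(obj, ActivationMap):
        if spacing is None:
            raise ValueError("writing an activation map requires the node spacing")
        img = _make_img(
            np.asarray(obj.times, dtype=np.float64), spacing,
            f"purkinje3d:kind=activation;thr={obj.threshold};t0={obj.stim_start}",
        )
    else:
        if spacing is None:
            raise ValueError("writing a raw array requires the spacing")
        img = _make_img(np.asarray(obj), spacing, "purkinje3d:kind=array")
    nib.save(img, path)


def _parse_descrip(img) -> dict:
    raw = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="replace")
    if not raw.startswith("purkinje3d:"):
        return {}
    out = {}
    for part in raw.split(":", 1)[1].split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_volume(path):
    """Read a volume, dispatching on the stored kind.

    Returns a PhaseField, VoxelMask, ActivationMap, or ``(array, spacing)``
    for plain arrays.  Raises if spacing metadata is missing (zero zooms).
    """
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    meta0 = _parse_descrip(img)
    if "sp" in meta0:
        spacing = float(meta0["sp"])
    elif all(z > 0 for z in zooms):
        spacing = float(zooms[0])
    else:
        raise ValueError(f"{path}: missing or invalid spacing metadata (zooms={zooms})")
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    meta = meta0
    kind = meta.get("kind")
    if kind == "phase":
        return PhaseField(values=np.asarray(data, dtype=np.float64),
                          spacing=spacing, axis=int(meta.get("axis", 2)))
    if kind == "mask":
        return VoxelMask(flags=data.astype(bool), role=meta.get("role", "tissue"))
    if kind == "activation":
        return ActivationMap(times=np.asarray(data, dtype=np.float64),
                             threshold=float(meta.get("thr", 0.5)),
                             stim_start=float(meta.get("t0", 0.0)))
    return np.asarray(data), spacing


def write_chart(chart, prefix):
    """Export the chart's s- and t-maps plus metadata for reuse across runs."""
    prefix = Path(prefix)
    spacing = float(chart.xs[1] - chart.xs[0])
    write_volume(chart.s_map, f"{prefix}_smap.nii", spacing=spacing)
    write_volume(chart.t_map, f"{prefix}_tmap.nii", spacing=spacing)
    meta = {
        "L": chart.wrap_length,
        "n_seeds": chart.n_seeds,
        "step": chart.step,
        "max_extent": chart.max_extent,
        "origin": [float(chart.xs[0]), float(chart.ys[0])],
        "spacing": spacing,
    }
    with open(f"{prefix}_chart.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_chart_arrays(prefix):
    """Read back exported chart arrays: (s_map, t_map, metadata dict)."""
    s_map, _ = read_volume(f"{prefix}_smap.nii")
    t_map, _ = read_volume(f"{prefix}_tmap.nii")
    with open(f"{prefix}_chart.json") as fh:
        meta = json.load(fh)
    return s_map, t_map, meta
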