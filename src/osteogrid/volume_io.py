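"""Voxel-volume containers and stack / table I/O.

A scanned short bone arrives as a stack of 2D images (one file per slice,
16-bit or 8-bit) with an isotropic voxel spacing.  ``VoxelVolume`` is the
in-memory container used throughout the package: a 3D array whose last axis
is the slice (stacking) axis, plus the voxel edge length in mm and a mapping
of lattice axes to anatomical axes.

Conventions
-----------
* Isotropic voxels only; anisotropic reconstructions must be resampled
  before entering the pipeline (every distance-based algorithm here assumes
  a single spacing).
* 0-based lattice indices; the physical position of index ``i`` is
  ``i * spacing`` mm; extents are half-open.
* Slice order is lexicographic filename order unless an explicit file list
  is given.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import RaggedStackError, ValidationError

#: default anatomical roles of the three lattice axes
DEFAULT_AXIS_ROLES: Mapping[str, int] = {
    "radioulnar": 0,
    "dorsopalmar": 1,
    "proximodistal": 2,
}

#: compartment label codes used across the package
LABEL_BACKGROUND = 0
LABEL_CORTICAL_BONE = 1
LABEL_CORTICAL_PORE = 2
LABEL_TRABECULAR_BONE = 3
LABEL_INTERNAL = 4
ALL_LABELS = (
    LABEL_BACKGROUND,
    LABEL_CORTICAL_BONE,
    LABEL_CORTICAL_PORE,
    LABEL_TRABECULAR_BONE,
    LABEL_INTERNAL,
)


@dataclass
class VoxelVolume:
    """A 3D scalar lattice with isotropic voxel spacing in mm.

    ``data`` may hold greyscale intensities, a binary bone indicator,
    compartment label codes, or a thickness field in mm.
    """

    data: np.ndarray
    spacing: float
    origin: tuple[int, int, int] = (0, 0, 0)
    axis_roles: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_AXIS_ROLES)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume must be 3D, got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValidationError("lattice dimensions must all be >= 1")
        if not (self.spacing > 0):
            raise ValidationError(f"spacing must be > 0 mm, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def proximodistal_axis(self) -> int:
        return int(self.axis_roles["proximodistal"])

    def is_binary(self) -> bool:
        vals = np.unique(self.data)
        return np.isin(vals, (0, 1)).all()

    def validate_binary(self) -> None:
        if not self.is_binary():
            raise ValidationError("payload is not binary {0, 1}")

    def validate_labels(self) -> None:
        if not np.isin(np.unique(self.data), ALL_LABELS).all():
            raise ValidationError("payload contains unregistered label codes")

    def validate_thickness(self) -> None:
        if (np.asarray(self.data) < 0).any():
            raise ValidationError("thickness payload must be >= 0 everywhere")

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        return replace(self, data=data)


@dataclass
class SpecimenRecord:
    """Metadata row for one specimen of a comparative sample."""

    specimen_id: str
    group: str
    sex: str = "unknown"
    cut_plane_index: int | None = None
    volume_path: str | None = None

    def validate_against(self, volume: VoxelVolume) -> None:
        axis = volume.proximodistal_axis
        n = volume.shape[axis]
        if self.cut_plane_index is not None and not (
            0 < self.cut_plane_index < n
        ):
            raise ValidationError(
                f"cut_plane_index {self.cut_plane_index} not strictly inside "
                f"[1, {n - 1}] on the proximodistal axis"
            )


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------

_SIDECAR = "stack_meta.json"


def read_stack(
    path_pattern: str | Sequence[str],
    spacing: float | None = None,
    axis_roles: Mapping[str, int] | None = None,
) -> VoxelVolume:
    """Read a multi-file image stack (one 2D image per slice) into a volume.

    ``path_pattern`` is a glob pattern, a directory containing the stack, or
    an explicit file list (which overrides lexicographic ordering).  If the
    directory holds a sidecar metadata file written by :func:`write_stack`,
    spacing / axis roles / thickness scale are recovered from it; an explicit
    ``spacing`` argument overrides the sidecar.
    """
    meta = None
    if isinstance(path_pattern, (str, os.PathLike)):
        path_pattern = os.fspath(path_pattern)
        if os.path.isdir(path_pattern):
            sidecar = os.path.join(path_pattern, _SIDECAR)
            if os.path.exists(sidecar):
                with open(sidecar) as fh:
                    meta = json.load(fh)
            files = sorted(
                glob.glob(os.path.join(path_pattern, "*.tif"))
                + glob.glob(os.path.join(path_pattern, "*.tiff"))
            )
        else:
            files = sorted(glob.glob(path_pattern))
    else:
        files = [os.fspath(p) for p in path_pattern]
    if not files:
        raise ValidationError(f"no slice files match {path_pattern!r}")

    slices = []
    shape0 = dtype0 = None
    for f in files:
        if not os.path.exists(f):
            raise ValidationError(f"missing slice file: {f}")
        sl = tifffile.imread(f)
        if sl.ndim != 2:
            raise RaggedStackError(f"slice {f} is not 2D (shape {sl.shape})")
        if shape0 is None:
            shape0, dtype0 = sl.shape, sl.dtype
        elif sl.shape != shape0 or sl.dtype != dtype0:
            raise RaggedStackError(
                f"slice {f} has shape {sl.shape}/{sl.dtype}, "
                f"expected {shape0}/{dtype0}"
            )
        slices.append(sl)
    data = np.stack(slices, axis=-1)

    if meta is not None:
        if spacing is None:
            spacing = float(meta["spacing"])
        if axis_roles is None:
            axis_roles = {k: int(v) for k, v in meta["axis_roles"].items()}
        scale = meta.get("thickness_scale")
        if scale is not None:
            data = data.astype(np.float64) * float(scale)
    if spacing is None:
        raise ValidationError("spacing must be given (no sidecar found)")
    if axis_roles is None:
        axis_roles = dict(DEFAULT_AXIS_ROLES)
    return VoxelVolume(data=data, spacing=float(spacing), axis_roles=dict(axis_roles))


def write_stack(volume: VoxelVolume, path: str, prefix: str = "slice") -> list[str]:
    """Write a volume as one TIFF per slice plus a plain-text sidecar.

    Integer payloads (binary masks, labels, greyscale) are written verbatim.
    Floating thickness payloads are rescaled to 16-bit; the scale factor is
    recorded in the sidecar so :func:`read_stack` restores mm values to
    within one quantisation step.
    """
    os.makedirs(path, exist_ok=True)
    data = np.asarray(volume.data)
    meta: dict = {
        "spacing": volume.spacing,
        "axis_roles": dict(volume.axis_roles),
        "shape": list(data.shape),
    }
    if np.issubdtype(data.dtype, np.floating):
        volume.validate_thickness()
        vmax = float(data.max())
        scale = (vmax / 65535.0) if vmax > 0 else 1.0
        out = np.round(data / scale).astype(np.uint16)
        meta["thickness_scale"] = scale
    else:
        if data.min() < 0 or data.max() > 65535:
            raise ValidationError("integer payload not representable in 16 bit")
        out = data.astype(np.uint16 if data.max() > 255 else np.uint8)

    nslices = out.shape[2]
    width = max(4, len(str(nslices)))
    written = []
    for k in range(nslices):
        f = os.path.join(path, f"{prefix}_{k:0{width}d}.tif")
        tifffile.imwrite(f, out[:, :, k])
        written.append(f)
    with open(os.path.join(path, _SIDECAR), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return written


# ---------------------------------------------------------------------------
# raw + header I/O (single-file alternative to TIFF stacks)
# ---------------------------------------------------------------------------

def write_raw(volume: VoxelVolume, path_stem: str) -> tuple[str, str]:
    """Write ``<stem>.raw`` (C-order voxel payload) + ``<stem>.hdr`` text header."""
    data = np.ascontiguousarray(volume.data)
    raw, hdr = path_stem + ".raw", path_stem + ".hdr"
    data.tofile(raw)
    with open(hdr, "w") as fh:
        fh.write(f"dims: {data.shape[0]} {data.shape[1]} {data.shape[2]}\n")
        fh.write(f"spacing: {volume.spacing!r}\n")
        fh.write(f"dtype: {data.dtype.name}\n")
        roles = " ".join(f"{k}={v}" for k, v in volume.axis_roles.items())
        fh.write(f"axis_roles: {roles}\n")
    return raw, hdr


def read_raw(path_stem: str) -> VoxelVolume:
    raw, hdr = path_stem + ".raw", path_stem + ".hdr"
    fields: dict[str, str] = {}
    with open(hdr) as fh:
        for line in fh:
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
    dims = tuple(int(t) for t in fields["dims"].split())
    dtype = np.dtype(fields["dtype"])
    roles = dict(
        (k, int(v)) for k, v in (t.split("=") for t in fields["axis_roles"].split())
    )
    data = np.fromfile(raw, dtype=dtype).reshape(dims)
    return VoxelVolume(data=data, spacing=float(fields["spacing"]), axis_roles=roles)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def write_table(rows, path: str) -> str:
    """Write records as UTF-8 CSV (header + one row per record, '.' decimals).

    ``rows`` is a list of dicts / dataclass-likes with identical field names,
    or a DataFrame.  Heterogeneous field names raise ``ValidationError``.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        dicts = []
        for r in rows:
            if hasattr(r, "__dataclass_fields__"):
                r = {k: getattr(r, k) for k in r.__dataclass_fields__}
            dicts.append(dict(r))
        if dicts:
            names = list(dicts[0].keys())
            for d in dicts[1:]:
                if list(d.keys()) != names:
                    raise ValidationError(
                        f"heterogeneous field names: {list(d.keys())} != {names}"
                    )
        df = pd.DataFrame(dicts)
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")
    return path


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
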