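"""Image-stack, mesh and table I/O with explicit physical-unit metadata.

Axis order is (z, y, x) everywhere: z is the section (block-face) axis.
Physical coordinates are carried in nanometres internally and reported in
micrometres in tables, matching how section thickness (nm) and chromosome
volumes (um^3) are conventionally quoted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

NM_PER_UM = 1000.0
UM3_PER_NM3 = 1e-9


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar field with anisotropic voxel spacing.

    Parameters
    ----------
    data:
        3D array in (z, y, x) order.
    spacing_nm:
        Voxel pitch (sz, sy, sx) in nanometres; all entries > 0.
    origin_nm:
        Physical position of voxel (0, 0, 0), voxel-center convention.
    """

    data: np.ndarray
    spacing_nm: tuple[float, float, float]
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if np.asarray(self.data).ndim != 3:
            raise ValueError("VoxelGrid data must be exactly 3-dimensional")
        if len(self.spacing_nm) != 3 or any(s <= 0 for s in self.spacing_nm):
            raise ValueError("spacing_nm must be three positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing_nm
        return sz * sy * sx * UM3_PER_NM3

    @property
    def physical_volume_um3(self) -> float:
        return self.voxel_volume_um3 * float(np.prod(self.data.shape))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical edge lengths (z, y, x) in micrometres."""
        return tuple(
            n * s / NM_PER_UM for n, s in zip(self.data.shape, self.spacing_nm)
        )


@dataclass(frozen=True)
class LabelVolume:
    """Integer object map aligned to a :class:`VoxelGrid`.

    Background is 0 and object ids form the contiguous set ``1..n_labels``.
    """

    labels: np.ndarray
    spacing_nm: tuple[float, float, float]
    origin_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise ValueError("LabelVolume labels must be 3-dimensional")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        present = np.unique(lab)
        present = present[present > 0]
        n = int(present.max(initial=0))
        if present.size != n:
            raise ValueError("label ids must be contiguous 1..n_labels")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing_nm
        return sz * sy * sx * UM3_PER_NM3

    def volumes_um3(self) -> np.ndarray:
        """Per-label physical volume, index i -> label i+1."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)
        return counts[1:] * self.voxel_volume_um3


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(grid: VoxelGrid | LabelVolume, path: str | Path) -> Path:
    """Write a grid as a multi-page TIFF plus a JSON sidecar with spacing.

    Integer data round-trips bit-identically through
    :func:`read_stack`/:func:`read_labels`.
    """
    path = Path(path)
    data = grid.data if isinstance(grid, VoxelGrid) else grid.labels
    tifffile.imwrite(path, np.asarray(data))
    meta = {
        "spacing_nm": list(grid.spacing_nm),
        "origin_nm": list(grid.origin_nm),
        "axis_order": "zyx",
        "kind": "labels" if isinstance(grid, LabelVolume) else "grayscale",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def _read_pages(path: Path) -> np.ndarray:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2D/3D grayscale stack, got shape {data.shape}")
    return data


def _read_spacing(path: Path, spacing_override) -> tuple:
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing_override must be three positive values (sz, sy, sx) in nm")
        return spacing, (0.0, 0.0, 0.0)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(
            f"{path}: no spacing metadata (missing sidecar {sidecar.name}); "
            "pass spacing_override=(sz, sy, sx) in nm — a silent default would corrupt all measurements"
        )
    meta = json.loads(sidecar.read_text())
    return tuple(meta["spacing_nm"]), tuple(meta.get("origin_nm", (0.0, 0.0, 0.0)))


def read_stack(path: str | Path, spacing_override=None) -> VoxelGrid:
    """Read a multi-page TIFF as a :class:`VoxelGrid` (z = page order).

    Spacing comes from the JSON sidecar written by :func:`write_stack`
    unless ``spacing_override`` (sz, sy, sx in nm) is given. A stack with
    no spacing information is an error, never a silent default.
    """
    path = Path(path)
    data = _read_pages(path)
    spacing, origin = _read_spacing(path, spacing_override)
    return VoxelGrid(data=data, spacing_nm=spacing, origin_nm=origin)


def read_labels(path: str | Path, spacing_override=None) -> LabelVolume:
    """Read a multi-page integer TIFF as a :class:`LabelVolume`."""
    path = Path(path)
    data = _read_pages(path)
    spacing, origin = _read_spacing(path, spacing_override)
    return LabelVolume(labels=data.astype(np.int32, copy=False), spacing_nm=spacing, origin_nm=origin)


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    """Write a triangle mesh (um coordinates) as PLY or OBJ.

    A non-watertight mesh is written with a warning rather than dropped,
    since downstream area sums remain meaningful.
    """
    path = Path(path)
    if not mesh.is_watertight:
        warnings.warn(f"{path.name}: mesh is not watertight", stacklevel=2)
    mesh.export(path)
    return path


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    return trimesh.load_mesh(Path(path))


def write_table(records, path: str | Path) -> Path:
    """Write morphometry (or any) records as CSV with unit-annotated headers.

    ``records`` may be a DataFrame or an iterable of dataclass-like rows
    exposing ``as_dict``. An empty record list yields a header-only CSV
    when the schema is known (DataFrame input).
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in records]
        if rows:
            df = pd.DataFrame(rows)
        else:
            from chromovol.morphometry import MorphometryRecord

            df = pd.DataFrame(columns=MorphometryRecord.columns())
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
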