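"""NIfTI volume I/O, geometry files, and study bundles."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import VoxelVolume
from .geometry import LVGeometry, capsule_geometry


class VolumeIOError(ValueError):
    pass


def read_volume(path) -> VoxelVolume:
    """Read a NIfTI-1 volume into a :class:`VoxelVolume`.

    The affine must be axis-aligned (diagonal rotation part with positive
    scales); rotated or sheared orientations are rejected because the
    package's index order (x, y, z) must map directly onto world axes.
    Values are returned in the on-disk dtype (no scaling applied), so a
    float32 round trip is bit-exact.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        affine = img.affine
        data = np.asarray(img.dataobj)
    except Exception as exc:  # corrupt header/payload
        raise VolumeIOError(f"could not read NIfTI volume {path}: {exc}") from exc
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-6 * max(1.0, np.abs(rot).max()):
        raise VolumeIOError(f"{path}: non-axis-aligned affine is not supported")
    spacing = np.diag(rot)
    if (spacing <= 0).any():
        raise VolumeIOError(f"{path}: affine must have positive diagonal spacing")
    return VoxelVolume(data, tuple(spacing), tuple(affine[:3, 3]))


def write_volume(volume: VoxelVolume, path, dtype=None) -> Path:
    """Write a volume as NIfTI-1 with spacing/origin encoded in the affine."""
    path = Path(path)
    values = volume.values
    if dtype is not None:
        values = values.astype(dtype)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(values, affine)
    img.header.set_data_dtype(values.dtype)
    nib.save(img, str(path))
    return path


def write_geometry(geometry: LVGeometry, path) -> Path:
    """Persist an analytic LV geometry as YAML."""
    shell = geometry.wall
    if not hasattr(shell, "endo_radius"):
        raise VolumeIOError("only analytic capsule geometries can be written to YAML")
    payload = {
        "lv_length": float(geometry.axis_length),
        "outer_diameter": 2.0 * float(shell.epi_radius),
        "wall_thickness": float(shell.epi_radius - shell.endo_radius),
        "base_point": [float(v) for v in geometry.base_point],
        "long_axis": [float(v) for v in geometry.long_axis],
        "anterior": [float(v) for v in geometry.anterior],
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_geometry(path) -> LVGeometry:
    """Load an analytic LV geometry from YAML (see :func:`write_geometry`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"geometry file not found: {path}")
    payload = yaml.safe_load(path.read_text())
    for key in ("lv_length", "outer_diameter", "wall_thickness"):
        if key not in payload:
            raise VolumeIOError(f"{path}: geometry file misses required field '{key}'")
    return capsule_geometry(
        payload["lv_length"],
        payload["outer_diameter"],
        payload["wall_thickness"],
        base_point=payload.get("base_point", (0.0, 0.0, 0.0)),
        long_axis=payload.get("long_axis", (0.0, 0.0, 1.0)),
        anterior=payload.get("anterior", (1.0, 0.0, 0.0)),
    )


@dataclass
class StudyBundle:
    """Paths of the files making up one late-enhancement study."""

    iodine: Path
    myocardium_mask: Path
    geometry: Path
    hematocrit: float
    blood_iodine: float
    metadata: dict | None = None

    def validate(self) -> None:
        for name in ("iodine", "myocardium_mask", "geometry"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"study bundle: {name} file not found: {p}")
        iodine = read_volume(self.iodine)
        mask = read_volume(self.myocardium_mask)
        if iodine.shape != mask.shape:
            raise VolumeIOError(
                f"study bundle: iodine grid {iodine.shape} does not match mask grid {mask.shape}"
            )
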