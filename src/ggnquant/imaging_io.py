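"""Volume/mask containers, NIfTI round-trip I/O and cohort-level filters.

CT volumes are 3D integer grids of Hounsfield units (HU) with physical voxel
spacing in millimetres; axes are ordered (x, y, z) with z the slice index.
Nodule masks are binary grids of the same shape.  Segmentation itself is out
of scope: masks arrive from the phantom generator or from files, and are
expected to already exclude large vessels, mirroring how a radiologist's
freehand region of interest is drawn.

Conventions: voxel indices are 0-based, physical sizes in mm, volumes in
cm^3; a voxel belongs to the nodule iff its mask flag is set.  Multi-observer
masks are stored one file per observer with ``_obs1`` / ``_obs2`` suffixes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    EmptyMaskError,
    InvalidVolumeError,
    MissingFeatureError,
    ShapeMismatchError,
)

HU_MIN = -1024
HU_MAX = 3071

#: 26-connectivity structuring element used to validate mask connectedness.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT image in Hounsfield units with physical voxel spacing."""

    voxels: np.ndarray  # integer HU, shape (nx, ny, nz)
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise InvalidVolumeError(f"volume must be 3D, got ndim={vox.ndim}")
        if not np.issubdtype(vox.dtype, np.integer):
            if not np.all(np.isfinite(vox)):
                raise InvalidVolumeError("volume contains non-finite voxels")
            raise InvalidVolumeError(f"HU grid must be integer, got {vox.dtype}")
        if vox.min() < HU_MIN or vox.max() > HU_MAX:
            raise InvalidVolumeError(
                f"HU out of range [{HU_MIN}, {HU_MAX}]: "
                f"[{vox.min()}, {vox.max()}]"
            )
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise InvalidVolumeError(f"spacing must be 3 positive reals, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz


@dataclass(frozen=True)
class NoduleMask:
    """Binary segmentation of one nodule, same grid as its CTVolume."""

    data: np.ndarray  # bool, shape (nx, ny, nz)

    def __post_init__(self) -> None:
        m = np.asarray(self.data)
        if m.ndim != 3:
            raise ShapeMismatchError(f"mask must be 3D, got ndim={m.ndim}")
        if m.dtype != bool:
            object.__setattr__(self, "data", m.astype(bool))
        if not self.data.any():
            raise EmptyMaskError("empty mask: no voxels flagged")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_connected(self) -> bool:
        """True iff the mask is a single 26-connected component."""
        _, n = ndimage.label(self.data, structure=_CONN26)
        return n == 1


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    dx, dy, dz = spacing_mm
    return np.diag([dx, dy, dz, 1.0])


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.voxels.astype(np.int16), _affine(volume.spacing_mm))
    nib.save(img, str(path))
    return path


def write_mask(mask: NoduleMask, spacing_mm: tuple[float, float, float], path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(spacing_mm))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> CTVolume:
    """Load a NIfTI CT volume; validates HU range, finiteness and spacing."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.all(np.isfinite(data)):
        raise InvalidVolumeError(f"{path}: volume contains non-finite voxels")
    vox = np.rint(data).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(voxels=vox, spacing_mm=spacing)


def load_mask(path: str | Path, volume: CTVolume, require_connected: bool = True) -> NoduleMask:
    """Load a binary NIfTI mask and validate it against its volume.

    Raises ``ShapeMismatchError`` if the grids differ, ``EmptyMaskError`` if
    no voxel is flagged, and ``InvalidVolumeError`` if the mask is not a
    single 26-connected component (unless ``require_connected`` is False).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.shape != volume.shape:
        raise ShapeMismatchError(
            f"shape mismatch: mask {data.shape} vs volume {volume.shape}"
        )
    mask = NoduleMask(data=data > 0)
    if require_connected and not mask.is_connected():
        raise InvalidVolumeError(f"{path}: mask is not a single 26-connected component")
    return mask


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a feature/metadata table as UTF-8 CSV with a header row."""
    path = Path(path)
    table.to_csv(path, index=False, encoding="utf-8")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


def filter_cohort(
    records: pd.DataFrame,
    features: pd.DataFrame,
    solid_size_limit_mm: float = 5.0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the cohort-inclusion rule on the solid component size.

    Nodules whose solid component measures >= ``solid_size_limit_mm`` on the
    mediastinal (soft-tissue) window are excluded: such lesions are no longer
    "ground-glass with little solid component" and fall outside the study
    population.  The rule is inclusive at the boundary (5.0 mm is excluded).

    Parameters
    ----------
    records : table with a ``nodule_id`` column.
    features : table with ``nodule_id`` and ``size_mediastinal_mm`` columns.

    Returns
    -------
    (retained records, exclusion log) — the log is a list of dicts, one per
    excluded nodule, suitable for JSON serialisation.  Idempotent: filtering
    retained records again removes nothing.
    """
    if "size_mediastinal_mm" not in features.columns:
        raise MissingFeatureError("features table lacks 'size_mediastinal_mm'")
    if "nodule_id" not in records.columns or "nodule_id" not in features.columns:
        raise MissingFeatureError("both tables need a 'nodule_id' column")
    merged = records.merge(
        features[["nodule_id", "size_mediastinal_mm"]], on="nodule_id", how="left"
    )
    if merged["size_mediastinal_mm"].isna().any():
        missing = merged.loc[merged["size_mediastinal_mm"].isna(), "nodule_id"].tolist()
        raise MissingFeatureError(f"no solid-size feature for nodules: {missing}")
    keep = merged["size_mediastinal_mm"] < solid_size_limit_mm
    excluded = merged.loc[~keep]
    log = [
        {
            "nodule_id": str(row.nodule_id),
            "size_mediastinal_mm": float(row.size_mediastinal_mm),
            "reason": f"solid component >= {solid_size_limit_mm} mm on mediastinal window",
        }
        for row in excluded.itertuples()
    ]
    retained = records.loc[records["nodule_id"].isin(merged.loc[keep, "nodule_id"])].reset_index(
        drop=True
    )
    return retained, log


def write_exclusion_log(log: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(log, indent=2, sort_keys=True), encoding="utf-8")
    return path
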