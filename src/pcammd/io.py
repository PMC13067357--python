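"""Volumetric containers and readers/writers.

Canonical on-disk format: NIfTI pairs (``<stem>_low.nii.gz`` /
``<stem>_high.nii.gz``) with a JSON sidecar (``<stem>.json``) carrying
the keV pair and free-form provenance.  DICOM series are supported as
read-only input with rescale slope/intercept applied.  Arrays follow
0-based (slice, row, col) index order throughout; ROI label volumes
share the same grid and convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .materials import MaterialLibrary

__all__ = [
    "DualEnergyVolume",
    "FractionMaps",
    "read_volume",
    "write_volume",
    "read_dicom_series",
    "write_fraction_maps",
    "read_fraction_maps",
    "write_roi_set",
    "read_roi_set",
    "library_checksum",
]


@dataclasses.dataclass
class DualEnergyVolume:
    """Paired low/high-energy HU volumes on a shared grid."""

    low: np.ndarray
    high: np.ndarray
    energies: tuple[float, float] = (70.0, 150.0)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.low = np.asarray(self.low, dtype=float)
        self.high = np.asarray(self.high, dtype=float)
        if self.low.shape != self.high.shape:
            raise ValueError(
                f"low/high grids differ: {self.low.shape} vs {self.high.shape}"
            )
        if not (np.all(np.isfinite(self.low)) and np.all(np.isfinite(self.high))):
            raise ValueError("attenuation values must be finite")

    @property
    def shape(self) -> tuple:
        return self.low.shape

    @property
    def n_voxels(self) -> int:
        return int(self.low.size)

    def as_points(self) -> np.ndarray:
        """(N, 2) measurement matrix: columns = (low, high) HU."""
        return np.stack([self.low.ravel(), self.high.ravel()], axis=1)


@dataclasses.dataclass
class FractionMaps:
    """Per-material volume-fraction images plus assignment metadata."""

    data: np.ndarray  # (n_materials, S, H, W)
    material_names: tuple[str, ...]
    method: str  # "bc_mmd" or "pca_mmd"
    energies: tuple[float, float] = (70.0, 150.0)
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        # full precision in memory; serialization casts to float32
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.material_names):
            raise ValueError("material count does not match data")

    @classmethod
    def from_flat(cls, fractions: np.ndarray, volume: DualEnergyVolume,
                  lib: MaterialLibrary, method: str, metadata: dict | None = None):
        data = fractions.T.reshape((fractions.shape[1],) + volume.shape)
        return cls(data=data, material_names=lib.material_names, method=method,
                   energies=volume.energies, metadata=metadata or {})

    def fraction(self, name: str) -> np.ndarray:
        return self.data[self.material_names.index(name)].astype(float)


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------
def _nifti():
    import nibabel as nib
    return nib


def write_volume(volume: DualEnergyVolume, stem: str | Path) -> None:
    """Write ``<stem>_low.nii.gz``, ``<stem>_high.nii.gz``, ``<stem>.json``."""
    nib = _nifti()
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    for tag, arr in (("low", volume.low), ("high", volume.high)):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine)
        nib.save(img, str(stem) + f"_{tag}.nii.gz")
    sidecar = {
        "energies_kev": list(volume.energies),
        "voxel_size_mm": list(volume.voxel_size_mm),
        "provenance": volume.provenance,
    }
    Path(str(stem) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_volume(stem: str | Path) -> DualEnergyVolume:
    """Read a volume written by :func:`write_volume`."""
    nib = _nifti()
    stem = Path(stem)
    paths = [Path(str(stem) + f"_{tag}.nii.gz") for tag in ("low", "high")]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"missing volume file: {p}")
    low_img, high_img = (nib.load(str(p)) for p in paths)
    low = np.asarray(low_img.dataobj, dtype=float)
    high = np.asarray(high_img.dataobj, dtype=float)
    sidecar_path = Path(str(stem) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return DualEnergyVolume(
        low=low, high=high,
        energies=tuple(sidecar.get("energies_kev", (70.0, 150.0))),
        voxel_size_mm=tuple(sidecar.get("voxel_size_mm", (1.0, 1.0, 1.0))),
        provenance=sidecar.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# DICOM input
# ---------------------------------------------------------------------------
def read_dicom_series(low_dir: str | Path, high_dir: str | Path) -> DualEnergyVolume:
    """Read paired DICOM series (one directory per energy) as HU volumes.

    Slices are sorted by ImagePositionPatient (z) falling back to
    InstanceNumber; RescaleSlope/Intercept are applied.  The two series
    must share in-plane dimensions and slice count.
    """
    low, spacing_low, energy_low = _read_one_series(low_dir)
    high, spacing_high, energy_high = _read_one_series(high_dir)
    if low.shape != high.shape:
        raise ValueError(
            f"inconsistent series geometry: {low.shape} vs {high.shape}"
        )
    energies = (energy_low or 70.0, energy_high or 150.0)
    return DualEnergyVolume(
        low=low, high=high, energies=energies, voxel_size_mm=spacing_low,
        provenance={"source": "dicom", "low_dir": str(low_dir), "high_dir": str(high_dir)},
    )


def _read_one_series(directory: str | Path):
    import pydicom

    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such DICOM directory: {directory}")
    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    def zkey(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=zkey)
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent series geometry: in-plane shapes {shapes}")
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(float) * slope + intercept)
    first = datasets[0]
    pixel = getattr(first, "PixelSpacing", [1.0, 1.0])
    thickness = float(getattr(first, "SliceThickness", 1.0))
    spacing = (thickness, float(pixel[0]), float(pixel[1]))
    energy = getattr(first, "KVP", None)
    return np.stack(slices), spacing, (float(energy) if energy else None)


# ---------------------------------------------------------------------------
# fraction maps and ROI sets
# ---------------------------------------------------------------------------
def write_fraction_maps(maps: FractionMaps, stem: str | Path,
                        voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """4-D NIfTI (materials along the 4th axis) + JSON metadata."""
    nib = _nifti()
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    # store as (S, H, W, M) so NIfTI treats materials as the 4th dim
    img = nib.Nifti1Image(np.moveaxis(maps.data, 0, -1).astype(np.float32), affine)
    nib.save(img, str(stem) + "_fractions.nii.gz")
    meta = {
        "material_names": list(maps.material_names),
        "method": maps.method,
        "energies_kev": list(maps.energies),
    }
    for key, value in maps.metadata.items():
        if isinstance(value, np.ndarray):
            continue  # array metadata stays in-memory only
        meta[key] = value
    Path(str(stem) + "_fractions.json").write_text(json.dumps(meta, indent=2, default=str))


def read_fraction_maps(stem: str | Path) -> FractionMaps:
    nib = _nifti()
    stem = Path(stem)
    img = nib.load(str(stem) + "_fractions.nii.gz")
    data = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    meta = json.loads(Path(str(stem) + "_fractions.json").read_text())
    return FractionMaps(
        data=data, material_names=tuple(meta["material_names"]),
        method=meta["method"], energies=tuple(meta["energies_kev"]),
        metadata={k: v for k, v in meta.items()
                  if k not in ("material_names", "method", "energies_kev")},
    )


def write_roi_set(roi_set, stem: str | Path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """Label volume as NIfTI + role table as CSV."""
    nib = _nifti()
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(roi_set.labels.astype(np.int32), affine)
    nib.save(img, str(stem) + "_rois.nii.gz")
    roi_set.table.to_csv(str(stem) + "_rois.csv", index=False)


def read_roi_set(stem: str | Path):
    from .phantom import RoiSet  # deferred: phantom imports io

    nib = _nifti()
    stem = Path(stem)
    img = nib.load(str(stem) + "_rois.nii.gz")
    labels = np.asarray(img.dataobj).astype(np.int32)
    table = pd.read_csv(str(stem) + "_rois.csv")
    return RoiSet(labels=labels, table=table)


def library_checksum(lib: MaterialLibrary) -> str:
    """Stable SHA-256 of the canonical library serialization."""
    payload = json.dumps(lib.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()
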