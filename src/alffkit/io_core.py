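"""Shared spatial/clinical types and readers/writers for the standard formats.

Volumes, masks and label atlases travel as NIfTI-1 (``.nii``/``.nii.gz``);
clinical tables and cluster tables as comma-separated text with a header row.
All inputs are assumed co-registered: no resampling is ever performed, and no
operation in the package may silently alter an affine or voxel size.
Voxel indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesVolume",
    "BrainMask",
    "LabelAtlas",
    "StatMap",
    "ClinicalTable",
    "CLINICAL_COLUMNS",
    "read_timeseries",
    "write_timeseries",
    "read_map",
    "write_map",
    "read_mask",
    "write_mask",
    "read_atlas",
    "write_atlas",
    "read_clinical_table",
    "write_clinical_table",
]

#: valid StatMap kinds: raw and standardized amplitude maps plus test statistics
MAP_KINDS = ("alff", "falff", "malff", "mfalff", "t", "p")

GROUPS = ("treatment", "control")

CLINICAL_COLUMNS = (
    "subject_id",
    "group",
    "vas_baseline",
    "vas_week1",
    "vas_week2",
    "vas_week3",
    "vas_week4",
    "sleep_week1",
    "sleep_week2",
    "sleep_week3",
    "sleep_week4",
)


def _voxel_size_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(affine, dtype=float)[:3, :3], axis=0)


@dataclass
class TimeSeriesVolume:
    """A 4D BOLD acquisition: (x, y, z, t) intensities plus geometry.

    ``tr_seconds`` is the repetition time (volume-to-volume interval); it sets
    the Nyquist frequency 1/(2*TR) for all spectral operations downstream.
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray
    voxel_size_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 1:
            raise ValueError("time dimension must have length >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if not (self.tr_seconds > 0):
            raise ValueError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.voxel_size_mm is None:
            self.voxel_size_mm = _voxel_size_from_affine(self.affine)
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """3D boolean grid selecting the voxels that enter every analysis."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask must contain at least one voxel")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_shape(self, volume_shape: tuple[int, ...]) -> None:
        if tuple(volume_shape[:3]) != self.data.shape:
            raise ValueError(
                f"mask shape {self.data.shape} does not match volume {tuple(volume_shape[:3])}"
            )


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation (0 = background) with region names."""

    data: np.ndarray
    names: dict[int, str]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("atlas must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.data.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        self.affine = np.asarray(self.affine, dtype=float)

    def name_at(self, voxel: tuple[int, int, int]) -> str:
        label = int(self.data[voxel])
        return self.names.get(label, "unlabeled") if label != 0 else "unlabeled"


@dataclass
class StatMap:
    """3D scalar field (ALFF, f-ALFF, t or p) aligned to a brain mask.

    Out-of-mask voxels are NaN ("invalid"); amplitude maps are non-negative
    inside the mask and fractional ALFF never exceeds 1.
    """

    data: np.ndarray
    kind: str
    affine: np.ndarray
    mask: BrainMask | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("StatMap data must be 3D")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {MAP_KINDS}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is not None:
            self.mask.check_shape(self.data.shape)
            inside = self.data[self.mask.data]
            if self.kind in ("alff", "falff") and np.nanmin(inside) < -1e-9:
                raise ValueError(f"{self.kind} map has negative in-mask values")
            if self.kind == "falff" and np.nanmax(inside) > 1 + 1e-9:
                raise ValueError("falff map exceeds 1")

    def in_mask(self) -> np.ndarray:
        """Return the in-mask values as a 1D array (C order)."""
        if self.mask is None:
            return self.data.ravel()
        return self.data[self.mask.data]


@dataclass
class ClinicalTable:
    """Per-subject group label plus VAS (0-10 points) and continuous sleep
    (hours) trajectories at baseline and weeks 1-4."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if df[list(CLINICAL_COLUMNS)].isna().any().any():
            raise ValueError("clinical table contains missing values")
        bad_groups = set(df["group"].unique()) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
        vas_cols = [c for c in CLINICAL_COLUMNS if c.startswith("vas")]
        vas = df[vas_cols].to_numpy(dtype=float)
        if (vas < 0).any() or (vas > 10).any():
            raise ValueError("VAS values must lie in [0, 10]")
        sleep_cols = [c for c in CLINICAL_COLUMNS if c.startswith("sleep")]
        if (df[sleep_cols].to_numpy(dtype=float) < 0).any():
            raise ValueError("sleep hours must be >= 0")

    def group(self, label: str) -> pd.DataFrame:
        return self.frame[self.frame["group"] == label]

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# NIfTI readers/writers


def read_timeseries(path) -> TimeSeriesVolume:
    """Read a 4D NIfTI-1 file; TR is taken from the header time unit."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI file, got {data.ndim}D: {path}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    _, t_unit = img.header.get_xyzt_units()
    scale = {"msec": 1e-3, "usec": 1e-6}.get(t_unit, 1.0)
    tr *= scale
    if tr <= 0:
        raise ValueError(f"NIfTI header of {path} carries no positive TR")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"non-finite intensities in {path}")
    return TimeSeriesVolume(data=data.astype(np.float64), tr_seconds=tr, affine=img.affine)


def write_timeseries(vol: TimeSeriesVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], vol.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_map(stat_map: StatMap, path) -> None:
    """Write a StatMap as NIfTI; out-of-mask voxels stay NaN on disk."""
    if stat_map.mask is not None:
        stat_map.mask.check_shape(stat_map.data.shape)
        if not np.allclose(stat_map.affine, stat_map.mask.affine):
            raise ValueError("map and mask affines disagree")
    img = nib.Nifti1Image(stat_map.data.astype(np.float64), stat_map.affine)
    nib.save(img, str(path))


def read_map(path, kind: str, mask: BrainMask | None = None) -> StatMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D map, got {data.ndim}D: {path}")
    return StatMap(data=data, kind=kind, affine=img.affine, mask=mask)


def write_mask(mask: BrainMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def read_mask(path) -> BrainMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask, got {data.ndim}D: {path}")
    return BrainMask(data=data > 0, affine=img.affine)


def write_atlas(atlas: LabelAtlas, path, names_path) -> None:
    """Write the label image as NIfTI and the label->name map as a CSV sidecar."""
    img = nib.Nifti1Image(atlas.data.astype(np.int32), atlas.affine)
    nib.save(img, str(path))
    pd.DataFrame(
        {"label": list(atlas.names), "name": list(atlas.names.values())}
    ).to_csv(names_path, index=False)


def read_atlas(path, names_path) -> LabelAtlas:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D atlas, got {data.ndim}D: {path}")
    names_df = pd.read_csv(names_path)
    names = {int(r.label): str(r.name) for r in names_df.itertuples()}
    return LabelAtlas(data=np.rint(data).astype(np.int32), names=names, affine=img.affine)


# ---------------------------------------------------------------------------
# Clinical tables


def read_clinical_table(path) -> ClinicalTable:
    """Read and validate a clinical CSV (comma-separated, header row,
    no missing values)."""
    return ClinicalTable(pd.read_csv(path))


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.frame.to_csv(path, index=False)
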