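"""Readers and writers for the formats the pipeline touches.

4-D diffusion-weighted volumes and 3-D masks/parameter maps travel as
NIfTI-1 (via nibabel); b-value tables as FSL-style ``.bval`` text (a
single whitespace-separated line) or a two-column ``volume<TAB>b`` table;
cohort tables as headered CSV.

Volumes are never reordered: the i-th b-value always describes the i-th
volume, in acquisition order.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "DWISeries",
    "ROIMask",
    "ParameterMap",
    "CohortTable",
    "read_bvals",
    "write_bvals",
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "read_parameter_map",
    "write_parameter_map",
    "read_cohort",
    "write_cohort",
]

#: Parameter names a ParameterMap may carry.
PARAMETER_NAMES = ("mu_diff", "f", "D", "Dstar", "DDC", "Alpha", "ADC", "S0")

#: Required cohort CSV columns besides the parameter columns.
COHORT_REQUIRED = ("subject_id", "group")
COHORT_GROUPS = ("adverse", "non_adverse")


@dataclasses.dataclass
class DWISeries:
    """A 4-D multi-b DWI acquisition.

    Attributes
    ----------
    signal : ndarray, shape (x, y, z, n)
        Non-negative signal intensities in scanner units, one volume per
        diffusion weighting.
    bvalues : ndarray, shape (n,)
        Diffusion weightings in s/mm², in volume (acquisition) order.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform.
    """

    signal: np.ndarray
    bvalues: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4-D, got {self.signal.ndim}-D")
        if self.signal.shape[3] != self.bvalues.size:
            raise ValueError(
                f"volume count ({self.signal.shape[3]}) does not match "
                f"b-value count ({self.bvalues.size})"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if np.any(self.signal < 0):
            raise ValueError("signal contains negative values")
        if np.any(self.bvalues < 0):
            raise ValueError("b-values must be non-negative")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def spatial_shape(self) -> tuple:
        return self.signal.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    def s0_volume(self) -> np.ndarray:
        """Reference S0 volume: mean of all volumes at the minimum b."""
        ref = self.bvalues == self.bvalues.min()
        return self.signal[..., ref].mean(axis=3)


@dataclasses.dataclass
class ROIMask:
    """A binary region of interest on a DWI spatial grid."""

    mask: np.ndarray
    label: str = "placenta"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError(f"ROI '{self.label}' is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class ParameterMap:
    """A voxelwise fitted-parameter volume; NaN marks unfit voxels."""

    values: np.ndarray
    parameter_name: str
    units: str = ""
    affine: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("parameter map must be 3-D")
        if self.parameter_name not in PARAMETER_NAMES:
            raise ValueError(
                f"unknown parameter {self.parameter_name!r}; "
                f"expected one of {PARAMETER_NAMES}"
            )


class CohortTable:
    """Per-subject cohort table (wraps a DataFrame).

    The schema requires unique ``subject_id`` and a ``group`` column with
    values ``adverse`` / ``non_adverse``; clinical covariates and ROI-mean
    parameter columns ride along, and unknown columns are preserved.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        for col in COHORT_REQUIRED:
            if col not in df.columns:
                raise ValueError(f"cohort table missing required column {col!r}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject_id values: {dupes}")
        if df["group"].isna().any() or (df["group"].astype(str) == "").any():
            raise ValueError("group label missing for some subjects")
        bad = set(df["group"].astype(str)) - set(COHORT_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {COHORT_GROUPS}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.df.equals(other.df)

    def group_counts(self) -> dict:
        return self.df["group"].value_counts().to_dict()

    def split_groups(self, column: str) -> tuple:
        """Return (adverse, non_adverse) values of a column, NaN dropped."""
        g = self.df.groupby("group")[column]
        out = []
        for name in COHORT_GROUPS:
            vals = g.get_group(name) if name in g.groups else pd.Series(dtype=float)
            out.append(vals.dropna())
        return tuple(out)

    def parameter_columns(self) -> list:
        known = {"mu_diff", "f", "D", "Dstar", "DDC", "Alpha", "ADC"}
        return [c for c in self.df.columns if c in known]


# ---------------------------------------------------------------------------
# b-value tables


def read_bvals(path) -> np.ndarray:
    """Read an FSL-style .bval line, or a two-column (volume, b) table."""
    text = Path(path).read_text().strip()
    if not text:
        raise ValueError(f"empty b-value file: {path}")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    rows = [ln.split() for ln in lines]
    try:
        if len(rows) > 1 and all(len(r) == 2 for r in rows):
            pairs = sorted((int(v), float(b)) for v, b in rows)
            bvals = np.array([b for _, b in pairs])
        else:
            bvals = np.array([float(x) for r in rows for x in r])
    except ValueError as exc:
        raise ValueError(f"unparseable b-value file {path}: {exc}") from exc
    if np.any(bvals < 0):
        raise ValueError("negative b-value in b-value file")
    return bvals


def write_bvals(bvalues, path) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in np.asarray(bvalues)) + "\n")


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_dwi(image_path, bval_path) -> DWISeries:
    """Load a 4-D DWI NIfTI plus its b-value table.

    Volumes stay in file order; the i-th b-value describes the i-th volume.
    """
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D DWI image, got {data.ndim}-D: {image_path}")
    bvals = read_bvals(bval_path)
    if data.shape[3] != bvals.size:
        raise ValueError(
            f"volume count ({data.shape[3]}) does not match b-value count "
            f"({bvals.size}) for {image_path}"
        )
    zooms = img.header.get_zooms()[:3]
    return DWISeries(data, bvals, tuple(float(z) for z in zooms), img.affine)


def write_dwi(series: DWISeries, image_path, bval_path=None) -> None:
    img = nib.Nifti1Image(series.signal.astype(np.float64), series.affine)
    img.header.set_zooms(tuple(series.voxel_size) + (1.0,))
    nib.save(img, str(image_path))
    if bval_path is not None:
        write_bvals(series.bvalues, bval_path)


def read_mask(path, reference: DWISeries) -> ROIMask:
    """Load a 3-D mask; any nonzero voxel belongs to the (single) ROI."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D mask, got {data.ndim}-D: {path}")
    if data.shape != reference.spatial_shape:
        raise ValueError(
            f"mask shape {data.shape} does not match DWI grid "
            f"{reference.spatial_shape}"
        )
    return ROIMask(data != 0, label=Path(path).name.split(".")[0])


def write_mask(mask: ROIMask, path, affine=None) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def write_parameter_map(pmap: ParameterMap, path) -> None:
    """Write a parameter map as NIfTI; NaN (unfit voxels) round-trips."""
    img = nib.Nifti1Image(pmap.values.astype(np.float64), pmap.affine)
    img.header["descrip"] = f"{pmap.parameter_name} [{pmap.units}]".encode()[:80]
    nib.save(img, str(path))


def read_parameter_map(path, parameter_name: str, units: str = "") -> ParameterMap:
    img = nib.load(str(path))
    return ParameterMap(np.asarray(img.dataobj, dtype=float), parameter_name, units, img.affine)


# ---------------------------------------------------------------------------
# Cohort CSV


def read_cohort(path) -> CohortTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty cohort file: {path}") from exc
    return CohortTable(df)


def write_cohort(table: CohortTable, path) -> None:
    table.df.to_csv(path, index=False)
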