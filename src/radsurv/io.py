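"""Core data types and I/O for volumes, masks and cohort tables.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` (slice-major, as CT volumes are stored);
voxel spacing is stored ``(dx, dy, dz)`` in millimetres and all geometry
code converts between the two orderings explicitly.  Coordinates are
0-based voxel centres.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

from radsurv.errors import (
    FormatError,
    GeometryError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: canonical clinical column names of a cohort table
CLINICAL_COLUMNS = (
    "age",
    "sex",
    "smoking_status",
    "extrathoracic_metastasis",
    "egfr_mutation",
    "baseline_diameter",
    "followup_diameter",
    "recist_response",
    "pfs_months",
    "event",
)


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar CT volume in Hounsfield units.

    Parameters
    ----------
    intensities:
        3D array indexed ``(z, y, x)``.
    spacing:
        Voxel spacing ``(dx, dy, dz)`` in mm; all components positive.
    origin:
        Physical position of voxel (0, 0, 0) in mm, ``(x0, y0, z0)``.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValidationError(f"expected a 3D volume, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("volume contains non-finite intensities")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class SegmentationMask:
    """A binary tumour mask aligned to an :class:`ImageVolume` grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    reader_id: str = "A"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels).astype(bool)
        if vox.ndim != 3:
            raise ValidationError(f"expected a 3D mask, got ndim={vox.ndim}")
        if not vox.any():
            raise ValidationError("mask has no foreground voxels")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        n_comp = ndimage.label(vox, structure=np.ones((3, 3, 3), dtype=int))[1]
        if n_comp > 1:
            warnings.warn(
                f"mask has {n_comp} 26-connected components; expected a single tumour",
                stacklevel=2,
            )
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def check_compatible(self, volume: ImageVolume, atol: float = 1e-4) -> None:
        """Raise :class:`GeometryError` unless grids/spacings match."""
        if self.shape != volume.shape:
            raise GeometryError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing, atol=atol):
            raise GeometryError(
                f"mask spacing {self.spacing} does not match volume spacing {volume.spacing}"
            )


# ---------------------------------------------------------------------------
# volumetric I/O (SimpleITK handles NRRD / NIfTI / DICOM series)
# ---------------------------------------------------------------------------


def _sitk_to_arrays(image: sitk.Image):
    arr = sitk.GetArrayFromImage(image)  # (z, y, x)
    spacing = tuple(float(s) for s in image.GetSpacing())  # (dx, dy, dz)
    origin = tuple(float(o) for o in image.GetOrigin())
    return arr, spacing, origin


def _read_dicom_series(path: Path) -> sitk.Image:
    reader = sitk.ImageSeriesReader()
    file_names = reader.GetGDCMSeriesFileNames(str(path))
    if not file_names:
        raise FormatError(f"no DICOM series found in directory {path}")
    reader.SetFileNames(file_names)  # sorted by slice position by GDCM
    image = reader.Execute()
    # verify uniform slice spacing along z
    positions = []
    fr = sitk.ImageFileReader()
    for fn in file_names:
        fr.SetFileName(fn)
        fr.ReadImageInformation()
        positions.append(float(fr.GetOrigin()[2]))
    gaps = np.diff(sorted(positions))
    if len(gaps) and not np.allclose(gaps, gaps[0], atol=1e-3):
        raise GeometryError(
            f"inconsistent DICOM slice spacing in {path}: gaps {np.unique(np.round(gaps, 3))}"
        )
    return image


def load_volume(path: str | Path, format: str | None = None) -> ImageVolume:
    """Load a CT volume from NRRD, NIfTI-1 or a DICOM series directory.

    ``format`` may be ``"nrrd"``, ``"nifti"`` or ``"dicom_dir"``; when
    omitted it is inferred from the path (directory -> DICOM series,
    otherwise by file extension).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti" if ".nii" in path.suffixes else "nrrd"
    try:
        if format == "dicom_dir":
            image = _read_dicom_series(path)
        elif format in ("nrrd", "nifti"):
            image = sitk.ReadImage(str(path))
        else:
            raise FormatError(f"unsupported format {format!r}")
    except RuntimeError as exc:  # SimpleITK read failure
        raise FormatError(f"could not read {path} as {format}: {exc}") from exc
    arr, spacing, origin = _sitk_to_arrays(image)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{path} contains non-finite intensities")
    return ImageVolume(intensities=arr, spacing=spacing, origin=origin)


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume to NRRD or NIfTI (chosen by file extension)."""
    image = sitk.GetImageFromArray(volume.intensities)
    image.SetSpacing(volume.spacing)
    image.SetOrigin(volume.origin)
    sitk.WriteImage(image, str(Path(path)))


def load_mask(
    path: str | Path,
    reference: ImageVolume | None = None,
    reader_id: str = "A",
) -> SegmentationMask:
    """Load a binary mask; values > 0.5 are treated as foreground."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")
    try:
        image = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"could not read mask {path}: {exc}") from exc
    arr, spacing, origin = _sitk_to_arrays(image)
    vox = arr > 0.5
    if not vox.any():
        raise ValidationError(f"mask {path} is empty")
    mask = SegmentationMask(voxels=vox, spacing=spacing, origin=origin, reader_id=reader_id)
    if reference is not None:
        mask.check_compatible(reference)
    return mask


def save_mask(mask: SegmentationMask, path: str | Path) -> None:
    image = sitk.GetImageFromArray(mask.voxels.astype(np.uint8))
    image.SetSpacing(mask.spacing)
    image.SetOrigin(mask.origin)
    sitk.WriteImage(image, str(Path(path)))


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and outcome for one patient."""

    patient_id: str
    age: float
    sex: str
    smoking_status: str
    extrathoracic_metastasis: bool
    egfr_mutation: str
    baseline_diameter: float
    followup_diameter: float
    recist_response: str  # "responder" | "nonresponder"
    pfs_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.pfs_months < 0:
            raise ValidationError(f"pfs_months must be >= 0, got {self.pfs_months}")
        if self.baseline_diameter <= 0 or self.followup_diameter <= 0:
            raise ValidationError("tumour diameters must be positive")
        if self.recist_response not in ("responder", "nonresponder"):
            raise ValidationError(f"unknown RECIST response {self.recist_response!r}")


@dataclass
class CohortTable:
    """Per-patient clinical covariates joined with radiomic feature sets.

    ``data`` is indexed by ``patient_id``; feature columns are prefixed per
    set and recorded in ``feature_sets`` (set name -> list of column names,
    in the canonical feature order).
    """

    data: pd.DataFrame
    feature_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate patient ids: {dupes}")
        if "pfs_months" in self.data.columns:
            times = pd.to_numeric(self.data["pfs_months"], errors="coerce")
            if (times < 0).any():
                raise ValidationError("negative PFS times in cohort table")
        for name, cols in self.feature_sets.items():
            missing = [c for c in cols if c not in self.data.columns]
            if missing:
                raise SchemaError(f"feature set {name!r} missing columns {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def features(self, set_name: str) -> pd.DataFrame:
        """Feature table of one set with the prefix stripped from names."""
        cols = self.feature_sets[set_name]
        prefix = f"{set_name}__"
        out = self.data[cols].copy()
        out.columns = [c[len(prefix):] if c.startswith(prefix) else c for c in cols]
        return out

    def survival(self) -> tuple[np.ndarray, np.ndarray]:
        times = self.data["pfs_months"].to_numpy(dtype=float)
        events = self.data["event"].to_numpy(dtype=bool)
        return times, events

    @classmethod
    def from_tables(
        cls,
        clinical: pd.DataFrame,
        feature_tables: Mapping[str, pd.DataFrame] | None = None,
    ) -> "CohortTable":
        """Join a clinical table (indexed by patient id) with feature tables.

        Feature columns are stored as ``<set>__<feature name>``.
        """
        data = clinical.copy()
        feature_sets: dict[str, list[str]] = {}
        for set_name, table in (feature_tables or {}).items():
            renamed = table.rename(columns=lambda c: f"{set_name}__{c}")
            missing = renamed.index.difference(data.index)
            if len(missing):
                raise SchemaError(
                    f"feature set {set_name!r} has patients absent from the clinical table: "
                    f"{list(missing)[:5]}"
                )
            data = data.join(renamed)
            feature_sets[set_name] = list(renamed.columns)
        return cls(data=data, feature_sets=feature_sets)


_BOOL_MAP = {
    "1": True, "0": False, "true": True, "false": False, "yes": True, "no": False,
    "present": True, "absent": False, "y": True, "n": False,
}

_RESPONSE_MAP = {
    "responder": "responder", "nonresponder": "nonresponder",
    "non-responder": "nonresponder", "response": "responder",
    "1": "responder", "0": "nonresponder", "cr": "responder", "pr": "responder",
    "sd": "nonresponder", "pd": "nonresponder",
}


def _coerce_bool(series: pd.Series, column: str) -> pd.Series:
    def conv(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, float, np.integer, np.floating)) and not pd.isna(v):
            return bool(v)
        key = str(v).strip().lower()
        if key in _BOOL_MAP:
            return _BOOL_MAP[key]
        raise SchemaError(f"cannot interpret {v!r} as boolean in column {column!r}")

    return series.map(conv)


def load_cohort_table(
    path: str | Path,
    schema_map: Mapping[str, str] | str | Path,
) -> CohortTable:
    """Read a cohort table from CSV or XLSX through a column-name mapping.

    ``schema_map`` maps canonical names to source column names.  Canonical
    keys are ``patient_id``, the clinical columns (:data:`CLINICAL_COLUMNS`)
    and optionally ``baseline:<feature>``, ``followup:<feature>``,
    ``percent_change:<feature>`` entries for radiomic feature columns.  It
    may be given inline as a mapping or as a path to a YAML/JSON file.
    Rows with a blank or unparseable survival time are dropped with a
    warning (they cannot enter any model fit).
    """
    path = Path(path)
    if isinstance(schema_map, (str, Path)):
        schema_path = Path(schema_map)
        text = schema_path.read_text()
        if schema_path.suffix in (".yaml", ".yml"):
            import yaml

            schema_map = yaml.safe_load(text)
        else:
            schema_map = json.loads(text)
    schema_map = dict(schema_map)

    if path.suffix in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    elif path.suffix == ".csv":
        raw = pd.read_csv(path)
    else:
        raise FormatError(f"unsupported cohort table format {path.suffix!r}")

    missing = [src for src in schema_map.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"cohort table {path} is missing mapped columns {missing}")
    required = ["patient_id", "pfs_months", "event"]
    absent = [k for k in required if k not in schema_map]
    if absent:
        raise SchemaError(f"schema_map must provide {absent}")

    clinical_keys = [k for k in schema_map if ":" not in k]
    feature_keys = [k for k in schema_map if ":" in k]

    table = pd.DataFrame(
        {canon: raw[schema_map[canon]] for canon in clinical_keys}
    )
    times = pd.to_numeric(table["pfs_months"], errors="coerce")
    bad = times.isna()
    if bad.any():
        dropped = table.loc[bad, "patient_id"].tolist()
        logger.warning(
            "dropping %d row(s) with blank/non-numeric survival time: %s",
            bad.sum(), dropped,
        )
        table = table.loc[~bad]
        raw = raw.loc[table.index]
        times = times.loc[~bad]
    table["pfs_months"] = times.astype(float)
    table["event"] = _coerce_bool(table["event"], "event")
    for col in ("age", "baseline_diameter", "followup_diameter"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="raise").astype(float)
    if "extrathoracic_metastasis" in table.columns:
        table["extrathoracic_metastasis"] = _coerce_bool(
            table["extrathoracic_metastasis"], "extrathoracic_metastasis"
        )
    if "recist_response" in table.columns:
        table["recist_response"] = (
            table["recist_response"].astype(str).str.strip().str.lower().map(_RESPONSE_MAP)
        )
        if table["recist_response"].isna().any():
            raise SchemaError("unrecognised RECIST response labels in cohort table")

    table = table.set_index("patient_id")
    if table.index.has_duplicates:
        raise ValidationError("duplicate patient_id values in cohort table")

    feature_tables: dict[str, pd.DataFrame] = {}
    for key in feature_keys:
        set_name, feat = key.split(":", 1)
        feature_tables.setdefault(set_name, pd.DataFrame(index=table.index))
        feature_tables[set_name][feat] = pd.to_numeric(
            raw[schema_map[key]], errors="coerce"
        ).to_numpy()

    return CohortTable.from_tables(table, feature_tables)
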