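"""Core domain types and file I/O.

Volumes are 3-D arrays with per-axis voxel spacing in millimetres; the third
array axis is the axial (z) stack direction.  Segmentation label codes follow
the BraTS convention: 0 = background, 1 = non-enhancing tumor (NET),
2 = peritumoral edema (ED), 4 = enhancing tumor (ET).  Derived regions are
TC = NET ∪ ET (tumor core) and WT = TC ∪ ED (whole tumor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "SUBTYPES",
    "LABEL_CODES",
    "LOBE_NAMES",
    "RegistrationError",
    "MaskError",
    "FormatError",
    "VolumeGrid",
    "MpMRIStudy",
    "SegmentationMask",
    "AnatomyContext",
    "SubjectRecord",
    "FeatureTable",
    "read_volume",
    "write_volume",
    "read_subject",
    "read_manifest",
    "read_cohort",
    "write_feature_table",
    "read_feature_table",
]

#: MRI channel keys, fixed order.
CHANNELS = ("T1", "T1GD", "T2", "FLAIR")

#: Canonical subtype order; used everywhere a deterministic ordering or
#: tie-break over the four classes is needed.
SUBTYPES = ("classical", "mesenchymal", "proneural", "neural")

#: BraTS-style label codes.
LABEL_CODES = {"NET": 1, "ED": 2, "ET": 4}
_VALID_CODES = frozenset({0, 1, 2, 4})

#: Names of the nine anatomical regions of the lobe parcellation (codes 1..9).
LOBE_NAMES = (
    "temporal",
    "frontal",
    "parietal",
    "occipital",
    "basal_ganglia",
    "cc_fornix",
    "insula",
    "cerebellum",
    "brain_stem",
)


class RegistrationError(ValueError):
    """Raised when grids expected to be co-registered disagree."""


class MaskError(ValueError):
    """Raised when a segmentation mask violates the label-code contract."""


class FormatError(ValueError):
    """Raised on malformed tabular input."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D scalar field on a regular voxel lattice.

    Parameters
    ----------
    values
        3-D array of voxel values.
    spacing
        Per-axis voxel size in mm, strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={values.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if np.issubdtype(values.dtype, np.floating) and not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass(frozen=True)
class MpMRIStudy:
    """Four co-registered structural MRI channels for one subject."""

    subject_id: str
    channels: Mapping[str, VolumeGrid]

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNELS):
            raise RegistrationError(
                f"study {self.subject_id!r}: expected channels {CHANNELS}, "
                f"got {sorted(self.channels)}"
            )
        ref = self.channels[CHANNELS[0]]
        for name in CHANNELS[1:]:
            if not ref.same_grid(self.channels[name]):
                raise RegistrationError(
                    f"registration error: channel {name} grid differs from {CHANNELS[0]} "
                    f"for subject {self.subject_id!r}"
                )

    @property
    def grid(self) -> VolumeGrid:
        return self.channels[CHANNELS[0]]

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing


@dataclass(frozen=True)
class SegmentationMask:
    """ED/ET/NET label volume; TC and WT are derived unions."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise MaskError("mask error: labels must be 3-D")
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = labels.astype(np.int64)
            if not np.array_equal(as_int, labels):
                raise MaskError("mask error: non-integer label values")
            labels = as_int
        codes = set(np.unique(labels).tolist())
        bad = codes - _VALID_CODES
        if bad:
            raise MaskError(f"mask error: unknown label codes {sorted(bad)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    def region(self, name: str) -> np.ndarray:
        """Boolean mask of a base region (NET/ED/ET) or union (TC/WT)."""
        if name in LABEL_CODES:
            return self.labels == LABEL_CODES[name]
        if name == "TC":
            return (self.labels == LABEL_CODES["NET"]) | (self.labels == LABEL_CODES["ET"])
        if name == "WT":
            return self.region("TC") | (self.labels == LABEL_CODES["ED"])
        raise KeyError(f"unknown region {name!r}")


@dataclass(frozen=True)
class AnatomyContext:
    """Shared anatomical reference: brain mask, ventricles, 9-lobe parcellation."""

    brain_mask: VolumeGrid
    ventricle_mask: VolumeGrid
    lobe_parcellation: VolumeGrid

    def __post_init__(self) -> None:
        brain = self.brain_mask.values.astype(bool)
        vent = self.ventricle_mask.values.astype(bool)
        lobes = self.lobe_parcellation.values
        if vent[~brain].any():
            raise ValueError("ventricle voxels outside brain mask")
        if (lobes[~brain] != 0).any():
            raise ValueError("lobe voxels outside brain mask")
        if (lobes[brain] == 0).any():
            raise ValueError("brain voxels without a lobe code")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: study + segmentation, with an optional subtype label."""

    subject_id: str
    study: MpMRIStudy
    mask: SegmentationMask
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.study.grid.shape != self.mask.labels.shape or not np.allclose(
            self.study.spacing, self.mask.spacing
        ):
            raise RegistrationError(
                f"registration error: mask grid differs from study for {self.subject_id!r}"
            )
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")


@dataclass
class FeatureTable:
    """Subjects × named features, with an optional subtype label per row.

    ``data`` holds only numeric feature columns indexed by subject id, in a
    deterministic column order; ``labels`` (if present) is aligned on the
    same index.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature columns: {dupes}")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.data.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, FeatureTable):
            return NotImplemented
        same_labels = (self.labels is None) == (other.labels is None) and (
            self.labels is None or self.labels.equals(other.labels)
        )
        return self.data.equals(other.data) and same_labels


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI file into a :class:`VolumeGrid`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata())
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(values=values, spacing=spacing)


def write_volume(grid: VolumeGrid, path: str | Path, dtype=np.float32) -> None:
    """Write a :class:`VolumeGrid` to NIfTI with a diagonal spacing affine."""
    affine = np.diag(list(grid.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=dtype), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Subject / manifest I/O

MANIFEST_COLUMNS = ("subject_id", "t1", "t1gd", "t2", "flair", "mask", "subtype")
_CHANNEL_KEYS = {"T1": "t1", "T1GD": "t1gd", "T2": "t2", "FLAIR": "flair"}


def read_subject(row: Mapping[str, str], base_dir: str | Path | None = None) -> SubjectRecord:
    """Build a validated :class:`SubjectRecord` from one manifest row.

    ``row`` maps manifest column names to values; relative paths are resolved
    against ``base_dir`` when given.
    """

    def _resolve(p: str) -> Path:
        p = Path(p)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        return p

    channels = {ch: read_volume(_resolve(row[key])) for ch, key in _CHANNEL_KEYS.items()}
    study = MpMRIStudy(subject_id=str(row["subject_id"]), channels=channels)
    mask_grid = read_volume(_resolve(row["mask"]))
    labels = np.rint(mask_grid.values).astype(np.int64)
    if not np.allclose(mask_grid.values, labels):
        raise MaskError("mask error: non-integer voxel values in mask file")
    mask = SegmentationMask(labels=labels, spacing=mask_grid.spacing)
    subtype = row.get("subtype")
    if subtype is not None and (pd.isna(subtype) or subtype == ""):
        subtype = None
    return SubjectRecord(subject_id=str(row["subject_id"]), study=study, mask=mask, subtype=subtype)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV, preserving row order."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "subtype"]
    if missing:
        raise FormatError(f"manifest missing columns: {missing}")
    return df


def read_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    """Read all subjects listed in a manifest, in manifest order."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    return [read_subject(row, base_dir=manifest_path.parent) for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# Feature-table I/O

_LABEL_COLUMN = "subtype"
_INDEX_COLUMN = "subject_id"


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table to CSV (17 significant digits, lossless for float64)."""
    df = table.data.copy()
    if table.labels is not None:
        df[_LABEL_COLUMN] = table.labels
    df.index.name = _INDEX_COLUMN
    df.to_csv(path, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    import csv

    with open(path, newline="") as fh:
        cols = next(csv.reader(fh))
    if len(cols) != len(set(cols)):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise FormatError(f"duplicate feature columns on read: {dupes}")
    df = pd.read_csv(path, index_col=_INDEX_COLUMN)
    labels = None
    if _LABEL_COLUMN in df.columns:
        labels = df.pop(_LABEL_COLUMN).astype(object)
        labels[pd.isna(labels)] = None
    df = df.astype(float)
    df.index = df.index.astype(str)
    return FeatureTable(data=df, labels=labels)


def write_json_report(obj: dict, path: str | Path, schema: str = "gbmrad/1") -> None:
    """Write a JSON report with a schema-version field."""
    payload = {"schema_version": schema}
    payload.update(obj)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default))
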