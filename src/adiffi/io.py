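"""Cohort and segmentation I/O.

Reads and writes atlas-space multi-label tumor segmentations (NIfTI-1)
together with a cohort metadata table (CSV), and derives the three
analysis subcompartments from the tissue labels:

* ``whole_tumor``    — necrosis ∪ enhancing ∪ edema
* ``tumor_core``     — necrosis ∪ enhancing
* ``non_enhancing``  — edema only

All masks of a cohort must live on one shared grid (same shape, same
affine within a small tolerance) so that voxels correspond across
patients. Geometry is always interpreted through the NIfTI affine in
RAS orientation (+x = subject right); voxel indices are 0-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "TISSUES",
    "DEFAULT_LABEL_MAP",
    "ALT_LABEL_MAP",
    "SUBTYPES",
    "MGMT_VALUES",
    "SEX_VALUES",
    "Compartment",
    "SegmentationVolume",
    "CohortTable",
    "CohortError",
    "GridMismatchError",
    "load_cohort",
    "derive_compartment",
    "write_segmentation",
]

TISSUES = ("necrosis", "edema", "enhancing")

#: Classic BraTS label dialect.
DEFAULT_LABEL_MAP: dict[int, str] = {1: "necrosis", 2: "edema", 4: "enhancing"}
#: Alternate dialect used by later segmentation-challenge releases.
ALT_LABEL_MAP: dict[int, str] = {1: "necrosis", 2: "edema", 3: "enhancing"}

SUBTYPES = ("MES", "RTK_I", "RTK_II", "OTHER")
MGMT_VALUES = ("methylated", "unmethylated", "missing")
SEX_VALUES = ("male", "female")

#: Default tolerance (mm) when comparing affines across a cohort.
GRID_ATOL = 1e-4

COHORT_COLUMNS = ("id", "subtype", "mgmt", "sex", "mask_path")


class CohortError(ValueError):
    """Invalid cohort table or segmentation."""


class GridMismatchError(CohortError):
    """A volume does not share the cohort grid."""


class Compartment(str, enum.Enum):
    """Analysis subcompartment of a tumor segmentation."""

    WHOLE_TUMOR = "whole_tumor"
    TUMOR_CORE = "tumor_core"
    NON_ENHANCING = "non_enhancing"

    @property
    def tissues(self) -> frozenset[str]:
        return _COMPARTMENT_TISSUES[self]


_COMPARTMENT_TISSUES: dict[Compartment, frozenset[str]] = {
    Compartment.WHOLE_TUMOR: frozenset(TISSUES),
    Compartment.TUMOR_CORE: frozenset({"necrosis", "enhancing"}),
    Compartment.NON_ENHANCING: frozenset({"edema"}),
}


@dataclass
class SegmentationVolume:
    """One patient's labeled 3D mask on the shared atlas grid.

    Parameters
    ----------
    voxels
        3D integer label array; 0 is background.
    affine
        4x4 voxel-to-world transform in mm (RAS).
    label_map
        Mapping of nonzero labels to tissue names
        (``necrosis`` / ``edema`` / ``enhancing``).
    """

    voxels: np.ndarray
    affine: np.ndarray
    label_map: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise CohortError(f"expected a 3D label array, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise CohortError(f"label array must be integer, got {self.voxels.dtype}")
        if self.affine.shape != (4, 4):
            raise CohortError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise CohortError("affine is not invertible")
        bad = set(self.label_map.values()) - set(TISSUES)
        if bad:
            raise CohortError(f"unknown tissue names in label_map: {sorted(bad)}")
        present = set(np.unique(self.voxels)) - {0}
        unmapped = present - set(self.label_map)
        if unmapped:
            raise CohortError(
                f"labels {sorted(int(v) for v in unmapped)} present in voxels "
                f"but absent from label_map {dict(self.label_map)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def tissue_mask(self, tissue: str) -> np.ndarray:
        labels = [lab for lab, t in self.label_map.items() if t == tissue]
        return np.isin(self.voxels, labels)


def derive_compartment(seg: SegmentationVolume, compartment: Compartment | str) -> np.ndarray:
    """Binary mask of an analysis subcompartment.

    Tissue labels are disjoint (one label per voxel), so compartments are
    plain unions: ``whole_tumor`` covers all three tissues, ``tumor_core``
    covers necrosis plus enhancing tumor, ``non_enhancing`` is edema only.
    """
    compartment = Compartment(compartment)
    labels = [lab for lab, t in seg.label_map.items() if t in compartment.tissues]
    return np.isin(seg.voxels, labels)


@dataclass
class CohortTable:
    """Patient records binding ids to subtype, MGMT status, sex, mask path."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.table)
        missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortError(f"cohort table is missing columns {missing_cols}")
        df = df.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)
        dup = df["id"][df["id"].duplicated()].unique().tolist()
        if dup:
            raise CohortError(f"duplicated patient ids: {dup}")
        for col, allowed in (("subtype", SUBTYPES), ("mgmt", MGMT_VALUES), ("sex", SEX_VALUES)):
            bad = sorted(set(df[col]) - set(allowed))
            if bad:
                raise CohortError(f"unknown {col} values {bad}; allowed: {list(allowed)}")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def labels(self, by: str) -> np.ndarray:
        if by not in ("subtype", "mgmt", "sex"):
            raise CohortError(f"cannot stratify by {by!r}")
        return self.table[by].to_numpy()

    def group_sizes(self, by: str) -> dict[str, int]:
        return self.table[by].value_counts().to_dict()

    def indices_of(self, by: str, group: str) -> np.ndarray:
        """Row indices of one group (row order of the table is preserved)."""
        return np.flatnonzero(self.labels(by) == group)

    def with_labels(self, by: str, new_labels: Sequence[str]) -> "CohortTable":
        df = self.table.copy()
        df[by] = list(new_labels)
        return CohortTable(df)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls(df)


def write_segmentation(seg: SegmentationVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(seg.voxels.astype(np.int16), seg.affine)
    nib.save(img, path)
    return path


def _read_segmentation(path: str | Path, label_map: Mapping[int, str]) -> SegmentationVolume:
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj).astype(np.int16)
    return SegmentationVolume(voxels=voxels, affine=img.affine, label_map=dict(label_map))


def load_cohort(
    table_path: str | Path,
    label_map: Mapping[int, str] | None = None,
    grid_atol: float = GRID_ATOL,
) -> tuple[CohortTable, list[SegmentationVolume]]:
    """Load a cohort CSV and all its segmentation volumes.

    Mask paths are resolved relative to the CSV's directory. Every volume
    is validated against the grid of the first one: identical shape, and
    affine entries equal within ``grid_atol`` mm. Row order is preserved.
    """
    table_path = Path(table_path)
    cohort = CohortTable.from_csv(table_path)
    label_map = dict(label_map) if label_map is not None else dict(DEFAULT_LABEL_MAP)

    volumes: list[SegmentationVolume] = []
    ref_shape: tuple[int, ...] | None = None
    ref_affine: np.ndarray | None = None
    for _, row in cohort.table.iterrows():
        mask_path = Path(row["mask_path"])
        if not mask_path.is_absolute():
            mask_path = table_path.parent / mask_path
        if not mask_path.exists():
            raise CohortError(f"mask for patient {row['id']} not found: {mask_path}")
        seg = _read_segmentation(mask_path, label_map)
        if ref_shape is None:
            ref_shape, ref_affine = seg.shape, seg.affine
        else:
            if seg.shape != ref_shape:
                raise GridMismatchError(
                    f"{mask_path}: shape {seg.shape} != cohort grid {ref_shape}"
                )
            if not np.allclose(seg.affine, ref_affine, atol=grid_atol, rtol=0):
                raise GridMismatchError(f"{mask_path}: affine differs beyond {grid_atol} mm")
        volumes.append(seg)
    return cohort, volumes
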