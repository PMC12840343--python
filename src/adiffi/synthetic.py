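"""Synthetic lesion-cohort generator with known ground truth.

Produces cohorts of atlas-space tumor segmentations whose spatial
distribution is fully specified: lesions are nested spheres (necrosis
core inside an enhancing shell inside an edema halo) rasterized on a
shared grid, with centers drawn per group from a multivariate normal.
An optional planted effect shifts and/or concentrates the centers of
one group so that downstream inference can be scored against a known
effect region. Under a null spec (no effect) the group labels are
exchangeable by construction.

Randomness contract: one master seed; the substream for patient ``i``
is ``default_rng([master_seed, i])``, so outputs are independent of
generation order and identical across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_LABEL_MAP,
    Compartment,
    CohortTable,
    SegmentationVolume,
    derive_compartment,
    write_segmentation,
)

__all__ = [
    "RadiusModel",
    "SpatialEffect",
    "SyntheticCohortSpec",
    "GroundTruth",
    "generate_cohort",
    "null_relabel_cohort",
    "write_cohort",
    "table1_cohort_spec",
]

_TISSUE_ORDER = ("necrosis", "enhancing", "edema")  # inner to outer

# Marginals used to fill the metadata columns that are not the grouping
# variable (proportions of a 227-patient reference cohort).
_MGMT_PROBS = {"methylated": 111 / 227, "unmethylated": 114 / 227, "missing": 2 / 227}
_SEX_PROBS = {"male": 147 / 227, "female": 80 / 227}


class SyntheticSpecError(ValueError):
    """Invalid synthetic cohort specification."""


@dataclass(frozen=True)
class RadiusModel:
    """Mean/sd (mm) of the equivalent-sphere radius per tissue shell.

    Sampled radii are sorted ascending and assigned inner-to-outer
    (necrosis <= enhancing <= edema), which guarantees nesting for every
    patient regardless of sampling noise.
    """

    necrosis_mean: float = 13.4
    necrosis_sd: float = 2.0
    enhancing_mean: float = 20.3
    enhancing_sd: float = 2.0
    edema_mean: float = 28.8
    edema_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in ("necrosis", "enhancing", "edema"):
            if getattr(self, f"{name}_mean") <= 0:
                raise SyntheticSpecError(f"{name} radius mean must be positive")
            if getattr(self, f"{name}_sd") < 0:
                raise SyntheticSpecError(f"{name} radius sd must be non-negative")

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        raw = [
            rng.normal(self.necrosis_mean, self.necrosis_sd),
            rng.normal(self.enhancing_mean, self.enhancing_sd),
            rng.normal(self.edema_mean, self.edema_sd),
        ]
        radii = np.sort(np.clip(raw, 1e-3, None))
        return dict(zip(_TISSUE_ORDER, (float(r) for r in radii)))


@dataclass(frozen=True)
class SpatialEffect:
    """Planted spatial predilection for one group.

    ``offset_mm`` shifts the group's center distribution. A boost region
    (``boost_center_mm`` + ``boost_radius_mm``) additionally concentrates
    a fraction ``boost_prob`` of the group's lesions inside a sphere:
    with that probability the center is rejection-sampled from the
    group's center distribution conditioned on the sphere.
    """

    group: str
    offset_mm: tuple[float, float, float] | None = None
    boost_center_mm: tuple[float, float, float] | None = None
    boost_radius_mm: float = 0.0
    boost_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.offset_mm is None and self.boost_center_mm is None:
            raise SyntheticSpecError("effect must define an offset and/or a boost region")
        if self.boost_center_mm is not None and self.boost_radius_mm <= 0:
            raise SyntheticSpecError("boost_radius_mm must be positive")
        if not 0.0 <= self.boost_prob <= 1.0:
            raise SyntheticSpecError("boost_prob must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    groups: tuple[tuple[str, int], ...] = (("MES", 5), ("RTK_I", 5))
    center_mean_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_cov_mm2: Sequence[Sequence[float]] | None = None  # default: diag(15^2)
    radius_model: RadiusModel = field(default_factory=RadiusModel)
    effect: SpatialEffect | None = None
    master_seed: int = 0
    #: "error": out-of-grid lesion raises; "resample": redraw the center.
    center_policy: str = "error"
    label_map: tuple[tuple[int, str], ...] = tuple(DEFAULT_LABEL_MAP.items())

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.grid_shape):
            raise SyntheticSpecError("grid_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise SyntheticSpecError("voxel sizes must be positive")
        if not self.groups:
            raise SyntheticSpecError("at least one group is required")
        for label, n in self.groups:
            if n < 1:
                raise SyntheticSpecError(f"group {label!r} must have n_patients >= 1")
        cov = np.asarray(self.cov)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise SyntheticSpecError("center covariance must be symmetric 3x3")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise SyntheticSpecError("center covariance is not positive definite") from exc
        if self.center_policy not in ("error", "resample"):
            raise SyntheticSpecError("center_policy must be 'error' or 'resample'")
        if self.effect is not None and self.effect.group not in [g for g, _ in self.groups]:
            raise SyntheticSpecError(f"effect group {self.effect.group!r} not in groups")

    @property
    def cov(self) -> np.ndarray:
        if self.center_cov_mm2 is None:
            return np.diag([15.0**2] * 3)
        return np.asarray(self.center_cov_mm2, dtype=float)

    @property
    def n_patients(self) -> int:
        return sum(n for _, n in self.groups)

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world transform centering the grid on the origin (RAS).

        With the grid centered, the midsagittal plane x = 0 mm lies in the
        middle of the volume, matching an atlas-like coordinate frame.
        """
        aff = np.eye(4)
        vox = np.asarray(self.voxel_size_mm, dtype=float)
        aff[:3, :3] = np.diag(vox)
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * vox
        return aff


@dataclass
class GroundTruth:
    """Per-patient truth plus the planted-effect region (empty under null)."""

    centers_mm: dict[str, tuple[float, float, float]]
    compartment_voxels: dict[str, dict[str, int]]
    effect_region_mask: np.ndarray

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "centers_mm": self.centers_mm,
            "compartment_voxels": self.compartment_voxels,
            "effect_region_voxels": [
                [int(i), int(j), int(k)] for i, j, k in zip(*np.nonzero(self.effect_region_mask))
            ],
            "grid_shape": list(self.effect_region_mask.shape),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _voxel_center_grids(spec: SyntheticCohortSpec) -> tuple[np.ndarray, ...]:
    """World-mm coordinates of voxel centers along each axis."""
    aff = spec.affine
    return tuple(
        aff[k, k] * np.arange(spec.grid_shape[k]) + aff[k, 3] for k in range(3)
    )


def _rasterize_nested_spheres(
    spec: SyntheticCohortSpec, center: np.ndarray, radii: dict[str, float]
) -> np.ndarray:
    """Label volume of nested spheres; voxel-center-in-sphere inclusion (<= r)."""
    inv = {t: lab for lab, t in spec.label_map}
    vol = np.zeros(spec.grid_shape, dtype=np.int16)
    xs, ys, zs = _voxel_center_grids(spec)
    r_out = radii["edema"]
    # bounding box keeps the distance computation local
    sl = []
    for ax, coords in enumerate((xs, ys, zs)):
        inside = np.flatnonzero(np.abs(coords - center[ax]) <= r_out)
        if inside.size == 0:
            return vol
        sl.append(slice(inside[0], inside[-1] + 1))
    d2 = (
        (xs[sl[0], None, None] - center[0]) ** 2
        + (ys[None, sl[1], None] - center[1]) ** 2
        + (zs[None, None, sl[2]] - center[2]) ** 2
    )
    box = np.zeros(d2.shape, dtype=np.int16)
    box[d2 <= radii["edema"] ** 2] = inv["edema"]
    box[d2 <= radii["enhancing"] ** 2] = inv["enhancing"]
    box[d2 <= radii["necrosis"] ** 2] = inv["necrosis"]
    vol[tuple(sl)] = box
    return vol


def _world_bounds(spec: SyntheticCohortSpec) -> tuple[np.ndarray, np.ndarray]:
    xs, ys, zs = _voxel_center_grids(spec)
    lo = np.array([xs[0], ys[0], zs[0]])
    hi = np.array([xs[-1], ys[-1], zs[-1]])
    return lo, hi


def _sample_center(
    spec: SyntheticCohortSpec, group: str, rng: np.random.Generator, patient_index: int
) -> np.ndarray:
    mean = np.asarray(spec.center_mean_mm, dtype=float)
    eff = spec.effect
    boosted = False
    if eff is not None and group == eff.group:
        if eff.offset_mm is not None:
            mean = mean + np.asarray(eff.offset_mm, dtype=float)
        if eff.boost_center_mm is not None:
            boosted = rng.random() < eff.boost_prob

    lo, hi = _world_bounds(spec)
    max_tries = 100_000
    for _ in range(max_tries):
        c = rng.multivariate_normal(mean, spec.cov)
        if boosted:
            # rejection-sample the base distribution conditioned on the sphere
            if np.linalg.norm(c - np.asarray(eff.boost_center_mm)) > eff.boost_radius_mm:
                continue
        return c
    raise SyntheticSpecError(
        f"patient {patient_index}: could not draw a center inside the boost region "
        f"after {max_tries} tries; enlarge the region or move it nearer the mean"
    )


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[CohortTable, list[SegmentationVolume], GroundTruth]:
    """Generate one synthetic cohort.

    Returns the metadata table, one segmentation per patient (all on the
    shared grid/affine of the spec), and the ground truth. Deterministic
    given ``spec.master_seed``.
    """
    label_map = dict(spec.label_map)
    lo, hi = _world_bounds(spec)
    records = []
    volumes: list[SegmentationVolume] = []
    centers: dict[str, tuple[float, float, float]] = {}
    comp_voxels: dict[str, dict[str, int]] = {}

    idx = 0
    for group, n in spec.groups:
        for _ in range(n):
            rng = np.random.default_rng([spec.master_seed, idx])
            radii = spec.radius_model.sample(rng)
            r = radii["edema"]
            for attempt in range(100_000):
                center = _sample_center(spec, group, rng, idx)
                fits = bool(np.all(center - r >= lo) and np.all(center + r <= hi))
                if fits:
                    break
                if spec.center_policy == "error":
                    raise SyntheticSpecError(
                        f"patient {idx}: lesion of radius {r:.1f} mm at "
                        f"{np.round(center, 1).tolist()} exceeds the grid bounds"
                    )
            else:
                raise SyntheticSpecError(
                    f"patient {idx}: no lesion of radius {r:.1f} mm fits the grid"
                )
            vox = _rasterize_nested_spheres(spec, center, radii)
            seg = SegmentationVolume(voxels=vox, affine=spec.affine, label_map=label_map)

            pid = f"P{idx:04d}"
            records.append(
                {
                    "id": pid,
                    "subtype": group,
                    "mgmt": _draw_categorical(rng, _MGMT_PROBS),
                    "sex": _draw_categorical(rng, _SEX_PROBS),
                    "mask_path": f"{pid}.nii",
                }
            )
            centers[pid] = tuple(float(v) for v in center)
            comp_voxels[pid] = {
                c.value: int(derive_compartment(seg, c).sum()) for c in Compartment
            }
            volumes.append(seg)
            idx += 1

    cohort = CohortTable(pd.DataFrame.from_records(records))
    truth = GroundTruth(
        centers_mm=centers,
        compartment_voxels=comp_voxels,
        effect_region_mask=effect_region_mask(spec),
    )
    return cohort, volumes, truth


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys])
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def effect_region_mask(spec: SyntheticCohortSpec) -> np.ndarray:
    """Binary volume marking where lesion presence is elevated by the effect.

    Empty (all False) iff the spec has no effect. For a boost effect the
    region is the boost sphere dilated by the mean edema radius — the set
    of voxels a boosted lesion can cover. For a pure offset effect it is
    the sphere of radius |offset| + mean edema radius around the shifted
    mean.
    """
    mask = np.zeros(spec.grid_shape, dtype=bool)
    eff = spec.effect
    if eff is None:
        return mask
    halo = spec.radius_model.edema_mean
    if eff.boost_center_mm is not None:
        center = np.asarray(eff.boost_center_mm, dtype=float)
        radius = eff.boost_radius_mm + halo
    else:
        offset = np.asarray(eff.offset_mm, dtype=float)
        center = np.asarray(spec.center_mean_mm, dtype=float) + offset
        radius = float(np.linalg.norm(offset)) + halo
    xs, ys, zs = _voxel_center_grids(spec)
    d2 = (
        (xs[:, None, None] - center[0]) ** 2
        + (ys[None, :, None] - center[1]) ** 2
        + (zs[None, None, :] - center[2]) ** 2
    )
    mask[d2 <= radius**2] = True
    return mask


def null_relabel_cohort(cohort: CohortTable, seed: int, by: str = "subtype") -> CohortTable:
    """Randomly reassign group labels, preserving group sizes exactly.

    The returned cohort has the same patients in the same row order; only
    the ``by`` column is permuted (label multiset unchanged).
    """
    labels = cohort.labels(by)
    if len(set(labels)) < 2:
        raise ValueError(f"cannot relabel a single-group cohort (by={by!r})")
    rng = np.random.default_rng(seed)
    return cohort.with_labels(by, labels[rng.permutation(len(labels))])


def table1_cohort_spec(
    master_seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    effect: SpatialEffect | None = None,
) -> SyntheticCohortSpec:
    """Default 227-patient spec: subtype sizes 85/69/54/19, whole-tumor
    volumes around 90-105 cm^3 (edema-radius mean 28.8 mm)."""
    return SyntheticCohortSpec(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        groups=(("MES", 85), ("RTK_I", 69), ("RTK_II", 54), ("OTHER", 19)),
        center_mean_mm=(0.0, 0.0, 0.0),
        center_cov_mm2=np.diag([15.0**2, 15.0**2, 12.0**2]).tolist(),
        radius_model=RadiusModel(),
        effect=effect,
        master_seed=master_seed,
        center_policy="resample",
    )


def write_cohort(
    out_dir: str | Path,
    cohort: CohortTable,
    volumes: Sequence[SegmentationVolume],
    truth: GroundTruth | None = None,
) -> Path:
    """Write NIfTI volumes, cohort.csv and ground_truth.json to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for seg, rel in zip(volumes, cohort.table["mask_path"]):
        write_segmentation(seg, out_dir / rel)
    table_path = cohort.to_csv(out_dir / "cohort.csv")
    if truth is not None:
        truth.to_json(out_dir / "ground_truth.json")
    return table_path
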