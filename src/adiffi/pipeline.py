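"""End-to-end run orchestration.

Sequences the analysis stages for a cohort — summary tables, per-patient
volumetrics and laterality, frequency/differential maps, and ADIFFI —
for every requested comparison x compartment cell, and records every
artifact in a JSON manifest (config hash + seed) so a completed run is
fully reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import inference, volumetrics
from .frequency import differential_map, frequency_map, map_summary
from .io import Compartment, CohortTable, SegmentationVolume, derive_compartment, load_cohort
from .inference import AdiffiConfig

log = logging.getLogger("adiffi")

__all__ = ["RunConfig", "run_analysis", "cohort_summary", "DEFAULT_COMPARISONS"]

DEFAULT_COMPARISONS: dict[str, list[tuple[str, str]]] = {
    "subtype": [("MES", "RTK_I"), ("MES", "RTK_II"), ("RTK_I", "RTK_II")],
    "mgmt": [("methylated", "unmethylated")],
    "sex": [("male", "female")],
}

#: Groups kept in cohort summaries but excluded from pairwise comparisons.
EXCLUDED_FROM_COMPARISONS = {"OTHER", "missing"}


@dataclass
class RunConfig:
    cohort_path: str
    out_dir: str
    group_by: str = "subtype"
    comparisons: list[tuple[str, str]] | None = None
    compartments: list[str] = field(
        default_factory=lambda: [c.value for c in Compartment]
    )
    adiffi: AdiffiConfig = field(default_factory=AdiffiConfig)
    midline_x_mm: float = 0.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.group_by not in DEFAULT_COMPARISONS:
            raise ValueError(f"group_by must be one of {list(DEFAULT_COMPARISONS)}")
        if self.comparisons is None:
            self.comparisons = list(DEFAULT_COMPARISONS[self.group_by])
        self.comparisons = [tuple(pair) for pair in self.comparisons]
        self.compartments = [Compartment(c).value for c in self.compartments]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        adiffi_cfg = AdiffiConfig(**raw.pop("adiffi", {}))
        return cls(adiffi=adiffi_cfg, **raw)

    def to_dict(self) -> dict:
        return {
            "cohort_path": str(self.cohort_path),
            "out_dir": str(self.out_dir),
            "group_by": self.group_by,
            "comparisons": [list(p) for p in self.comparisons],
            "compartments": list(self.compartments),
            "adiffi": vars(self.adiffi).copy(),
            "midline_x_mm": self.midline_x_mm,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def cohort_summary(cohort: CohortTable) -> pd.DataFrame:
    """Counts and percentages per stratification variable and level."""
    rows = []
    n = len(cohort)
    for var in ("subtype", "mgmt", "sex"):
        counts = cohort.table[var].value_counts()
        for level, count in counts.items():
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "n": int(count),
                    "percent": round(count / n * 100, 1),
                }
            )
    return pd.DataFrame(rows)


def _volumetrics_stage(
    cohort: CohortTable,
    volumes: Sequence[SegmentationVolume],
    config: RunConfig,
    out: Path,
) -> dict:
    vol_df = volumetrics.volume_table(cohort.ids, volumes)
    # laterality per compartment that has a meaningful center (whole + core)
    for comp in (Compartment.WHOLE_TUMOR, Compartment.TUMOR_CORE):
        sides, xs = [], []
        for seg in volumes:
            mask = derive_compartment(seg, comp)
            if not mask.any():
                sides.append("empty")
                xs.append(np.nan)
                continue
            com = volumetrics.center_of_mass(mask, seg.affine)
            xs.append(float(com[0]))
            sides.append(volumetrics.classify_hemisphere(com, config.midline_x_mm))
        vol_df[f"{comp.value}_com_x_mm"] = xs
        vol_df[f"{comp.value}_hemisphere"] = sides
    vol_path = out / "patient_volumetrics.csv"
    vol_df.to_csv(vol_path, index=False)

    labels = cohort.labels(config.group_by)
    usable = ~np.isin(labels, list(EXCLUDED_FROM_COMPARISONS))
    stats_rows = []
    for comp in config.compartments:
        values_by_group = {
            g: vol_df.loc[(labels == g) & usable, comp].to_numpy()
            for g in sorted(set(labels[usable]))
        }
        test, stat, p = volumetrics.compare_volumes(values_by_group)
        stats_rows.append(
            {"analysis": f"volume_{comp}", "test": test, "statistic": stat, "p": p}
        )

    side = vol_df["whole_tumor_hemisphere"].to_numpy()
    n_r, n_l, n_mid = (
        int((side == "right").sum()),
        int((side == "left").sum()),
        int((side == "midline").sum()),
    )
    stat, p = volumetrics.laterality_gof(n_r, n_l)
    stats_rows.append(
        {"analysis": "laterality_gof_whole_cohort", "test": "chi2_gof", "statistic": stat, "p": p}
    )
    groups = sorted(set(labels[usable]))
    table = [
        [
            int(((labels == g) & (side == "right")).sum()),
            int(((labels == g) & (side == "left")).sum()),
        ]
        for g in groups
    ]
    if len(groups) >= 2 and not any(sum(row) == 0 for row in table):
        stat, p, df = volumetrics.laterality_contingency(table)
        stats_rows.append(
            {
                "analysis": f"laterality_by_{config.group_by}",
                "test": "chi2_independence",
                "statistic": stat,
                "p": p,
            }
        )
    stats_path = out / "group_statistics.csv"
    pd.DataFrame(stats_rows).to_csv(stats_path, index=False)
    return {
        "patient_volumetrics": str(vol_path),
        "group_statistics": str(stats_path),
        "hemisphere_counts": {"right": n_r, "left": n_l, "midline": n_mid},
    }


def _save_map(values: np.ndarray, affine: np.ndarray, path: Path) -> str:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), path)
    return str(path)


def _comparison_cell(
    cohort: CohortTable,
    volumes: Sequence[SegmentationVolume],
    config: RunConfig,
    group_a: str,
    group_b: str,
    comp: Compartment,
    out: Path,
) -> dict:
    t0 = time.perf_counter()
    idx_a = cohort.indices_of(config.group_by, group_a)
    idx_b = cohort.indices_of(config.group_by, group_b)
    for g, idx in ((group_a, idx_a), (group_b, idx_b)):
        if idx.size == 0:
            raise ValueError(f"requested group {g!r} not present in the cohort")
    masks_a = [derive_compartment(volumes[i], comp) for i in idx_a]
    masks_b = [derive_compartment(volumes[i], comp) for i in idx_b]
    affine = volumes[0].affine

    cell = f"{group_a}_vs_{group_b}__{comp.value}"
    cell_dir = out / cell
    cell_dir.mkdir(parents=True, exist_ok=True)

    result = inference.adiffi(
        masks_a,
        masks_b,
        config.adiffi,
        group_a=group_a,
        group_b=group_b,
        compartment=comp,
    )
    fa, fb, diff = result.frequency_a, result.frequency_b, result.differential

    summaries = []
    for fm in (fa, fb):
        max_f, above = map_summary(fm)
        summaries.append(
            {
                "group": fm.group_label,
                "n": fm.n_total,
                "max_frequency_pct": max_f,
                **{f"voxels_above_{int(t)}pct": c for t, c in above.items()},
            }
        )
    pd.DataFrame(summaries).to_csv(cell_dir / "frequency_summary.csv", index=False)

    cluster_rows = [
        {
            "cluster_id": i + 1,
            "size_voxels": c.size,
            "min_raw_p": c.min_p,
            "mean_differential_pct": c.mean_differential,
            "direction": c.direction,
            "relative_effect_pct": c.relative_effect,
            "significant": c.significant,
        }
        for i, c in enumerate(result.clusters)
    ]
    pd.DataFrame(
        cluster_rows,
        columns=[
            "cluster_id",
            "size_voxels",
            "min_raw_p",
            "mean_differential_pct",
            "direction",
            "relative_effect_pct",
            "significant",
        ],
    ).to_csv(cell_dir / "clusters.csv", index=False)

    label_map = np.zeros(result.p_map.shape, dtype=np.int16)
    for i, c in enumerate(result.clusters, start=1):
        label_map[tuple(c.indices.T)] = i

    artifacts = {
        "frequency_a": _save_map(fa.values, affine, cell_dir / f"frequency_{group_a}.nii"),
        "frequency_b": _save_map(fb.values, affine, cell_dir / f"frequency_{group_b}.nii"),
        "differential": _save_map(diff.values, affine, cell_dir / "differential.nii"),
        "p_map": _save_map(result.p_map, affine, cell_dir / "p_map.nii"),
        "significant_mask": _save_map(
            result.significant_mask().astype(np.float32), affine, cell_dir / "significant.nii"
        ),
        "cluster_labels": _save_map(label_map, affine, cell_dir / "cluster_labels.nii"),
        "frequency_summary": str(cell_dir / "frequency_summary.csv"),
        "clusters": str(cell_dir / "clusters.csv"),
    }
    report = {
        "n_significant_clusters": result.n_significant_clusters,
        "min_raw_p": result.min_raw_p,
        "n_significant_voxels": result.n_significant_voxels,
        "cluster_size_threshold": result.cluster_size_threshold,
        "corrected_p_max_cluster": result.corrected_p_max_cluster,
        "null_max_size_quantiles": {
            q: float(np.quantile(result.null_max_sizes, float(q)))
            for q in ("0.5", "0.9", "0.95", "1.0")
        },
    }
    log.info(
        "%s: %d clusters (%d significant, min size %d) in %.1fs",
        cell,
        len(result.clusters),
        result.n_significant_clusters,
        result.cluster_size_threshold,
        time.perf_counter() - t0,
    )
    return {"artifacts": artifacts, "report": report}


def run_analysis(config: RunConfig) -> dict:
    """Execute every requested comparison x compartment; return the manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.adiffi.seed,
        "status": "invalid",
        "stages": {},
    }
    manifest_path = out / "manifest.json"
    try:
        cohort, volumes = load_cohort(config.cohort_path)
        summary = cohort_summary(cohort)
        summary_path = out / "cohort_summary.csv"
        summary.to_csv(summary_path, index=False)
        manifest["stages"]["cohort_summary"] = {"path": str(summary_path)}

        manifest["stages"]["volumetrics"] = _volumetrics_stage(cohort, volumes, config, out)

        cells = {}
        for group_a, group_b in config.comparisons:
            for comp_name in config.compartments:
                comp = Compartment(comp_name)
                cell = f"{group_a}_vs_{group_b}__{comp.value}"
                try:
                    cells[cell] = _comparison_cell(
                        cohort, volumes, config, group_a, group_b, comp, out
                    )
                except Exception as exc:
                    raise RuntimeError(f"stage {cell!r} failed: {exc}") from exc
        manifest["stages"]["comparisons"] = cells
        manifest["status"] = "complete"
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
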