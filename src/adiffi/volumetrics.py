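"""Per-patient volumetrics, rank-based group comparisons, and laterality.

Conventions, stated once because they decide printed p-values:

* Volume comparisons: Kruskal-Wallis for 3+ groups; two-sided
  Mann-Whitney U for 2 groups (exact when combined n <= 20 and there are
  no ties, normal approximation with midrank tie correction and no
  continuity correction otherwise).
* Hemisphere goodness of fit against 50/50: 1-df chi-square WITHOUT
  continuity correction.
* Contingency tests of independence: Yates continuity correction for
  2x2 tables, none for larger tables.
* Geometry is computed in world mm (RAS: +x = subject right); the
  midsagittal plane defaults to x = 0. Centers of mass exactly on the
  midline are classified ``midline`` and excluded from laterality counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Compartment, SegmentationVolume, derive_compartment

__all__ = [
    "EmptyMaskError",
    "TumorLocation",
    "compartment_volume",
    "volume_table",
    "compare_volumes",
    "center_of_mass",
    "classify_hemisphere",
    "laterality_gof",
    "laterality_contingency",
    "hemisphere_counts",
]

MIDLINE_TOL = 1e-9


class EmptyMaskError(ValueError):
    """Raised when a geometric quantity is requested for an empty mask."""


@dataclass(frozen=True)
class TumorLocation:
    center_of_mass_mm: tuple[float, float, float]
    hemisphere: str  # "left" | "right" | "midline"


def compartment_volume(mask: np.ndarray, voxel_volume_mm3: float) -> float:
    """Volume of a binary mask in cm^3 (voxel count x voxel volume / 1000)."""
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel_volume_mm3 must be positive")
    return float(np.count_nonzero(mask)) * voxel_volume_mm3 / 1000.0


def volume_table(
    ids: Sequence[str], volumes: Sequence[SegmentationVolume]
) -> pd.DataFrame:
    """Per-patient volumes (cm^3) of all three compartments."""
    rows = []
    for pid, seg in zip(ids, volumes):
        vv = seg.voxel_volume_mm3
        row = {"id": pid}
        for c in Compartment:
            row[c.value] = compartment_volume(derive_compartment(seg, c), vv)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_volumes(values_by_group: Mapping[str, Sequence[float]]) -> tuple[str, float, float]:
    """Rank-based comparison of a quantity across groups.

    Returns ``(test_name, statistic, p)``: two-sided Mann-Whitney U for
    exactly two groups, Kruskal-Wallis for three or more.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    samples = list(groups.values())
    if len(samples) == 2:
        a, b = samples
        pooled = np.concatenate([a, b])
        exact = pooled.size <= 20 and np.unique(pooled).size == pooled.size
        if exact:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        else:
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=False
            )
        return "mann-whitney-u", float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*samples)
    return "kruskal-wallis", float(res.statistic), float(res.pvalue)


def center_of_mass(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Unweighted mean world-mm coordinate of the mask's voxel centers."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise EmptyMaskError("cannot compute the center of mass of an empty mask")
    affine = np.asarray(affine, dtype=float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    return world.mean(axis=0)


def classify_hemisphere(
    com_mm: Sequence[float], midline_x_mm: float = 0.0, tol: float = MIDLINE_TOL
) -> str:
    x = float(com_mm[0])
    if not np.isfinite(x):
        raise ValueError("center of mass is not finite")
    if abs(x - midline_x_mm) <= tol:
        return "midline"
    return "right" if x > midline_x_mm else "left"


def hemisphere_counts(
    locations: Sequence[TumorLocation] | Sequence[str],
) -> tuple[int, int, int]:
    """(n_right, n_left, n_midline); midline cases are counted separately
    and excluded from the chi-square inputs."""
    sides = [
        loc.hemisphere if isinstance(loc, TumorLocation) else loc for loc in locations
    ]
    return sides.count("right"), sides.count("left"), sides.count("midline")


def laterality_gof(n_right: int, n_left: int) -> tuple[float, float]:
    """1-df chi-square goodness of fit against a 50/50 hemisphere split.

    No continuity correction. Returns (statistic, two-sided p).
    """
    if n_right < 0 or n_left < 0:
        raise ValueError("counts must be non-negative")
    if n_right + n_left == 0:
        raise ValueError("at least one lateralized patient is required")
    res = stats.chisquare([n_right, n_left])
    return float(res.statistic), float(res.pvalue)


def laterality_contingency(table: Sequence[Sequence[int]]) -> tuple[float, float, int]:
    """Chi-square test of independence on a groups x {right,left} table.

    Yates continuity correction is applied to 2x2 tables only. Returns
    (statistic, p, df).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("table has a zero row or column margin")
    correction = arr.shape == (2, 2)
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue), int(res.dof)
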