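"""Voxel-wise lesion frequency maps and group-vs-group differentials.

A frequency map holds, per voxel, the percentage of a group's patients
whose lesion (for a given compartment) covers that voxel:
``F(v) = counts(v) / n_total * 100``. A differential map is the signed
voxel-wise difference of two groups' frequency maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Compartment

__all__ = ["FrequencyMap", "DifferentialMap", "frequency_map", "differential_map", "map_summary"]


@dataclass
class FrequencyMap:
    values: np.ndarray  # percentages in [0, 100]
    counts: np.ndarray  # N_tumor(v), integer
    n_total: int
    group_label: str
    compartment: Compartment


@dataclass
class DifferentialMap:
    values: np.ndarray  # F_a - F_b, in [-100, 100]
    group_a: str
    group_b: str
    compartment: Compartment


def frequency_map(
    masks: Sequence[np.ndarray],
    group_label: str,
    compartment: Compartment | str,
    n_total: int | None = None,
) -> FrequencyMap:
    """Per-voxel percentage of patients with lesion presence.

    ``n_total`` defaults to ``len(masks)`` and must equal it when given.
    """
    if len(masks) == 0:
        raise ValueError(f"group {group_label!r} has no masks")
    if n_total is None:
        n_total = len(masks)
    elif n_total != len(masks):
        raise ValueError(f"n_total={n_total} does not match {len(masks)} masks")
    shape = masks[0].shape
    counts = np.zeros(shape, dtype=np.int32)
    for m in masks:
        if m.shape != shape:
            raise ValueError("masks do not share a grid")
        counts += m.astype(bool)
    values = counts / n_total * 100.0
    return FrequencyMap(
        values=values,
        counts=counts,
        n_total=n_total,
        group_label=group_label,
        compartment=Compartment(compartment),
    )


def differential_map(fa: FrequencyMap, fb: FrequencyMap) -> DifferentialMap:
    """Signed voxel-wise difference ``F_a - F_b`` of two frequency maps."""
    if fa.compartment != fb.compartment:
        raise ValueError(
            f"compartment mismatch: {fa.compartment.value} vs {fb.compartment.value}"
        )
    if fa.values.shape != fb.values.shape:
        raise ValueError("frequency maps do not share a grid")
    if fa.group_label == fb.group_label:
        raise ValueError("differential map requires two different groups")
    return DifferentialMap(
        values=fa.values - fb.values,
        group_a=fa.group_label,
        group_b=fb.group_label,
        compartment=fa.compartment,
    )


def map_summary(
    f: FrequencyMap, thresholds: Sequence[float] = (10.0, 20.0)
) -> tuple[float, dict[float, int]]:
    """Maximum frequency and voxel counts strictly above each threshold."""
    for t in thresholds:
        if not 0 < t < 100:
            raise ValueError(f"threshold {t} outside (0, 100)")
    max_frequency = float(f.values.max()) if f.values.size else 0.0
    above = {float(t): int(np.count_nonzero(f.values > t)) for t in thresholds}
    return max_frequency, above
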