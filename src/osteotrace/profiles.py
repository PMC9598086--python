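"""Axial "time-series" profiles: mark positions projected on an anatomical
axis, binned into units proportional to bone length, and stacked for
comparison across samples."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import BoneTemplate, MarkRecord
from .errors import ValidationError


@dataclass
class SeriesProfile:
    label: str
    axis: str
    counts: np.ndarray  # (n_units,) int
    bone_length: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def n_units(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros(len(self.counts))
        return self.counts / total


def axial_positions(
    marks: Iterable[MarkRecord],
    template: BoneTemplate,
    axis: str = "x",
    tol: float = 0.05,
) -> np.ndarray:
    """Normalized [0, 1] positions of marks along an anatomical axis; linear
    marks are represented by their midpoint."""
    if axis not in "xyz":
        raise ValidationError("axis must be x, y or z")
    k = "xyz".index(axis)
    marks = list(marks)
    for m in marks:
        if m.template_id != template.template_id:
            raise ValidationError(
                f"mark {m.mark_id} belongs to template {m.template_id}, "
                f"not {template.template_id}"
            )
    if not marks:
        return np.empty(0)
    coord = np.array([m.position[k] for m in marks])
    lo = template.points[:, k].min()
    extent = template.points[:, k].max() - lo
    pos = (coord - lo) / extent
    if np.any(pos < -tol) or np.any(pos > 1.0 + tol):
        raise ValidationError("mark position outside the template axis extent")
    return np.clip(pos, 0.0, 1.0)


def bin_series(
    positions: np.ndarray,
    n_units: int = 50,
    *,
    label: str = "",
    axis: str = "x",
    bone_length: float = 1.0,
) -> SeriesProfile:
    """Histogram of normalized positions into half-open bins [k/N, (k+1)/N);
    the last bin is closed so position 1.0 is counted."""
    if n_units < 2:
        raise ValidationError("n_units must be >= 2")
    positions = np.asarray(positions, float)
    if len(positions) == 0:
        warnings.warn("empty position list: all-zero profile")
        return SeriesProfile(label=label, axis=axis,
                             counts=np.zeros(n_units, dtype=np.int64),
                             bone_length=bone_length)
    if positions.min() < 0.0 or positions.max() > 1.0:
        raise ValidationError("positions must lie in [0, 1]")
    idx = np.minimum((positions * n_units).astype(np.int64), n_units - 1)
    counts = np.bincount(idx, minlength=n_units)
    return SeriesProfile(label=label, axis=axis, counts=counts,
                         bone_length=bone_length)


def relative_profile(profiles: Sequence[SeriesProfile]) -> pd.DataFrame:
    """Stack per-sample proportions plus their across-sample mean; supports
    sequential concatenation of elements by concatenating profiles first."""
    if not profiles:
        raise ValidationError("need at least one profile")
    n_units = {p.n_units for p in profiles}
    if len(n_units) != 1:
        raise ValidationError(f"profiles have mismatched n_units: {sorted(n_units)}")
    table = pd.DataFrame(
        {p.label or f"sample{i}": p.proportions for i, p in enumerate(profiles)}
    )
    table.insert(0, "bin", np.arange(profiles[0].n_units))
    table["mean"] = table.drop(columns="bin").mean(axis=1)
    return table


def concat_profiles(profiles: Sequence[SeriesProfile], label: str = "") -> SeriesProfile:
    """Concatenate element profiles end-to-end (femur then tibia style)."""
    if not profiles:
        raise ValidationError("need at least one profile")
    return SeriesProfile(
        label=label or "+".join(p.label for p in profiles),
        axis=profiles[0].axis,
        counts=np.concatenate([p.counts for p in profiles]),
        bone_length=float(sum(p.bone_length for p in profiles)),
    )
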