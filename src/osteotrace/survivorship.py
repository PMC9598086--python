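"""Polygonal/interval cropping on the template cloud, superimposition
heatmaps, and overlap-based MNE.

Crops are boolean index masks into the shared template point cloud, which
makes overlap counting exact. Externally supplied cropped clouds are matched
back onto template points by nearest neighbour within a tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .core import AssemblageStore, BoneTemplate
from .errors import EmptyCropError, ValidationError

_PLANE_AXES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


@dataclass
class CropMask:
    """Retained-point mask of one specimen over its template cloud."""

    specimen_id: str
    template_id: str
    retained: np.ndarray  # (n_template_points,) bool

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool)
        if not self.retained.any():
            raise EmptyCropError("empty crop: mask retains zero points")

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


@dataclass
class HeatmapField:
    """Per-template-point specimen overlap counts; max(counts) is the MNE."""

    template_id: str
    counts: np.ndarray  # (n_template_points,) int
    n_specimens: int

    @property
    def mne(self) -> int:
        return int(self.counts.max())

    def to_frame(self, template: BoneTemplate) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "point_index": np.arange(len(self.counts)),
                "x": template.points[:, 0],
                "y": template.points[:, 1],
                "z": template.points[:, 2],
                "count": self.counts,
            }
        )


def crop_polygonal(
    template: BoneTemplate,
    polygon_2d: Sequence[Sequence[float]],
    projection_plane: str = "xy",
    keep: str = "inside",
    *,
    specimen_id: str = "",
) -> CropMask:
    """Retain the template points whose projection falls inside (or outside)
    a simple polygon; boundary points count as inside."""
    if projection_plane not in _PLANE_AXES:
        raise ValidationError(f"projection plane must be one of {list(_PLANE_AXES)}")
    if keep not in ("inside", "outside"):
        raise ValidationError("keep must be 'inside' or 'outside'")
    verts = np.asarray(polygon_2d, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValidationError("polygon needs >= 3 (x, y) vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ValidationError("self-intersecting or otherwise invalid polygon")
    i, j = _PLANE_AXES[projection_plane]
    proj = shapely.points(template.points[:, [i, j]])
    inside = shapely.covers(poly, proj)  # covers => boundary counts as inside
    retained = inside if keep == "inside" else ~inside
    if not retained.any():
        raise EmptyCropError("empty crop: polygon retains zero points")
    return CropMask(specimen_id=specimen_id, template_id=template.template_id,
                    retained=retained)


def crop_interval(
    template: BoneTemplate,
    axis: str = "x",
    lo_frac: float = 0.0,
    hi_frac: float = 1.0,
    *,
    specimen_id: str = "",
) -> CropMask:
    """Retain points whose normalized coordinate on ``axis`` lies in
    ``[lo_frac, hi_frac)`` (``hi_frac == 1`` closes the upper end)."""
    if axis not in "xyz":
        raise ValidationError("axis must be x, y or z")
    if not (0.0 <= lo_frac < hi_frac <= 1.0):
        raise ValidationError(f"invalid interval [{lo_frac}, {hi_frac})")
    k = "xyz".index(axis)
    coord = template.points[:, k]
    lo, hi = coord.min(), coord.max()
    frac = (coord - lo) / (hi - lo)
    retained = (frac >= lo_frac) & ((frac < hi_frac) | (hi_frac == 1.0))
    if not retained.any():
        raise EmptyCropError("empty crop: interval retains zero points")
    return CropMask(specimen_id=specimen_id, template_id=template.template_id,
                    retained=retained)


def mask_from_cloud(
    template: BoneTemplate,
    cropped_points: np.ndarray,
    *,
    tolerance: float = 0.5,
    specimen_id: str = "",
) -> tuple[CropMask, int]:
    """Match an externally cropped cloud back to template points by nearest
    neighbour within ``tolerance`` mm; returns (mask, n_unmatched)."""
    tree = cKDTree(template.points)
    dist, idx = tree.query(np.asarray(cropped_points, dtype=np.float64).reshape(-1, 3))
    matched = dist <= tolerance
    n_unmatched = int((~matched).sum())
    if n_unmatched:
        warnings.warn(
            f"{n_unmatched} cropped points had no template point within "
            f"{tolerance} mm and were rejected"
        )
    retained = np.zeros(template.n_points, dtype=bool)
    retained[idx[matched]] = True
    if not retained.any():
        raise EmptyCropError("empty crop: no cropped point matched the template")
    return (
        CropMask(specimen_id=specimen_id, template_id=template.template_id,
                 retained=retained),
        n_unmatched,
    )


def superimpose(masks: Sequence[CropMask]) -> HeatmapField:
    """Stack crop masks into a per-point overlap count field."""
    if not masks:
        raise ValidationError("need at least one crop mask")
    template_ids = {m.template_id for m in masks}
    if len(template_ids) != 1:
        raise ValidationError(f"masks reference mixed templates: {sorted(template_ids)}")
    counts = np.sum([m.retained.astype(np.int64) for m in masks], axis=0)
    return HeatmapField(
        template_id=masks[0].template_id,
        counts=counts,
        n_specimens=len(masks),
    )


def mne_report(
    store: AssemblageStore, masks_by_group: dict[tuple[str, str], Sequence[CropMask]]
) -> pd.DataFrame:
    """One row per (element, side) group with specimen count and MNE."""
    rows = []
    for (element, side), masks in sorted(masks_by_group.items()):
        if not masks:
            warnings.warn(f"empty group ({element}, {side}) omitted")
            continue
        field = superimpose(list(masks))
        rows.append(
            {
                "element": element,
                "side": side,
                "n_specimens": field.n_specimens,
                "mne": field.mne,
            }
        )
    return pd.DataFrame(rows, columns=["element", "side", "n_specimens", "mne"])


def full_mask(template: BoneTemplate, specimen_id: str = "") -> CropMask:
    """Mask of a complete (uncropped) specimen."""
    return CropMask(
        specimen_id=specimen_id,
        template_id=template.template_id,
        retained=np.ones(template.n_points, dtype=bool),
    )


def max_interval_overlap(intervals: Iterable[tuple[float, float]]) -> int:
    """Analytic maximum stabbing count of half-open intervals [lo, hi)."""
    events: list[tuple[float, int]] = []
    for lo, hi in intervals:
        events.append((lo, 1))
        events.append((hi, -1))
    # closing before opening at equal coordinates keeps [a,b),[b,c) disjoint
    events.sort(key=lambda e: (e[0], e[1]))
    best = cur = 0
    for _, delta in events:
        cur += delta
        best = max(best, cur)
    return best
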