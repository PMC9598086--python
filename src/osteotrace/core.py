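"""Core data model: canonical bone templates, mark records, specimens and the
in-memory assemblage store.

Coordinate convention: templates live in a canonical frame with the centroid at
the origin, x = proximo-distal axis (increasing distal -> proximal), y =
medio-lateral axis, z = cranio-caudal axis, all in millimetres.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateCloudError,
    OffTemplateError,
    UnknownFilterError,
    ValidationError,
)

ELEMENTS = ("femur", "tibia", "humerus", "radius", "metacarpal", "metatarsal")
SIDES = ("left", "right")
MARK_TYPES = ("pit", "score", "cut", "percussion")
LINEAR_TYPES = ("score", "cut")
PUNCTUAL_TYPES = ("pit", "percussion")
FRACTURE_STATES = ("green", "dry", "unknown")

#: minimum lambda1/lambda2 eigenvalue ratio for a cloud to have a dominant axis
AXIS_RATIO_MIN = 1.5

#: default bounding-box expansion (mm) when validating mark positions
DEFAULT_BBOX_TOL = 5.0


@dataclass
class BoneTemplate:
    """Canonical-frame point cloud of one skeletal element."""

    template_id: str
    element: str
    side: str
    size_class: int
    points: np.ndarray  # (n, 3) float64, mm
    length: float  # inter-epiphyseal extent along x, mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.element not in ELEMENTS:
            raise ValidationError(f"unknown element {self.element!r}; valid: {ELEMENTS}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}; valid: {SIDES}")
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("points must be an (n, 3) array")
        if len(self.points) < 100:
            raise ValidationError("template needs >= 100 points")
        span = float(self.points[:, 0].max() - self.points[:, 0].min())
        if self.length <= 0 or abs(span - self.length) > 1e-6:
            raise ValidationError(
                f"length {self.length} inconsistent with x span {span}"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        return self.points.min(axis=0), self.points.max(axis=0)

    def normalized_x(self, x: np.ndarray | float) -> np.ndarray | float:
        """Map absolute x (mm) to the [0, 1] proximo-distal fraction."""
        x0 = self.points[:, 0].min()
        return (x - x0) / self.length


@dataclass
class MarkRecord:
    """One bone surface modification.

    Linear types (score, cut) carry two endpoints and their position is the
    midpoint; punctual types (pit, percussion) carry a position only.
    """

    mark_id: str
    specimen_id: str
    template_id: str
    mark_type: str
    position: np.ndarray  # (3,) mm
    endpoints: np.ndarray | None = None  # (2, 3) mm or None

    def __post_init__(self) -> None:
        if self.mark_type not in MARK_TYPES:
            raise ValidationError(
                f"unknown mark type {self.mark_type!r}; valid: {MARK_TYPES}"
            )
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        if self.endpoints is not None:
            self.endpoints = np.asarray(self.endpoints, dtype=np.float64).reshape(2, 3)
        if self.mark_type in PUNCTUAL_TYPES:
            if self.endpoints is not None:
                raise ValidationError("endpoints not allowed for punctual mark types")
        else:
            if self.endpoints is None:
                raise ValidationError("endpoints required for linear mark types")
            if np.allclose(self.endpoints[0], self.endpoints[1]):
                raise ValidationError("linear mark endpoints must be distinct")
            mid = self.endpoints.mean(axis=0)
            if np.abs(self.position - mid).max() > 1e-9:
                raise ValidationError("position must equal endpoint midpoint")

    @property
    def is_linear(self) -> bool:
        return self.mark_type in LINEAR_TYPES


@dataclass
class SpecimenRecord:
    specimen_id: str
    site: str
    taxon: str
    element: str
    side: str
    size_class: int
    age: str = "unknown"
    fracture_state: str = "unknown"
    shaft_circumference_type: str = "unknown"
    template_id: str | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValidationError(f"unknown element {self.element!r}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")
        if self.fracture_state not in FRACTURE_STATES:
            raise ValidationError(f"unknown fracture state {self.fracture_state!r}")


QUERY_KEYS = ("element", "side", "mark_type", "site", "specimen", "size_class")


class AssemblageStore:
    """In-memory registry of templates, specimens, marks and crop masks.

    Mutating operations are appended to a provenance log; queries never
    mutate. Mark ids are zero-padded sequential so stores are reproducible.
    """

    def __init__(self) -> None:
        self.templates: dict[str, BoneTemplate] = {}
        self.specimens: dict[str, SpecimenRecord] = {}
        self.marks: dict[str, MarkRecord] = {}
        self.crop_masks: dict[str, Any] = {}
        self.provenance: list[dict[str, Any]] = []
        self._mark_counter = 0

    # -- provenance -------------------------------------------------------
    def _log(self, operation: str, **params: Any) -> None:
        self.provenance.append(
            {
                "operation": operation,
                "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
                "parameters": params,
            }
        )

    # -- mutators ---------------------------------------------------------
    def add_template(self, template: BoneTemplate) -> None:
        self.templates[template.template_id] = template
        self._log("add_template", template_id=template.template_id)

    def add_specimen(self, specimen: SpecimenRecord) -> None:
        if specimen.specimen_id in self.specimens:
            raise ValidationError(f"duplicate specimen id {specimen.specimen_id!r}")
        if specimen.template_id is not None:
            tpl = self.templates.get(specimen.template_id)
            if tpl is None:
                raise ValidationError(
                    f"specimen references unknown template {specimen.template_id!r}"
                )
            if (tpl.element, tpl.side) != (specimen.element, specimen.side):
                raise ValidationError(
                    "specimen element/side inconsistent with its template"
                )
        self.specimens[specimen.specimen_id] = specimen
        self._log("add_specimen", specimen_id=specimen.specimen_id)

    def next_mark_id(self) -> str:
        self._mark_counter += 1
        return f"M{self._mark_counter:06d}"

    def add_crop_mask(self, mask: Any) -> None:
        self.crop_masks[mask.specimen_id] = mask
        self._log("add_crop_mask", specimen_id=mask.specimen_id)

    # -- queries ----------------------------------------------------------
    def template_for_specimen(self, specimen_id: str) -> BoneTemplate:
        spec = self.specimens[specimen_id]
        if spec.template_id is None:
            raise ValidationError(f"specimen {specimen_id!r} has no template")
        return self.templates[spec.template_id]


def canonicalize_template(
    raw_points: Sequence[Sequence[float]] | np.ndarray,
    element: str,
    side: str,
    *,
    size_class: int = 3,
    template_id: str = "T000001",
    axis_ratio_min: float = AXIS_RATIO_MIN,
) -> BoneTemplate:
    """Rigidly transform a raw cloud into the canonical anatomical frame.

    The principal axes of the point covariance become x >= y >= z by
    explained variance, the centroid moves to the origin, and axis signs are
    fixed deterministically (largest-magnitude component of each of the first
    two eigenvectors positive; z completes a right-handed frame).

    Raises
    ------
    DegenerateCloudError
        If the covariance has rank < 3 or lambda1/lambda2 < ``axis_ratio_min``
        (no dominant proximo-distal axis).
    """
    pts = np.asarray(raw_points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError("raw_points must be (n, 3)")
    if len(pts) < 100:
        raise ValidationError("need >= 100 points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[2] <= 0 or evals[2] < 1e-12 * evals[0]:
        raise DegenerateCloudError("degenerate cloud: covariance rank < 3")
    if evals[0] / evals[1] < axis_ratio_min:
        raise DegenerateCloudError(
            "degenerate cloud: no dominant axis "
            f"(ratio {evals[0] / evals[1]:.3f} < {axis_ratio_min})"
        )
    # deterministic sign fix, then right-handed completion
    ex, ey = evecs[:, 0], evecs[:, 1]
    if ex[np.argmax(np.abs(ex))] < 0:
        ex = -ex
    if ey[np.argmax(np.abs(ey))] < 0:
        ey = -ey
    ez = np.cross(ex, ey)
    rot = np.column_stack([ex, ey, ez])
    canonical = centered @ rot
    canonical -= canonical.mean(axis=0)
    length = float(canonical[:, 0].max() - canonical[:, 0].min())
    return BoneTemplate(
        template_id=template_id,
        element=element,
        side=side,
        size_class=size_class,
        points=canonical,
        length=length,
    )


def register_mark(
    store: AssemblageStore,
    specimen_id: str,
    mark_type: str,
    position: Sequence[float] | None = None,
    endpoints: Sequence[Sequence[float]] | None = None,
    *,
    bbox_tol: float = DEFAULT_BBOX_TOL,
) -> MarkRecord:
    """Validate and persist one mark; linear marks derive position from the
    endpoint midpoint."""
    if specimen_id not in store.specimens:
        raise ValidationError(f"unknown specimen {specimen_id!r}")
    template = store.template_for_specimen(specimen_id)

    if mark_type in PUNCTUAL_TYPES:
        if endpoints is not None:
            raise ValidationError("endpoints not allowed for punctual mark types")
        if position is None:
            raise ValidationError("position required for punctual mark types")
        pos = np.asarray(position, dtype=np.float64)
        ep = None
    elif mark_type in LINEAR_TYPES:
        if endpoints is None:
            raise ValidationError("endpoints required for linear mark types")
        ep = np.asarray(endpoints, dtype=np.float64).reshape(2, 3)
        pos = ep.mean(axis=0)
        if position is not None and np.abs(np.asarray(position) - pos).max() > 1e-9:
            raise ValidationError("supplied position disagrees with endpoint midpoint")
    else:
        raise ValidationError(f"unknown mark type {mark_type!r}; valid: {MARK_TYPES}")

    lo, hi = template.bbox
    if np.any(pos < lo - bbox_tol) or np.any(pos > hi + bbox_tol):
        raise OffTemplateError(
            f"off-template mark: position {pos.tolist()} outside expanded bbox"
        )
    record = MarkRecord(
        mark_id=store.next_mark_id(),
        specimen_id=specimen_id,
        template_id=template.template_id,
        mark_type=mark_type,
        position=pos,
        endpoints=ep,
    )
    store.marks[record.mark_id] = record
    store._log("register_mark", mark_id=record.mark_id, mark_type=mark_type)
    return record


def query_marks(
    store: AssemblageStore, filters: Mapping[str, Any] | None = None, **kw: Any
) -> list[MarkRecord]:
    """Return marks matching the conjunction of all filters, ordered by id.

    Valid filter keys: element, side, mark_type, site, specimen, size_class.
    """
    f: dict[str, Any] = dict(filters or {})
    f.update(kw)
    unknown = set(f) - set(QUERY_KEYS)
    if unknown:
        raise UnknownFilterError(
            f"unknown filter key(s) {sorted(unknown)}; valid keys: {list(QUERY_KEYS)}"
        )
    out = []
    for mark in store.marks.values():
        spec = store.specimens[mark.specimen_id]
        if "mark_type" in f and mark.mark_type != f["mark_type"]:
            continue
        if "specimen" in f and mark.specimen_id != f["specimen"]:
            continue
        if "element" in f and spec.element != f["element"]:
            continue
        if "side" in f and spec.side != f["side"]:
            continue
        if "site" in f and spec.site != f["site"]:
            continue
        if "size_class" in f and spec.size_class != f["size_class"]:
            continue
        out.append(mark)
    return sorted(out, key=lambda m: m.mark_id)


def marks_positions(marks: Iterable[MarkRecord]) -> np.ndarray:
    """Stack mark positions into an (n, 3) array (linear marks: midpoints)."""
    arr = [m.position for m in marks]
    return np.asarray(arr, dtype=np.float64).reshape(-1, 3)
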