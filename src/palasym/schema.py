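"""Domain types for palatal landmark configurations.

The canonical template has 41 points: 5 fixed anatomical landmarks, 12 curve
semilandmarks (4 per cervical curve left/right plus 4 on the median palatine
suture) and 24 surface semilandmarks (12 per hemi-palate).  Bilateral
structure is encoded as an involutive pairing ``pair(pair(l)) = l`` with
midline points as fixed points of the involution; the pairing is what makes
reflection-with-relabelling, and hence object-symmetry analysis, well
defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PointDef",
    "CurveDef",
    "TemplateSchema",
    "LandmarkConfiguration",
    "PopulationDataset",
    "SchemaError",
    "default_palate_schema",
    "validate_configuration",
    "AGE_GROUPS",
]

#: Canonical age-group labels, youngest (deciduous dentition) to oldest.
AGE_GROUPS = ("I", "II", "III", "IV", "V", "VI")

_ROLES = ("fixed", "curve", "surface")
_SIDES = ("left", "right", "midline")


class SchemaError(ValueError):
    """Raised when a template schema violates its structural invariants."""


@dataclass(frozen=True)
class PointDef:
    """One template point: identity, role and bilateral pairing.

    Ids are 1-based and stable: every downstream table indexes landmarks by
    these numbers.  ``pair_id`` equals ``id`` exactly for midline points.
    """

    id: int
    name: str
    role: str  # fixed | curve | surface
    side: str  # left | right | midline
    pair_id: int
    curve_id: str | None = None


@dataclass(frozen=True)
class CurveDef:
    """An open curve: two fixed anchor landmarks and its ordered semilandmarks."""

    curve_id: str
    anchor_ids: tuple[int, int]
    semilandmark_ids: tuple[int, ...]


@dataclass(frozen=True)
class TemplateSchema:
    """Ordered template of landmark definitions with bilateral pairing.

    Provides the 0-based permutation used for relabelling after reflection
    and the bookkeeping (roles, sides, curves) the sliding and asymmetry
    machinery needs.
    """

    points: tuple[PointDef, ...]
    midplane_landmark_ids: tuple[int, ...]
    curves: tuple[CurveDef, ...] = ()

    # -- basic accessors ---------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(p.id for p in self.points)

    def point(self, point_id: int) -> PointDef:
        try:
            return self._by_id[point_id]
        except KeyError:
            raise KeyError(f"no point with id {point_id}") from None

    def pair(self, point_id: int) -> int:
        """Bilateral partner of ``point_id`` (itself for midline points)."""
        return self.point(point_id).pair_id

    @property
    def _by_id(self) -> dict[int, PointDef]:
        return {p.id: p for p in self.points}

    def index_of(self, point_id: int) -> int:
        return self.ids.index(point_id)

    # -- derived arrays ----------------------------------------------------

    @property
    def pair_permutation(self) -> np.ndarray:
        """0-based row permutation implementing the relabelling step."""
        pos = {p.id: i for i, p in enumerate(self.points)}
        return np.array([pos[p.pair_id] for p in self.points], dtype=int)

    @property
    def midline_mask(self) -> np.ndarray:
        mid = set(self.midplane_landmark_ids)
        return np.array([p.id in mid for p in self.points], dtype=bool)

    @property
    def roles(self) -> np.ndarray:
        return np.array([p.role for p in self.points])

    def role_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in _ROLES}
        for p in self.points:
            counts[p.role] += 1
        return counts

    def ids_with_role(self, role: str) -> tuple[int, ...]:
        return tuple(p.id for p in self.points if p.role == role)

    def curve(self, curve_id: str) -> CurveDef:
        for c in self.curves:
            if c.curve_id == curve_id:
                return c
        raise KeyError(f"no curve {curve_id!r}")

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`SchemaError` listing
        every violation found."""
        problems: list[str] = []
        ids = [p.id for p in self.points]
        if len(set(ids)) != len(ids):
            problems.append("point ids are not unique")
        by_id = {p.id: p for p in self.points}
        for p in self.points:
            if p.role not in _ROLES:
                problems.append(f"point {p.id}: unknown role {p.role!r}")
            if p.side not in _SIDES:
                problems.append(f"point {p.id}: unknown side {p.side!r}")
            q = by_id.get(p.pair_id)
            if q is None:
                problems.append(f"point {p.id}: pair_id {p.pair_id} not in schema")
                continue
            if q.pair_id != p.id:
                problems.append(
                    f"pairing is not an involution at {p.id} -> {p.pair_id} -> {q.pair_id}"
                )
            if (p.side == "midline") != (p.pair_id == p.id):
                problems.append(
                    f"point {p.id}: side={p.side} inconsistent with pair_id={p.pair_id}"
                )
            if p.side != "midline":
                if q.role != p.role:
                    problems.append(f"pair {p.id}/{q.id}: mismatched roles")
                opposite = {"left": "right", "right": "left"}.get(p.side)
                if q.side != opposite:
                    problems.append(f"pair {p.id}/{q.id}: sides {p.side}/{q.side}")
        mid_from_points = {p.id for p in self.points if p.side == "midline"}
        if set(self.midplane_landmark_ids) != mid_from_points:
            problems.append(
                "midplane_landmark_ids do not match the midline-side points"
            )
        for c in self.curves:
            for a in c.anchor_ids:
                if a not in by_id:
                    problems.append(f"curve {c.curve_id}: anchor {a} missing")
            for s in c.semilandmark_ids:
                p = by_id.get(s)
                if p is None or p.role != "curve":
                    problems.append(
                        f"curve {c.curve_id}: semilandmark {s} missing or not role=curve"
                    )
                elif p.curve_id != c.curve_id:
                    problems.append(
                        f"point {s}: curve_id {p.curve_id!r} != {c.curve_id!r}"
                    )
        # paired curve semilandmarks must sit on mirrored curves
        for p in self.points:
            if p.role == "curve" and p.side == "left":
                q = by_id.get(p.pair_id)
                if q is not None and q.curve_id == p.curve_id:
                    problems.append(
                        f"pair {p.id}/{q.id}: both on curve {p.curve_id!r}"
                    )
        if problems:
            raise SchemaError("; ".join(problems))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "midplane_landmark_ids": list(self.midplane_landmark_ids),
            "points": [
                {
                    "id": p.id,
                    "name": p.name,
                    "role": p.role,
                    "side": p.side,
                    "pair_id": p.pair_id,
                    "curve_id": p.curve_id,
                }
                for p in self.points
            ],
            "curves": [
                {
                    "curve_id": c.curve_id,
                    "anchor_ids": list(c.anchor_ids),
                    "semilandmark_ids": list(c.semilandmark_ids),
                }
                for c in self.curves
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TemplateSchema":
        doc = json.loads(text)
        points = tuple(
            PointDef(
                id=int(d["id"]),
                name=d["name"],
                role=d["role"],
                side=d["side"],
                pair_id=int(d["pair_id"]),
                curve_id=d.get("curve_id"),
            )
            for d in doc["points"]
        )
        curves = tuple(
            CurveDef(
                curve_id=d["curve_id"],
                anchor_ids=tuple(int(a) for a in d["anchor_ids"]),
                semilandmark_ids=tuple(int(s) for s in d["semilandmark_ids"]),
            )
            for d in doc.get("curves", ())
        )
        schema = cls(
            points=points,
            midplane_landmark_ids=tuple(int(i) for i in doc["midplane_landmark_ids"]),
            curves=curves,
        )
        schema.validate()
        return schema


def _build_default_schema() -> TemplateSchema:
    """Construct the canonical 41-point palatal template schema.

    Numbering follows the standard configuration: fixed landmarks 1-5
    (Incisor, Ento-left, Ento-right, Post-foramen, Middle), cervical-curve
    semilandmarks 6-9 (left) and 10-13 (right), surface semilandmarks 14-25
    (right) and 26-37 (left, paired in order), median-suture curve
    semilandmarks 38-41.  Midline set: {1, 4, 5, 38, 39, 40, 41}.
    """
    pts: list[PointDef] = []
    pts.append(PointDef(1, "Incisor", "fixed", "midline", 1))
    pts.append(PointDef(2, "Ento-left", "fixed", "left", 3))
    pts.append(PointDef(3, "Ento-right", "fixed", "right", 2))
    pts.append(PointDef(4, "Post-foramen", "fixed", "midline", 4))
    pts.append(PointDef(5, "Middle", "fixed", "midline", 5))
    for i, lid in enumerate(range(6, 10)):
        pts.append(
            PointDef(lid, "Curve sml left", "curve", "left", lid + 4, "curve_left")
        )
    for i, lid in enumerate(range(10, 14)):
        pts.append(
            PointDef(lid, "Curve sml right", "curve", "right", lid - 4, "curve_right")
        )
    for lid in range(14, 26):
        pts.append(PointDef(lid, "Surface sml right", "surface", "right", lid + 12))
    for lid in range(26, 38):
        pts.append(PointDef(lid, "Surface sml left", "surface", "left", lid - 12))
    for lid in range(38, 42):
        pts.append(
            PointDef(lid, "Curve sml middle", "curve", "midline", lid, "curve_middle")
        )
    curves = (
        CurveDef("curve_left", (1, 2), (6, 7, 8, 9)),
        CurveDef("curve_right", (1, 3), (10, 11, 12, 13)),
        CurveDef("curve_middle", (4, 5), (38, 39, 40, 41)),
    )
    schema = TemplateSchema(
        points=tuple(pts),
        midplane_landmark_ids=(1, 4, 5, 38, 39, 40, 41),
        curves=curves,
    )
    schema.validate()
    return schema


def default_palate_schema() -> TemplateSchema:
    """Return the canonical 41-point palatal template schema.

    The schema is also shipped as a JSON package resource
    (``palasym/data/palate_template_schema.json``) for external tools; the
    in-code construction here is the source of truth and the resource is
    checked against it in the test suite.
    """
    return _build_default_schema()


@dataclass
class LandmarkConfiguration:
    """One individual's landmark coordinates plus metadata.

    Coordinates are in mm for raw input and dimensionless Procrustes units
    after superimposition.  ``is_reflected_copy`` marks the reflected and
    relabelled copy used in object-symmetry analysis.
    """

    individual_id: str
    coordinates: np.ndarray  # (n_points, 3) float
    age_group: str = ""
    sex: str = ""  # M | F | ND | ""
    collection: str = ""
    is_reflected_copy: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            individual_id=self.individual_id,
            coordinates=self.coordinates.copy(),
            age_group=self.age_group,
            sex=self.sex,
            collection=self.collection,
            is_reflected_copy=self.is_reflected_copy,
        )


@dataclass
class PopulationDataset:
    """A set of configurations sharing one template schema."""

    schema: TemplateSchema
    configurations: list[LandmarkConfiguration]
    provenance: str = ""
    ground_truth: object | None = None

    def __len__(self) -> int:
        return len(self.configurations)

    def coordinate_stack(self) -> np.ndarray:
        """(n_config, n_points, 3) array in dataset order."""
        return np.stack([c.coordinates for c in self.configurations])

    def originals(self) -> list[LandmarkConfiguration]:
        return [c for c in self.configurations if not c.is_reflected_copy]

    def validate(self) -> list[str]:
        problems: list[str] = []
        seen: set[str] = set()
        for c in self.configurations:
            problems += [
                f"{c.individual_id}: {v}"
                for v in validate_configuration(c, self.schema)
            ]
            if not c.is_reflected_copy:
                if c.individual_id in seen:
                    problems.append(f"duplicate individual_id {c.individual_id!r}")
                seen.add(c.individual_id)
        return problems


def validate_configuration(
    config: LandmarkConfiguration, schema: TemplateSchema
) -> list[str]:
    """Report structural violations of a configuration against a schema.

    Returns a list of human-readable violation strings; an empty list means
    the configuration is valid.
    """
    problems: list[str] = []
    coords = np.asarray(config.coordinates)
    if coords.ndim != 2 or coords.shape[1] != 3:
        problems.append(f"coordinates have shape {coords.shape}, expected (n, 3)")
        return problems
    if coords.shape[0] != schema.n_points:
        problems.append(
            f"configuration has {coords.shape[0]} rows, schema expects {schema.n_points}"
        )
    if not np.all(np.isfinite(coords)):
        problems.append("coordinates contain non-finite values")
    else:
        centered = coords - coords.mean(axis=0)
        if float(np.sqrt((centered**2).sum())) <= 0.0:
            problems.append("zero centroid size (all points identical)")
    return problems
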