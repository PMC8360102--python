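"""Synthetic bilateral palate-like populations with known asymmetry.

The generator builds an analytic stand-in for a palatal vault — a
triangulated half-ellipsoid dome with two lateral alveolar-ridge polylines
and a median-suture polyline — places the 41-point template on it
(semilandmarks at 20% arc-length spacing along each curve, surface
semilandmarks on a parametric grid of the right hemi-dome mirrored to the
left), and draws individuals as

    group mean (template x growth scale, mild vault deepening)
    + symmetric individual deviation
    + 1/2 antisym(group DA field) + 1/2 antisym(individual FA draw)
    + isotropic landmark measurement error,

followed by a random rigid motion and scale jitter so the superimposition
machinery is genuinely exercised.  ``antisym(v) = (v - mirror_relabel(v))/2``
projects onto the asymmetric subspace, so the injected asymmetry of an
individual is exactly ``antisym(da_field) + antisym(fa draw)`` in template
(mm) space — the ground truth serialized with every dataset.

All perturbations default to a small fraction of centroid size so the
Procrustes projection stays near-linear and ground-truth comparisons are
meaningful; larger regimes trigger a warning.  The measurement-error
default (0.05 mm) is the accuracy of a structured-light surface scanner.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import special_ortho_group

from .io import GeometryBundle
from .schema import (
    AGE_GROUPS,
    LandmarkConfiguration,
    PopulationDataset,
    TemplateSchema,
    default_palate_schema,
)
from .semilandmarks import reflect_coords

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "make_palate_geometry",
    "simulate_population",
    "six_group_design",
    "antisymmetrize",
    "symmetrize",
]

# Table-style study design: per-group (collection, sex, count) cells.
_DESIGN_CELLS: dict[str, tuple[tuple[str, str, int], ...]] = {
    "I": (("Bologna", "M", 3), ("Bologna", "F", 1), ("Florence", "F", 1)),
    "II": (("Bologna", "M", 7), ("Bologna", "F", 4), ("Florence", "M", 1), ("Florence", "F", 2)),
    "III": (("Bologna", "M", 4), ("Bologna", "F", 2), ("Florence", "M", 4), ("Florence", "F", 1)),
    "IV": (
        ("Bologna", "M", 5),
        ("Bologna", "F", 6),
        ("Florence", "M", 6),
        ("Florence", "F", 8),
        ("Florence", "ND", 1),
    ),
    "V": (("Bologna", "M", 13), ("Bologna", "F", 13), ("Florence", "M", 29), ("Florence", "F", 27)),
    "VI": (("Bologna", "M", 14), ("Bologna", "F", 15), ("Florence", "M", 5), ("Florence", "F", 11)),
}

#: Landmark ids receiving the directional displacement, per age group:
#: posterior (ento-molar) asymmetry in the youngest and school-age groups,
#: anterior surface asymmetry from early childhood and again in seniors.
_DA_TARGET_IDS: dict[str, tuple[int, ...]] = {
    "I": (2, 3),
    "II": (14, 15, 16),
    "III": (2, 3),
    "IV": (14, 15),
    "V": (14, 15),
    "VI": (14, 15, 16),
}


@dataclass
class SimulationSpec:
    """Parameters of the synthetic population.

    Defaults encode the six-age-group skeletal-collection design
    (n = 5, 14, 11, 26, 82, 45; 183 individuals in total) with growth as
    isotropic scaling plus mild vault deepening, group-specific directional
    displacement fields of a few tenths of a millimetre on a ~50 mm dome,
    individual fluctuating-asymmetry noise, symmetric individual variation,
    and 0.05 mm measurement error.
    """

    n_per_group: tuple[int, ...] = (5, 14, 11, 26, 82, 45)
    group_names: tuple[str, ...] = AGE_GROUPS
    semi_axes: tuple[float, float, float] = (25.0, 30.0, 12.0)  # mm: width, length, depth
    growth_scale: tuple[float, ...] = (0.55, 0.70, 0.85, 0.95, 1.0, 1.0)
    vault_deepen: tuple[float, ...] = (0.92, 0.95, 0.98, 1.0, 1.0, 1.0)
    da_magnitude: tuple[float, ...] = (0.15, 0.45, 0.25, 0.20, 0.20, 0.35)  # mm, ||field||_F
    sigma_fa: float = 0.15  # mm per coordinate, antisymmetric individual noise
    sigma_sym: float = 0.5  # mm per coordinate, symmetric individual variation
    sigma_noise: float = 0.05  # mm, isotropic landmark measurement error
    sex_effect: float = 0.0  # mm, optional symmetric M-vs-F displacement
    da_fields: dict[str, np.ndarray] | None = None  # override (41, 3) mm fields
    rigid_motion: bool = True
    scale_jitter: float = 0.03  # relative, uniform +/-
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.group_names)
        for name in ("n_per_group", "growth_scale", "vault_deepen", "da_magnitude"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have {k} entries")
        for s in (self.sigma_fa, self.sigma_sym, self.sigma_noise):
            if s < 0:
                raise ValueError("sigmas must be >= 0")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass
class GroundTruth:
    """Generator-space ground truth serialized alongside a dataset."""

    spec: SimulationSpec
    template: np.ndarray  # (41, 3) mm
    group_means: dict[str, np.ndarray]
    da_fields: dict[str, np.ndarray]  # antisymmetrized, mm
    true_da_norm: dict[str, float]  # ||antisym field||_F, mm
    individual_asymmetry: dict[str, np.ndarray]  # id -> (41, 3) mm

    def to_json(self) -> str:
        doc = {
            "spec": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.spec).items()
                if k != "da_fields"
            },
            "template": self.template.tolist(),
            "group_means": {k: v.tolist() for k, v in self.group_means.items()},
            "da_fields": {k: v.tolist() for k, v in self.da_fields.items()},
            "true_da_norm": self.true_da_norm,
            "individual_asymmetry": {
                k: v.tolist() for k, v in self.individual_asymmetry.items()
            },
        }
        return json.dumps(doc)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def six_group_design(seed: int = 0, **overrides) -> SimulationSpec:
    """The six-age-group study design preset (183 individuals in total)."""
    return SimulationSpec(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# symmetric/antisymmetric projections
# ---------------------------------------------------------------------------


def antisymmetrize(v: np.ndarray, schema: TemplateSchema) -> np.ndarray:
    """Projection onto the asymmetric subspace: (v - mirror_relabel(v)) / 2."""
    return (v - reflect_coords(v, schema)) / 2.0


def symmetrize(v: np.ndarray, schema: TemplateSchema) -> np.ndarray:
    """Projection onto the symmetric subspace: (v + mirror_relabel(v)) / 2."""
    return (v + reflect_coords(v, schema)) / 2.0


def _similarity_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity tangent space at ``base``:
    3 translations, 3 infinitesimal rotations, 1 scaling (7 x 3n)."""
    n = base.shape[0]
    centered = base - base.mean(axis=0)
    gens = []
    for j in range(3):
        e = np.zeros((n, 3))
        e[:, j] = 1.0
        gens.append(e)
    for j in range(3):
        axis = np.zeros(3)
        axis[j] = 1.0
        gens.append(np.cross(np.broadcast_to(axis, (n, 3)), centered))
    gens.append(centered)
    G = np.stack([g.ravel() for g in gens], axis=1)
    Q, _ = np.linalg.qr(G)
    return Q


def project_to_shape_space(field: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Remove the components of a displacement field that a similarity
    transform of ``base`` could absorb (net translation, rotation, scaling).

    Superimposition removes exactly those components, so only the projected
    part of an injected field is recoverable as shape asymmetry; the
    generator injects fields that are already pure shape displacements and
    reports their norms as ground truth.
    """
    Q = _similarity_basis(base)
    v = np.asarray(field, dtype=float).ravel()
    return (v - Q @ (Q.T @ v)).reshape(field.shape)


# ---------------------------------------------------------------------------
# geometry and template
# ---------------------------------------------------------------------------


def _dome_z(x: np.ndarray, y: np.ndarray, axes: tuple[float, float, float]) -> np.ndarray:
    a, b, c = axes
    r2 = (x / a) ** 2 + (y / b) ** 2
    return -c * np.sqrt(np.clip(1.0 - r2, 0.0, None))


def _rim_point(t: np.ndarray, axes: tuple[float, float, float]) -> np.ndarray:
    a, b, c = axes
    t = np.atleast_1d(t)
    z = -0.15 * c * (1.0 - np.sin(t))
    return np.column_stack([a * np.cos(t), b * np.sin(t), z])


def _dome_mesh(axes: tuple[float, float, float], n_rings: int = 20, n_sectors: int = 40):
    a, b, _ = axes
    thetas = 2.0 * np.pi * np.arange(n_sectors) / n_sectors
    verts = [np.array([0.0, 0.0, _dome_z(np.array(0.0), np.array(0.0), axes)])]
    for i in range(1, n_rings + 1):
        r = i / n_rings
        x = a * r * np.cos(thetas)
        y = b * r * np.sin(thetas)
        z = _dome_z(x, y, axes)
        verts.append(np.column_stack([x, y, z]))
    vertices = np.vstack(verts)

    def vid(ring: int, sector: int) -> int:
        return 1 + (ring - 1) * n_sectors + (sector % n_sectors)

    faces = []
    for j in range(n_sectors):
        faces.append([0, vid(1, j), vid(1, j + 1)])
    for i in range(1, n_rings):
        for j in range(n_sectors):
            v00, v01 = vid(i, j), vid(i, j + 1)
            v10, v11 = vid(i + 1, j), vid(i + 1, j + 1)
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    return vertices, np.array(faces, dtype=int)


def _points_at_arclength(polyline: np.ndarray, fractions) -> np.ndarray:
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    out = []
    for f in np.atleast_1d(fractions):
        target = f * total
        out.append(
            [np.interp(target, s, polyline[:, d]) for d in range(3)]
        )
    return np.array(out)


def make_palate_geometry(
    spec: SimulationSpec | None = None,
    schema: TemplateSchema | None = None,
    n_curve_samples: int = 400,
) -> tuple[GeometryBundle, np.ndarray]:
    """Analytic palate stand-in: dome mesh, ridge/suture polylines, and the
    41-point template placed on them.

    Curve semilandmarks sit at 20/40/60/80% of each curve's arc length;
    surface semilandmarks lie on a regular parametric grid of the right
    hemi-dome, projected onto the mesh, with the left side the exact mirror
    image.  Returns ``(geometry, template_coords)`` with the template in a
    frame whose midsagittal plane is x = 0.
    """
    spec = spec or SimulationSpec()
    schema = schema or default_palate_schema()
    axes = spec.semi_axes
    a, b, c = axes

    vertices, faces = _dome_mesh(axes)
    t_left = np.linspace(np.pi / 2, 1.25 * np.pi, n_curve_samples)
    t_right = np.linspace(np.pi / 2, -0.25 * np.pi, n_curve_samples)
    curve_left = _rim_point(t_left, axes)
    curve_right = _rim_point(t_right, axes)
    y_mid = np.linspace(0.6 * b, -0.2 * b, n_curve_samples)
    curve_middle = np.column_stack(
        [np.zeros_like(y_mid), y_mid, _dome_z(np.zeros_like(y_mid), y_mid, axes)]
    )
    geometry = GeometryBundle(
        vertices=vertices,
        faces=faces,
        curves={
            "curve_left": curve_left,
            "curve_right": curve_right,
            "curve_middle": curve_middle,
        },
    )

    coords = np.zeros((schema.n_points, 3))

    def put(point_id: int, xyz) -> None:
        coords[schema.index_of(point_id)] = xyz

    put(1, curve_left[0])  # Incisor: shared anterior anchor of both ridge curves
    put(2, curve_left[-1])  # Ento-left
    put(3, curve_right[-1])  # Ento-right
    put(4, curve_middle[0])  # Post-foramen
    put(5, curve_middle[-1])  # Middle
    fracs = (0.2, 0.4, 0.6, 0.8)
    for cid, poly in (
        ("curve_left", curve_left),
        ("curve_right", curve_right),
        ("curve_middle", curve_middle),
    ):
        cdef = schema.curve(cid)
        pts = _points_at_arclength(poly, fracs)
        for lid, p in zip(cdef.semilandmark_ids, pts):
            put(lid, p)

    # right hemi-dome parametric grid, anterior to posterior rows
    xs = np.array([0.2, 0.45, 0.7]) * a
    ys = np.array([0.55, 0.25, -0.05, -0.35]) * b
    grid = np.array([[x, y, float(_dome_z(np.array(x), np.array(y), axes))] for y in ys for x in xs])
    from .semilandmarks import closest_point_on_mesh

    projected, _, _ = closest_point_on_mesh(grid, vertices, faces)
    right_ids = [p.id for p in schema.points if p.role == "surface" and p.side == "right"]
    for lid, p in zip(right_ids, projected):
        put(lid, p)
    for lid in right_ids:
        mirrored = coords[schema.index_of(lid)].copy()
        mirrored[0] *= -1.0
        put(schema.pair(lid), mirrored)
    return geometry, coords


def _default_da_field(
    group: str, base: np.ndarray, schema: TemplateSchema, magnitude: float
) -> np.ndarray:
    """Directional shape-displacement field with ||field||_F = magnitude.

    Antisymmetric by construction and orthogonal to the similarity tangent
    space at ``base``, so the whole injected norm lives in shape space.
    """
    field = np.zeros_like(base)
    for lid in _DA_TARGET_IDS[group]:
        field[schema.index_of(lid)] = (1.0, 0.0, 0.5)  # lateral shift + mild vertical
    anti = project_to_shape_space(antisymmetrize(field, schema), base)
    nrm = float(np.sqrt((anti**2).sum()))
    if nrm == 0 or magnitude == 0:
        return np.zeros_like(base)
    return anti * (magnitude / nrm)


def _assign_metadata(group: str, n: int) -> list[tuple[str, str]]:
    """(collection, sex) per individual: the design cells when n matches the
    preset, a balanced round-robin otherwise."""
    cells = _DESIGN_CELLS.get(group)
    if cells is not None and sum(c[-1] for c in cells) == n:
        out: list[tuple[str, str]] = []
        for coll, sex, count in cells:
            out.extend([(coll, sex)] * count)
        return out
    combos = [("Bologna", "M"), ("Florence", "F"), ("Bologna", "F"), ("Florence", "M")]
    return [combos[i % 4] for i in range(n)]


def simulate_population(
    spec: SimulationSpec | None = None,
    schema: TemplateSchema | None = None,
) -> PopulationDataset:
    """Draw a synthetic population; ground truth rides on the dataset.

    See the module docstring for the generative model.  The returned
    dataset contains originals only (no reflected copies); its
    ``ground_truth`` attribute is a :class:`GroundTruth`.
    """
    spec = spec or SimulationSpec()
    schema = schema or default_palate_schema()
    rng = np.random.default_rng(spec.seed)
    geometry, template = make_palate_geometry(spec, schema)
    template_cs = float(np.sqrt(((template - template.mean(0)) ** 2).sum()))

    configs: list[LandmarkConfiguration] = []
    group_means: dict[str, np.ndarray] = {}
    da_fields: dict[str, np.ndarray] = {}
    true_da: dict[str, float] = {}
    indiv_asym: dict[str, np.ndarray] = {}

    for g_idx, (group, n) in enumerate(zip(spec.group_names, spec.n_per_group)):
        mean_k = template * spec.growth_scale[g_idx]
        mean_k = mean_k.copy()
        mean_k[:, 2] *= spec.vault_deepen[g_idx]
        group_means[group] = mean_k
        if spec.da_fields is not None and group in spec.da_fields:
            delta = project_to_shape_space(
                antisymmetrize(np.asarray(spec.da_fields[group], dtype=float), schema),
                mean_k,
            )
        else:
            delta = _default_da_field(group, mean_k, schema, spec.da_magnitude[g_idx])
        da_fields[group] = delta
        true_da[group] = float(np.sqrt((delta**2).sum()))
        if true_da[group] > 0.02 * template_cs:
            warnings.warn(
                f"group {group}: injected asymmetry exceeds 2% of centroid size; "
                "Procrustes linearity of ground-truth comparisons degrades",
                stacklevel=2,
            )
        meta = _assign_metadata(group, n)
        for j in range(n):
            iid = f"{group}_{j + 1:03d}"
            sym_dev = symmetrize(
                spec.sigma_sym * rng.normal(size=(schema.n_points, 3)), schema
            )
            phi = project_to_shape_space(
                antisymmetrize(
                    spec.sigma_fa * rng.normal(size=(schema.n_points, 3)), schema
                ),
                mean_k,
            )
            noise = spec.sigma_noise * rng.normal(size=(schema.n_points, 3))
            coll, sex = meta[j]
            sex_shift = np.zeros(3)
            if spec.sex_effect and sex == "M":
                sex_shift = np.array([0.0, spec.sex_effect, 0.0])
            coords = mean_k + sym_dev + 0.5 * delta + 0.5 * phi + noise + sex_shift
            indiv_asym[iid] = delta + phi
            if spec.rigid_motion:
                Rr = special_ortho_group.rvs(3, random_state=rng)
                s = 1.0 + rng.uniform(-spec.scale_jitter, spec.scale_jitter)
                t = rng.uniform(-10.0, 10.0, 3)
                coords = s * coords @ Rr + t
            configs.append(
                LandmarkConfiguration(
                    individual_id=iid,
                    coordinates=coords,
                    age_group=group,
                    sex=sex,
                    collection=coll,
                )
            )

    gt = GroundTruth(
        spec=spec,
        template=template,
        group_means=group_means,
        da_fields=da_fields,
        true_da_norm=true_da,
        individual_asymmetry=indiv_asym,
    )
    return PopulationDataset(
        schema=schema,
        configurations=configs,
        provenance=f"simulated (seed={spec.seed})",
        ground_truth=gt,
    )
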