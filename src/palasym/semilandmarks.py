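"""Thin-plate splines, bending-energy sliding, and mirroring utilities.

The 3D TPS kernel used here is U(r) = -r (the sign that makes the kernel
conditionally positive definite, so bending energy is nonnegative on the
subspace orthogonal to affine functions of the reference).  The bending
energy of a target Y relative to a reference is the quadratic form
trace(Y' B Y), where B is the upper-left block of the inverse TPS system
matrix; affine images of the reference have exactly zero energy.

Sliding relaxes semilandmarks along local tangent directions — one tangent
for curve semilandmarks (from the polyline), a tangent plane for surface
semilandmarks (from the mesh normal) — solving the linear least-squares
problem that minimises bending energy against the reference, then projects
the slid points back onto their curve or surface.  Fixed landmarks never
move, and a sliding pass whose projection step would raise the energy is
rolled back, so the reported energy trace is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import GeometryBundle, GeometryError
from .schema import LandmarkConfiguration, TemplateSchema

__all__ = [
    "TpsTransform",
    "SlidingResult",
    "TpsError",
    "tps_fit",
    "bending_energy_matrix",
    "slide_semilandmarks",
    "mirror_configuration",
    "reflect_coords",
    "midsagittal_frame",
    "to_midsagittal_frame",
    "complete_template_by_mirroring",
    "project_to_polyline",
    "polyline_tangents",
]


class TpsError(ValueError):
    """Singular thin-plate-spline system (e.g. duplicated reference points)."""


@dataclass
class TpsTransform:
    """An exact TPS interpolant from ``reference`` onto a target."""

    reference: np.ndarray  # (n, 3)
    affine: np.ndarray  # (4, 3): row 0 translation, rows 1-3 linear part
    weights: np.ndarray  # (n, 3) warp weights
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        K = -cdist(points, self.reference)
        P = np.hstack([np.ones((len(points), 1)), points])
        return K @ self.weights + P @ self.affine


@dataclass
class SlidingResult:
    positions: np.ndarray  # (n_points, 3)
    bending_energy_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0


def _tps_system(reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    reference = np.asarray(reference, dtype=float)
    n = len(reference)
    if n < 5:
        raise TpsError("3D TPS needs at least 5 reference points")
    D = cdist(reference, reference)
    dup = np.argwhere((D < 1e-12) & ~np.eye(n, dtype=bool))
    if len(dup):
        pairs = sorted({tuple(sorted(t)) for t in dup.tolist()})
        raise TpsError(f"duplicated reference points at index pairs {pairs[:5]}")
    K = -D
    P = np.hstack([np.ones((n, 1)), reference])
    if np.linalg.matrix_rank(P) < 4:
        raise TpsError("reference points are coplanar; TPS system is singular")
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    return L, K, P


def tps_fit(reference: np.ndarray, target: np.ndarray) -> TpsTransform:
    """Fit the exact TPS interpolant mapping ``reference`` onto ``target``."""
    target = np.asarray(target, dtype=float)
    L, K, _ = _tps_system(reference)
    n = len(reference)
    if target.shape != (n, 3):
        raise ValueError(f"target must be ({n}, 3)")
    rhs = np.vstack([target, np.zeros((4, 3))])
    sol = np.linalg.solve(L, rhs)
    W = sol[:n]
    A = sol[n:]
    energy = float(np.trace(W.T @ K @ W))
    return TpsTransform(
        reference=np.asarray(reference, dtype=float),
        affine=A,
        weights=W,
        bending_energy=max(energy, 0.0) if energy > -1e-9 else energy,
    )


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Symmetric PSD matrix B with trace(Y' B Y) the bending energy of Y.

    B is the upper-left n x n block of the inverse TPS system matrix; its
    null space is spanned by [1, x, y, z] of the reference.
    """
    L, _, _ = _tps_system(reference)
    n = len(reference)
    Linv = np.linalg.inv(L)
    B = Linv[:n, :n]
    return (B + B.T) / 2.0


# ---------------------------------------------------------------------------
# geometry projection helpers
# ---------------------------------------------------------------------------


def project_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Nearest point on an ordered polyline for each query point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a  # (m, 3)
    denom = (ab**2).sum(axis=1)
    denom[denom == 0] = 1.0
    out = np.empty_like(points)
    for i, p in enumerate(points):
        t = ((p - a) * ab).sum(axis=1) / denom
        t = np.clip(t, 0.0, 1.0)
        cand = a + t[:, None] * ab
        d2 = ((cand - p) ** 2).sum(axis=1)
        out[i] = cand[np.argmin(d2)]
    return out


def polyline_tangents(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Unit tangent of the polyline at the segment nearest to each point.

    Central differences of neighbouring vertices are used at interior
    vertices; endpoints fall back to the one-sided segment direction.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = polyline[:-1]
    b = polyline[1:]
    ab = b - a
    denom = (ab**2).sum(axis=1)
    denom[denom == 0] = 1.0
    tangents = np.empty_like(points)
    for i, p in enumerate(points):
        t = ((p - a) * ab).sum(axis=1) / denom
        t = np.clip(t, 0.0, 1.0)
        cand = a + t[:, None] * ab
        d2 = ((cand - p) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        # central difference across the two segments sharing the nearest vertex
        lo = max(j - 1, 0)
        hi = min(j + 1, len(polyline) - 1)
        vec = polyline[hi] - polyline[lo]
        nrm = np.linalg.norm(vec)
        if nrm == 0:
            vec = ab[j]
            nrm = np.linalg.norm(vec)
        tangents[i] = vec / nrm
    return tangents


def closest_point_on_mesh(
    points: np.ndarray, vertices: np.ndarray, faces: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact nearest point on a triangle soup for each query point.

    Brute-force over faces (vectorised per query point), which is plenty for
    template-sized meshes; returns (closest, distance, face_index).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    A = vertices[faces[:, 0]]
    E0 = vertices[faces[:, 1]] - A  # triangle edges (Eberly's parametrisation)
    E1 = vertices[faces[:, 2]] - A
    a = (E0 * E0).sum(axis=1)
    b = (E0 * E1).sum(axis=1)
    c = (E1 * E1).sum(axis=1)
    det = np.maximum(a * c - b * b, 1e-300)
    closest = np.empty_like(points)
    dists = np.empty(len(points))
    face_idx = np.empty(len(points), dtype=int)
    for i, p in enumerate(points):
        D = A - p
        d = (E0 * D).sum(axis=1)
        e = (E1 * D).sum(axis=1)
        s = b * e - c * d
        t = b * d - a * e
        # interior solution, then clamp to the triangle edges
        s_in = s / det
        t_in = t / det
        s_cl = np.clip(s_in, 0.0, 1.0)
        t_cl = np.clip(t_in, 0.0, 1.0)
        inside = (s_in >= 0) & (t_in >= 0) & (s_in + t_in <= 1)
        # candidate points: interior (valid where inside) and the 3 clamped edges
        cand_params = []
        # edge t=0: q(s) = A + s E0, s = clamp(-d/a)
        s0 = np.clip(-d / np.maximum(a, 1e-300), 0.0, 1.0)
        cand_params.append((s0, np.zeros_like(s0)))
        # edge s=0: q(t) = A + t E1, t = clamp(-e/c)
        t0 = np.clip(-e / np.maximum(c, 1e-300), 0.0, 1.0)
        cand_params.append((np.zeros_like(t0), t0))
        # edge s+t=1: parametrise s, q = A + s E0 + (1-s) E1
        num = (c + e) - (b + d)
        den = np.maximum(a - 2 * b + c, 1e-300)
        s1 = np.clip(num / den, 0.0, 1.0)
        cand_params.append((s1, 1.0 - s1))
        if inside.any():
            cand_params.append((np.where(inside, s_cl, 0.0), np.where(inside, t_cl, 0.0)))
        best_d2 = np.full(len(A), np.inf)
        best_q = np.zeros_like(A)
        for k, (ss, tt) in enumerate(cand_params):
            if k == 3:  # interior candidate only valid where inside
                mask = inside
                if not mask.any():
                    continue
            else:
                mask = np.ones(len(A), dtype=bool)
            q = A + ss[:, None] * E0 + tt[:, None] * E1
            d2 = ((q - p) ** 2).sum(axis=1)
            take = mask & (d2 < best_d2)
            best_d2[take] = d2[take]
            best_q[take] = q[take]
        j = int(np.argmin(best_d2))
        closest[i] = best_q[j]
        dists[i] = np.sqrt(best_d2[j])
        face_idx[i] = j
    return closest, dists, face_idx


def _mesh_projection(points: np.ndarray, geometry: GeometryBundle):
    """Nearest surface points and orthonormal tangent bases from face normals."""
    closest, dist, tri = closest_point_on_mesh(
        np.atleast_2d(points), geometry.vertices, geometry.faces
    )
    normals = geometry.mesh.face_normals[tri]
    t1 = np.cross(normals, np.array([1.0, 0.0, 0.0]))
    bad = np.linalg.norm(t1, axis=1) < 1e-8
    t1[bad] = np.cross(normals[bad], np.array([0.0, 1.0, 0.0]))
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normals, t1)
    t2 /= np.linalg.norm(t2, axis=1, keepdims=True)
    return np.asarray(closest), np.asarray(dist), t1, t2


def slide_semilandmarks(
    current: np.ndarray,
    reference: np.ndarray,
    schema: TemplateSchema,
    geometry: GeometryBundle,
    max_iter: int = 5,
    tol: float = 1e-8,
) -> SlidingResult:
    """Slide semilandmarks to minimise bending energy against ``reference``.

    Each iteration solves the tangent-space least-squares problem for all
    semilandmarks jointly, projects the slid points back onto their curve or
    surface, and stops when the relative energy decrease falls below ``tol``
    (or after ``max_iter`` iterations).  An iteration that fails to decrease
    the energy after projection is rolled back.
    """
    Y = np.array(current, dtype=float)
    reference = np.asarray(reference, dtype=float)
    B = bending_energy_matrix(reference)
    roles = schema.roles
    curve_rows = np.where(roles == "curve")[0]
    surf_rows = np.where(roles == "surface")[0]
    curve_of_row = {schema.index_of(p.id): p.curve_id for p in schema.points if p.role == "curve"}

    bbox_lo = geometry.vertices.min(axis=0) - 0.5 * geometry.diameter()
    bbox_hi = geometry.vertices.max(axis=0) + 0.5 * geometry.diameter()

    def energy(Z: np.ndarray) -> float:
        return float(np.trace(Z.T @ B @ Z))

    trace = [energy(Y)]
    it = 0
    for it in range(1, max_iter + 1):
        # tangent directions at the current positions
        dir_rows: list[int] = []
        dir_vecs: list[np.ndarray] = []
        for r in curve_rows:
            cid = curve_of_row[r]
            if cid not in geometry.curves:
                raise GeometryError(f"geometry has no curve {cid!r}")
            t = polyline_tangents(Y[r], geometry.curves[cid])[0]
            dir_rows.append(r)
            dir_vecs.append(t)
        if len(surf_rows):
            _, _, t1, t2 = _mesh_projection(Y[surf_rows], geometry)
            for k, r in enumerate(surf_rows):
                dir_rows.extend([r, r])
                dir_vecs.extend([t1[k], t2[k]])
        rows = np.array(dir_rows)
        U = np.stack(dir_vecs)  # (q, 3)
        q = len(rows)

        # quadratic model: E(Y + sum c_m u_m e_{l_m}) minimised over c
        BY = B @ Y  # (n, 3)
        g = (U * BY[rows]).sum(axis=1)  # (q,)
        M = B[np.ix_(rows, rows)] * (U @ U.T)  # (q, q)
        c, *_ = np.linalg.lstsq(M, -g, rcond=None)
        if not np.all(np.isfinite(c)):
            raise TpsError("non-finite sliding solution (singular tangent system)")

        Ynew = Y.copy()
        np.add.at(Ynew, rows, c[:, None] * U)

        if np.any(Ynew[np.concatenate([curve_rows, surf_rows])] < bbox_lo) or np.any(
            Ynew[np.concatenate([curve_rows, surf_rows])] > bbox_hi
        ):
            raise GeometryError("slid point left the geometry bounding box")

        # project back onto the assigned geometry
        for r in curve_rows:
            Ynew[r] = project_to_polyline(Ynew[r], geometry.curves[curve_of_row[r]])[0]
        if len(surf_rows):
            closest, _, _, _ = _mesh_projection(Ynew[surf_rows], geometry)
            Ynew[surf_rows] = closest

        e_new = energy(Ynew)
        if e_new > trace[-1] + 1e-15:
            it -= 1
            break  # projection undid the descent: keep the previous positions
        Y = Ynew
        decrease = trace[-1] - e_new
        trace.append(e_new)
        if decrease < tol * max(abs(trace[0]), 1e-30):
            break
    return SlidingResult(positions=Y, bending_energy_trace=trace, n_iterations=it)


# ---------------------------------------------------------------------------
# mirroring
# ---------------------------------------------------------------------------


def reflect_coords(coords: np.ndarray, schema: TemplateSchema) -> np.ndarray:
    """Negate x and permute rows by the bilateral pairing (relabelling)."""
    coords = np.asarray(coords, dtype=float)
    out = coords.copy()
    out[:, 0] *= -1.0
    return out[schema.pair_permutation]


def mirror_configuration(
    config: LandmarkConfiguration, schema: TemplateSchema
) -> LandmarkConfiguration:
    """Reflected, relabelled copy of a configuration.

    The configuration must be expressed in a frame where the midsagittal
    plane is x = 0 (see :func:`to_midsagittal_frame`); applying the
    operation twice returns the original exactly.
    """
    out = config.copy()
    out.coordinates = reflect_coords(config.coordinates, schema)
    out.is_reflected_copy = not config.is_reflected_copy
    return out


def midsagittal_frame(
    coords: np.ndarray, schema: TemplateSchema
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (rotation R, translation t) carrying the best-fit
    plane through the midline landmarks to x = 0.

    The plane is fit through the midline landmark set by total least squares
    (smallest principal axis of the midline points = plane normal).  Returns
    (R, t) such that ``(coords - t) @ R`` is in the midsagittal frame.
    """
    coords = np.asarray(coords, dtype=float)
    mid = coords[schema.midline_mask]
    t = mid.mean(axis=0)
    centered = coords - t
    midc = mid - t
    # normal = eigenvector of smallest eigenvalue of the midline scatter
    _, _, Vt = np.linalg.svd(midc, full_matrices=True)
    normal = Vt[-1]
    # build right-handed basis with the normal as x
    ref = np.array([0.0, 0.0, 1.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e2 = np.cross(normal, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(normal, e2)
    R = np.column_stack([normal, e2, e3])
    if np.linalg.det(R) < 0:
        R[:, 2] *= -1.0
    return R, t


def to_midsagittal_frame(coords: np.ndarray, schema: TemplateSchema) -> np.ndarray:
    R, t = midsagittal_frame(coords, schema)
    return (np.asarray(coords, dtype=float) - t) @ R


def complete_template_by_mirroring(
    half_template: np.ndarray,
    schema: TemplateSchema,
    geometry: GeometryBundle,
) -> np.ndarray:
    """Complete a hemi-template by mirroring the digitised surface
    semilandmarks across the midsagittal plane and projecting them onto the
    actual surface.

    ``half_template`` is a full (n_points, 3) array in which the left-side
    surface semilandmark rows are ignored (may be NaN); they are replaced by
    the projected mirror images of their right-side partners.  The input
    must already be in the midsagittal frame (midplane x = 0).
    """
    coords = np.array(half_template, dtype=float)
    left_surface = [
        schema.index_of(p.id)
        for p in schema.points
        if p.role == "surface" and p.side == "left"
    ]
    perm = schema.pair_permutation
    for row in left_surface:
        partner = perm[row]
        mirrored = coords[partner].copy()
        mirrored[0] *= -1.0
        coords[row] = mirrored
    projected, dist, _, _ = _mesh_projection(coords[left_surface], geometry)
    if np.any(dist > 0.05 * geometry.diameter()):
        raise GeometryError(
            "mirrored surface semilandmarks are far from the surface; "
            "is the configuration in the midsagittal frame?"
        )
    coords[left_surface] = projected
    return coords
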