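"""Generalized Procrustes analysis and Procrustes distances.

Full GPA: every configuration is centred at the origin and scaled to
centroid size one, then iteratively rotated to the running consensus (the
arithmetic mean of the aligned configurations) until the consensus is
stationary.  Rotations are proper (det +1) always — reflected copies in an
object-symmetry analysis must stay reflected, otherwise the asymmetric
signal would be silently removed.

When sliding options and geometry are supplied, semilandmarks are relaxed
against the current consensus (minimising thin-plate-spline bending energy)
between alignment passes; see :mod:`palasym.semilandmarks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import GeometryBundle
from .schema import PopulationDataset, TemplateSchema

__all__ = [
    "ProcrustesFit",
    "SlideOptions",
    "DegenerateConfigurationError",
    "centroid_size",
    "optimal_rotation",
    "gpa",
    "procrustes_distance",
    "distance_matrix",
]


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide; the configuration carries no shape."""


@dataclass
class SlideOptions:
    """Semilandmark sliding options used inside :func:`gpa`.

    ``n_outer``: number of GPA outer iterations that include a sliding pass
    (after that, alignment continues to convergence with positions frozen).
    ``max_iter``/``tol``: per-pass inner sliding iterations and relative
    energy-decrease stopping tolerance.
    """

    n_outer: int = 3
    max_iter: int = 5
    tol: float = 1e-8


@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes superimposition.

    ``aligned`` holds Procrustes shape coordinates (centroid at the origin,
    centroid size one); ``consensus`` is their arithmetic mean;
    ``centroid_sizes`` are the sizes (mm) removed from the raw input.
    """

    aligned: np.ndarray  # (n_config, n_points, 3)
    consensus: np.ndarray  # (n_points, 3)
    centroid_sizes: np.ndarray  # (n_config,)
    n_iterations: int
    converged: bool
    objective_trace: list[float] = field(default_factory=list)


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared deviations from the centroid (mm)."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 0.0:
        raise DegenerateConfigurationError("all landmarks identical: centroid size 0")
    return cs


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (3x3, det +1) minimising ||A @ R - B||_F.

    A and B must be centred and of equal shape.  The determinant sign is
    corrected along the smallest singular direction, so reflected inputs are
    never un-reflected.  For rank-deficient cross-covariances the SVD
    convention makes the result deterministic (the rotation closest to the
    optimum reachable without reflection).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    H = A.T @ B
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:  # fully degenerate: fall back to identity-continuous choice
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def _normalize(coords: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 0.0:
        raise DegenerateConfigurationError("zero centroid size")
    return centered / cs, cs, centroid


def gpa(
    data: PopulationDataset | np.ndarray | Sequence[np.ndarray],
    slide: SlideOptions | None = None,
    geometry: GeometryBundle | Sequence[GeometryBundle] | None = None,
    schema: TemplateSchema | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    anchor_first: bool = True,
) -> ProcrustesFit:
    """Generalized Procrustes analysis with optional semilandmark sliding.

    Parameters
    ----------
    data
        A :class:`PopulationDataset` or an (n_config, n_points, 3) stack.
    slide, geometry, schema
        When all are given, each outer iteration interleaves
        align -> update consensus -> slide semilandmarks (bending energy
        against the consensus) -> re-align.  ``geometry`` may be a single
        shared bundle or one bundle per configuration, expressed in each
        configuration's raw coordinate frame.
    anchor_first
        Rotate the final solution so the consensus is optimally aligned
        with the first configuration's initial orientation; makes outputs
        reproducible across runs and input frames.
    """
    if isinstance(data, PopulationDataset):
        X = data.coordinate_stack()
        schema = schema or data.schema
    else:
        X = np.asarray(np.stack(list(data)) if not isinstance(data, np.ndarray) else data, dtype=float)
    if X.ndim != 3 or X.shape[2] != 3:
        raise ValueError("expected an (n_config, n_points, 3) stack")
    n = X.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")

    norm = [_normalize(X[i]) for i in range(n)]
    Xc = np.stack([t[0] for t in norm])  # unit-size, centred
    sizes = np.array([t[1] for t in norm])
    centroids = np.stack([t[2] for t in norm])
    first_frame = Xc[0].copy()

    do_slide = slide is not None and geometry is not None and schema is not None
    if do_slide:
        from . import semilandmarks as _sl

        if isinstance(geometry, GeometryBundle):
            bundles = [geometry] * n
        else:
            bundles = list(geometry)
            if len(bundles) != n:
                raise ValueError("need one GeometryBundle per configuration")

    rotations = np.stack([np.eye(3)] * n)
    consensus = Xc[0].copy()
    aligned = Xc.copy()
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            rotations[i] = optimal_rotation(Xc[i], consensus)
            aligned[i] = Xc[i] @ rotations[i]
        new_consensus = aligned.mean(axis=0)
        trace.append(float(((aligned - new_consensus) ** 2).sum()))

        slid_this_iter = False
        if do_slide and it <= slide.n_outer:
            for i in range(n):
                geo_i = bundles[i].transformed(
                    centroids[i], 1.0 / sizes[i], rotations[i]
                )
                res = _sl.slide_semilandmarks(
                    aligned[i],
                    new_consensus,
                    schema,
                    geo_i,
                    max_iter=slide.max_iter,
                    tol=slide.tol,
                )
                # fold slid positions back into the pre-rotation frame and
                # re-normalise (sliding perturbs centroid and size slightly)
                slid = res.positions @ rotations[i].T
                Xc[i], _, _ = _normalize(slid)
            slid_this_iter = True
            new_consensus = np.stack(
                [Xc[i] @ optimal_rotation(Xc[i], new_consensus) for i in range(n)]
            ).mean(axis=0)

        delta = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
        consensus = new_consensus
        if delta < tol and not slid_this_iter:
            converged = True
            break

    if anchor_first:
        Q = optimal_rotation(consensus, first_frame)
        aligned = aligned @ Q
        consensus = consensus @ Q
    return ProcrustesFit(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        n_iterations=it,
        converged=converged,
        objective_trace=trace,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the coordinate-wise difference of two superimposed
    configurations (partial Procrustes distance in the common shape space)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


def distance_matrix(fit: ProcrustesFit | np.ndarray) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise Procrustes distances."""
    X = fit.aligned if isinstance(fit, ProcrustesFit) else np.asarray(fit, dtype=float)
    flat = X.reshape(X.shape[0], -1)
    return squareform(pdist(flat, metric="euclidean"))
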