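"""Readers and writers for landmark files, geometry and result tables.

Supported landmark dialects:

``csv``
    One row per landmark with columns
    ``individual_id, landmark_id, x, y, z, age_group, sex, collection``.
    This is the native dialect: per-individual metadata travels with the
    coordinates.
``tps``
    ``LM3=``/``ID=`` blocks (3D variant of the classic interchange format).
    Carries ids only.
``morphologika``
    ``[individuals]/[landmarks]/[dimensions]/[names]/[rawpoints]`` sections.
    Carries ids only.

Meshes are read through :mod:`trimesh` (PLY/OBJ/STL); curve polylines are
plain CSV files with ``x,y,z`` columns.  All writers use repr-precision
floats so that write -> read -> write is byte-identical and round trips are
lossless well below 1e-9 mm.
"""

from __future__ import annotations

import io as _stdio
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh

from .schema import (
    LandmarkConfiguration,
    PopulationDataset,
    TemplateSchema,
    default_palate_schema,
)

__all__ = [
    "GeometryBundle",
    "LandmarkParseError",
    "GeometryError",
    "read_landmarks",
    "write_landmarks",
    "read_geometry",
    "write_geometry",
    "write_table",
    "read_table",
]

_FMT = "%.17g"  # round-trips IEEE doubles exactly


class LandmarkParseError(ValueError):
    """Malformed landmark file (names the offending line/specimen)."""


class GeometryError(ValueError):
    """Invalid mesh or polyline geometry."""


@dataclass
class GeometryBundle:
    """Triangle mesh plus named curve polylines, in mm.

    ``vertices`` (n, 3) / ``faces`` (m, 3) describe the surface on which
    surface semilandmarks slide; ``curves`` maps curve_id to an ordered
    (p, 3) polyline.
    """

    vertices: np.ndarray
    faces: np.ndarray
    curves: dict[str, np.ndarray] = field(default_factory=dict)
    _mesh: trimesh.Trimesh | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.curves = {k: np.asarray(v, dtype=float) for k, v in self.curves.items()}
        self.validate()

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be triangles (m, 3)")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise GeometryError("faces index out-of-range vertices")
        for cid, poly in self.curves.items():
            if poly.ndim != 2 or poly.shape[1] != 3 or len(poly) < 2:
                raise GeometryError(f"curve {cid!r} must be an ordered (p>=2, 3) polyline")

    @property
    def mesh(self) -> trimesh.Trimesh:
        if self._mesh is None:
            self._mesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._mesh

    def diameter(self) -> float:
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return float(np.linalg.norm(hi - lo))

    def transformed(self, translation, scale: float, rotation) -> "GeometryBundle":
        """Return the bundle mapped by ``x -> ((x - translation) * scale) @ rotation``."""
        t = np.asarray(translation, dtype=float)
        R = np.asarray(rotation, dtype=float)
        return GeometryBundle(
            vertices=((self.vertices - t) * scale) @ R,
            faces=self.faces.copy(),
            curves={k: ((v - t) * scale) @ R for k, v in self.curves.items()},
        )


# ---------------------------------------------------------------------------
# landmark files
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "individual_id",
    "landmark_id",
    "x",
    "y",
    "z",
    "age_group",
    "sex",
    "collection",
]


def read_landmarks(
    path: str | Path,
    format: str = "csv",
    schema: TemplateSchema | None = None,
) -> PopulationDataset:
    """Read a landmark file into a :class:`PopulationDataset`.

    Truncated specimens (fewer rows than the schema expects) are rejected,
    never padded.
    """
    schema = schema or default_palate_schema()
    path = Path(path)
    if format == "csv":
        configs = _read_csv(path, schema)
    elif format == "tps":
        configs = _read_tps(path, schema)
    elif format == "morphologika":
        configs = _read_morphologika(path, schema)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    return PopulationDataset(schema=schema, configurations=configs, provenance=str(path))


def write_landmarks(
    dataset: PopulationDataset, path: str | Path, format: str = "csv"
) -> Path:
    """Write a dataset; the output re-reads losslessly (<= 1e-9 mm)."""
    path = Path(path)
    if format == "csv":
        text = _format_csv(dataset)
    elif format == "tps":
        text = _format_tps(dataset)
    elif format == "morphologika":
        text = _format_morphologika(dataset)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    path.write_text(text)
    return path


def _read_csv(path: Path, schema: TemplateSchema) -> list[LandmarkConfiguration]:
    try:
        df = pd.read_csv(path, dtype={"individual_id": str}, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise LandmarkParseError(f"{path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise LandmarkParseError(f"{path}: missing columns {missing}")
    configs: list[LandmarkConfiguration] = []
    expected = list(schema.ids)
    # preserve file order of first appearance
    for ind, sub in df.groupby("individual_id", sort=False):
        got = [int(v) for v in sub["landmark_id"]]
        if got != expected:
            if sorted(got) == sorted(expected):
                sub = sub.set_index("landmark_id").loc[expected].reset_index()
            else:
                raise LandmarkParseError(
                    f"{path}: specimen {ind!r} has landmark ids {got[:5]}... "
                    f"(n={len(got)}), expected the {len(expected)} schema ids"
                )
        coords = sub[["x", "y", "z"]].to_numpy(dtype=float)
        meta = sub.iloc[0]
        configs.append(
            LandmarkConfiguration(
                individual_id=str(ind),
                coordinates=coords,
                age_group=str(meta.get("age_group", "") or ""),
                sex=str(meta.get("sex", "") or ""),
                collection=str(meta.get("collection", "") or ""),
            )
        )
    return configs


def _format_csv(dataset: PopulationDataset) -> str:
    buf = _stdio.StringIO()
    buf.write(",".join(_CSV_COLUMNS) + "\n")
    for c in dataset.configurations:
        for lid, (x, y, z) in zip(dataset.schema.ids, c.coordinates):
            buf.write(
                f"{c.individual_id},{lid},{_FMT % x},{_FMT % y},{_FMT % z},"
                f"{c.age_group},{c.sex},{c.collection}\n"
            )
    return buf.getvalue()


def _read_tps(path: Path, schema: TemplateSchema) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith(("LM3=", "LM=")):
            raise LandmarkParseError(f"{path}:{i + 1}: expected LM3= block, got {line!r}")
        n = int(line.split("=", 1)[1])
        rows = []
        i += 1
        while i < len(lines) and len(rows) < n:
            s = lines[i].strip()
            if not s:
                raise LandmarkParseError(
                    f"{path}:{i + 1}: truncated block, got {len(rows)}/{n} rows"
                )
            parts = s.split()
            if len(parts) != 3:
                raise LandmarkParseError(
                    f"{path}:{i + 1}: expected 3 coordinates, got {len(parts)}"
                )
            rows.append([float(v) for v in parts])
            i += 1
        if len(rows) < n:
            raise LandmarkParseError(f"{path}: truncated final block ({len(rows)}/{n})")
        ind = f"specimen_{len(configs) + 1}"
        if i < len(lines) and lines[i].strip().upper().startswith("ID="):
            ind = lines[i].strip().split("=", 1)[1]
            i += 1
        if n != schema.n_points:
            raise LandmarkParseError(
                f"{path}: specimen {ind!r} has {n} landmarks, expected {schema.n_points}"
            )
        configs.append(
            LandmarkConfiguration(individual_id=ind, coordinates=np.array(rows))
        )
    return configs


def _format_tps(dataset: PopulationDataset) -> str:
    buf = _stdio.StringIO()
    for c in dataset.configurations:
        buf.write(f"LM3={len(c.coordinates)}\n")
        for x, y, z in c.coordinates:
            buf.write(f"{_FMT % x} {_FMT % y} {_FMT % z}\n")
        buf.write(f"ID={c.individual_id}\n")
    return buf.getvalue()


def _read_morphologika(path: Path, schema: TemplateSchema) -> list[LandmarkConfiguration]:
    text = path.read_text()
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].lower()
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
        else:
            raise LandmarkParseError(f"{path}:{ln}: content before first [section]")
    for key in ("individuals", "landmarks", "dimensions", "rawpoints"):
        if key not in sections:
            raise LandmarkParseError(f"{path}: missing [{key}] section")
    n_ind = int(sections["individuals"][0])
    n_lmk = int(sections["landmarks"][0])
    n_dim = int(sections["dimensions"][0])
    if n_dim != 3:
        raise LandmarkParseError(f"{path}: unsupported dimension {n_dim}, need 3")
    if n_lmk != schema.n_points:
        raise LandmarkParseError(
            f"{path}: {n_lmk} landmarks per specimen, expected {schema.n_points}"
        )
    names = sections.get("names", [f"specimen_{i + 1}" for i in range(n_ind)])
    raw = sections["rawpoints"]
    configs: list[LandmarkConfiguration] = []
    idx = 0
    block_name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, block_name
        if block_name is None:
            return
        if len(rows) != n_lmk:
            raise LandmarkParseError(
                f"{path}: specimen {block_name!r} has {len(rows)} rows, expected {n_lmk}"
            )
        configs.append(
            LandmarkConfiguration(individual_id=block_name, coordinates=np.array(rows))
        )
        rows = []
        block_name = None

    for line in raw:
        if line.startswith("'"):
            flush()
            block_name = line[1:].strip()
        else:
            parts = line.split()
            if len(parts) != 3:
                raise LandmarkParseError(
                    f"{path}: bad coordinate line {line!r} in [rawpoints]"
                )
            rows.append([float(v) for v in parts])
    flush()
    if len(configs) != n_ind:
        raise LandmarkParseError(
            f"{path}: [rawpoints] holds {len(configs)} specimens, header says {n_ind}"
        )
    for c, name in zip(configs, names):
        if c.individual_id.startswith("specimen_") and name:
            c.individual_id = name
    return configs


def _format_morphologika(dataset: PopulationDataset) -> str:
    n = len(dataset.configurations)
    buf = _stdio.StringIO()
    buf.write(f"[individuals]\n{n}\n")
    buf.write(f"[landmarks]\n{dataset.schema.n_points}\n")
    buf.write("[dimensions]\n3\n")
    buf.write("[names]\n")
    for c in dataset.configurations:
        buf.write(f"{c.individual_id}\n")
    buf.write("[rawpoints]\n")
    for c in dataset.configurations:
        buf.write(f"'{c.individual_id}\n")
        for x, y, z in c.coordinates:
            buf.write(f"{_FMT % x} {_FMT % y} {_FMT % z}\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def read_geometry(
    mesh_path: str | Path,
    curve_paths: Mapping[str, str | Path] | None = None,
) -> GeometryBundle:
    """Load a triangle mesh (PLY/OBJ/STL) plus optional curve polylines (CSV)."""
    mesh = trimesh.load(str(mesh_path), force="mesh", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or mesh.faces.shape[1] != 3:
        raise GeometryError(f"{mesh_path}: not a triangle mesh")
    curves: dict[str, np.ndarray] = {}
    for cid, cpath in (curve_paths or {}).items():
        df = pd.read_csv(cpath, float_precision="round_trip")
        if not {"x", "y", "z"} <= set(df.columns):
            raise GeometryError(f"{cpath}: polyline CSV needs x,y,z columns")
        poly = df[["x", "y", "z"]].to_numpy(dtype=float)
        if len(poly) < 2:
            raise GeometryError(f"{cpath}: polyline needs >= 2 points")
        curves[cid] = poly
    return GeometryBundle(
        vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces), curves=curves
    )


def _write_ply_double(bundle: GeometryBundle, path: Path) -> None:
    # ascii PLY with double-precision vertices (library exporters downcast
    # to float32, which breaks lossless round trips)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(bundle.vertices)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write(f"element face {len(bundle.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for x, y, z in bundle.vertices:
            fh.write(f"{_FMT % x} {_FMT % y} {_FMT % z}\n")
        for a, b, c in bundle.faces:
            fh.write(f"3 {a} {b} {c}\n")


def write_geometry(bundle: GeometryBundle, directory: str | Path, stem: str = "surface") -> dict[str, Path]:
    """Write mesh as ascii PLY and each curve as a CSV polyline; return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    mesh_path = directory / f"{stem}.ply"
    _write_ply_double(bundle, mesh_path)
    paths["mesh"] = mesh_path
    for cid, poly in bundle.curves.items():
        p = directory / f"{cid}.csv"
        with open(p, "w") as fh:
            fh.write("x,y,z\n")
            for x, y, z in poly:
                fh.write(f"{_FMT % x},{_FMT % y},{_FMT % z}\n")
        paths[cid] = p
    return paths


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_table(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as TSV with deterministic formatting and row order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = rows.copy()
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            out = []
            for v in row:
                if isinstance(v, (float, np.floating)):
                    out.append(_FMT % v)
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
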