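"""Surface-mesh and feature-map I/O with fixed-topology validation.

Supported formats: GIfTI surfaces (.surf.gii) and shape files (.shape.gii)
via nibabel, Wavefront OBJ (ASCII v/f records, parsed directly so vertex
order is preserved exactly), and headered TSV feature tables.  Vertex indices
are 0-based internally; OBJ's 1-based indices are converted at the boundary.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from surfage.synthetic_cortex import (
    FEATURE_NAMES,
    FeatureMap,
    SurfaceMesh,
    vertices_per_hemisphere,
)


class SurfaceValidationError(ValueError):
    pass


def _validate_topology(coords: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Check manifoldness and component structure; return hemisphere labels."""
    n = coords.shape[0]
    if faces.min() < 0 or faces.max() >= n:
        bad = np.flatnonzero((faces < 0).any(axis=1) | (faces >= n).any(axis=1))[0]
        raise SurfaceValidationError(
            f"face {bad} references vertex outside [0, {n}): {faces[bad].tolist()}"
        )
    key = np.sort(faces, axis=1)
    _, counts = np.unique(key, axis=0, return_counts=True)
    if np.any(counts > 1):
        dup = np.unique(key, axis=0)[counts > 1][0]
        raise SurfaceValidationError(f"duplicated face {dup.tolist()}")
    # each undirected edge must belong to at most 2 faces
    edges = np.vstack([key[:, [0, 1]], key[:, [0, 2]], key[:, [1, 2]]])
    _, edge_counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(edge_counts > 2):
        raise SurfaceValidationError("non-manifold edge shared by >2 faces")

    rows = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    cols = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    adj = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp not in (1, 2):
        raise SurfaceValidationError(
            f"expected 1 or 2 connected components, found {n_comp}"
        )
    if n_comp == 1:
        return np.zeros(n, dtype=np.int8)
    centroids = [coords[labels == c].mean(axis=0) for c in range(2)]
    left_comp = int(np.argmin([c[0] for c in centroids]))  # leftmost = left
    return (labels != left_comp).astype(np.int8)


def _infer_level(n_vertices: int, n_hemispheres: int) -> int:
    per_hemi = n_vertices // n_hemispheres
    for level in range(0, 10):
        if vertices_per_hemisphere(level) == per_hemi:
            return level
    return -1  # not an icosphere; valid surfaces may still be loaded


def _mesh_from_arrays(coords: np.ndarray, faces: np.ndarray) -> SurfaceMesh:
    hemi = _validate_topology(coords, faces)
    level = _infer_level(coords.shape[0], int(hemi.max()) + 1)
    return SurfaceMesh(coords, faces.astype(np.int64), hemi, level)


def read_surface(path: str, format: str = "auto") -> SurfaceMesh:
    """Read a triangulated surface; validates manifoldness, face indices and
    component count, and infers hemisphere labels (leftmost centroid = left)."""
    fmt = format
    if fmt == "auto":
        fmt = "gifti" if str(path).endswith(".gii") else "obj"
    if fmt == "gifti":
        img = nib.load(str(path))
        coords = faces = None
        for da in img.darrays:
            if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                coords = np.asarray(da.data, dtype=float)
            elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = np.asarray(da.data, dtype=np.int64)
        if coords is None or faces is None:
            raise SurfaceValidationError(f"{path}: missing pointset or triangles")
    elif fmt == "obj":
        coords_l, faces_l = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0] == "v":
                    coords_l.append([float(v) for v in parts[1:4]])
                elif parts[0] == "f":
                    faces_l.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
        coords = np.asarray(coords_l, dtype=float)
        faces = np.asarray(faces_l, dtype=np.int64)
    else:
        raise ValueError(f"unknown format {format!r}")
    return _mesh_from_arrays(coords, faces)


def write_surface(mesh: SurfaceMesh, path: str, format: str = "auto") -> None:
    fmt = format
    if fmt == "auto":
        fmt = "gifti" if str(path).endswith(".gii") else "obj"
    if fmt == "gifti":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.coordinates.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    elif fmt == "obj":
        with open(path, "w") as fh:
            for v in mesh.coordinates:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def summarize_surface(mesh: SurfaceMesh) -> dict:
    """Vertex/face/edge counts, per hemisphere and total."""
    edges = np.vstack(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [0, 2]], mesh.faces[:, [1, 2]]]
    )
    n_edges = np.unique(np.sort(edges, axis=1), axis=0).shape[0]
    return dict(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        n_edges=n_edges,
        n_hemispheres=mesh.n_hemispheres,
        level=mesh.level,
    )


def read_features(path: str, mesh: SurfaceMesh, format: str = "auto") -> FeatureMap:
    """Read a per-vertex feature table/shape file onto a given mesh.

    Column order is normalized to (thickness, sulcal_depth, gmwm_ratio);
    the row count must equal the mesh's vertex count and rows must be finite.
    """
    fmt = format
    if fmt == "auto":
        fmt = "gifti" if str(path).endswith(".gii") else "tsv"
    scan_id = os.path.basename(str(path)).split(".")[0]
    if fmt == "gifti":
        img = nib.load(str(path))
        if len(img.darrays) != len(FEATURE_NAMES):
            raise ValueError(
                f"{path}: expected {len(FEATURE_NAMES)} data arrays "
                f"({', '.join(FEATURE_NAMES)}), found {len(img.darrays)}"
            )
        values = np.column_stack([np.asarray(da.data, float) for da in img.darrays])
    else:
        df = pd.read_csv(path, sep="\t")
        unknown = set(df.columns) - set(FEATURE_NAMES) - {"vertex_index"}
        if unknown:
            raise ValueError(
                f"unknown feature columns {sorted(unknown)}; expected "
                f"{list(FEATURE_NAMES)} (+ optional vertex_index)"
            )
        missing = set(FEATURE_NAMES) - set(df.columns)
        if missing:
            raise ValueError(f"missing feature columns {sorted(missing)}")
        if "vertex_index" in df.columns:
            df = df.sort_values("vertex_index")
        values = df[list(FEATURE_NAMES)].to_numpy(float)
    if values.shape[0] != mesh.n_vertices:
        raise ValueError(
            f"{values.shape[0]} feature rows but mesh has {mesh.n_vertices} vertices"
        )
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values).all(axis=1))[0])
        raise ValueError(f"non-finite feature values at vertex {bad}")
    return FeatureMap(scan_id, values, mesh.level)


def write_features(fm: FeatureMap, path: str, format: str = "auto") -> None:
    fmt = format
    if fmt == "auto":
        fmt = "gifti" if str(path).endswith(".gii") else "tsv"
    if fmt == "gifti":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    fm.values[:, i].astype(np.float32), intent="NIFTI_INTENT_SHAPE"
                )
                for i in range(len(FEATURE_NAMES))
            ]
        )
        nib.save(img, str(path))
    else:
        df = pd.DataFrame(fm.values, columns=list(FEATURE_NAMES))
        df.insert(0, "vertex_index", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)


def check_shared_topology(meshes: list[SurfaceMesh]) -> None:
    """All scans of a cohort must live on one identical mesh (same faces)."""
    ref = meshes[0]
    for i, m in enumerate(meshes[1:], start=1):
        if m.faces.shape != ref.faces.shape or not np.array_equal(m.faces, ref.faces):
            raise SurfaceValidationError(
                f"mesh {i} topology differs from mesh 0; the model requires "
                "identical graph structure for every input"
            )
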