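"""Icosahedron downsampling of feature maps between subdivision levels.

Because icosphere vertex ordering is parent-first, the coarse mesh's vertex i
coincides geometrically with the fine mesh's vertex i within each hemisphere;
``select`` mode exploits that directly, while ``patch_mean`` averages each
coarse vertex's Voronoi patch of fine vertices (nearest-coarse-vertex
assignment on the unit sphere, per hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from surfage.synthetic_cortex import FeatureMap, SurfaceMesh


@dataclass
class DownsampleMap:
    """Sparse aggregation matrix: coarse features = weights @ fine features.

    Rows are coarse vertices; row weights are non-negative and sum to 1."""

    weights: sp.csr_matrix  # (n_coarse, n_fine)
    source_level: int
    target_level: int
    mode: str

    def to_frame(self) -> pd.DataFrame:
        coo = self.weights.tocoo()
        return pd.DataFrame(
            {"coarse_index": coo.row, "fine_index": coo.col, "weight": coo.data}
        ).sort_values(["coarse_index", "fine_index"], ignore_index=True)


def _hemi_offsets(mesh: SurfaceMesh) -> list[int]:
    return [sl.start for sl in mesh.hemisphere_slices()]


def build_downsample_map(
    fine: SurfaceMesh, coarse: SurfaceMesh, mode: str = "patch_mean"
) -> DownsampleMap:
    """Map a fine icosphere's vertices onto a coarse icosphere's.

    ``select``: coarse vertex i takes fine vertex i (valid by parent-first
    ordering; verified by coordinate agreement within 1e-6).
    ``patch_mean``: coarse vertex i averages, with uniform weights, the fine
    vertices nearer to it than to any other coarse vertex of the same
    hemisphere (Euclidean on the unit sphere; ties -> lowest coarse index).
    """
    if fine.n_hemispheres != coarse.n_hemispheres:
        raise ValueError("hemisphere count mismatch")
    if coarse.level > fine.level:
        raise ValueError("coarse level must not exceed fine level")
    if mode not in ("select", "patch_mean"):
        raise ValueError(f"unknown mode {mode!r}")

    fine_slices = fine.hemisphere_slices()
    coarse_slices = coarse.hemisphere_slices()
    fine_unit = fine.unit_positions()
    coarse_unit = coarse.unit_positions()

    rows, cols, vals = [], [], []
    for fsl, csl in zip(fine_slices, coarse_slices):
        n_f = fsl.stop - fsl.start
        n_c = csl.stop - csl.start
        fu = fine_unit[fsl]
        cu = coarse_unit[csl]
        if mode == "select":
            err = np.abs(fu[:n_c] - cu).max()
            if err > 1e-6:
                raise ValueError(
                    f"parent-first ordering violated: coordinate mismatch {err:.2e}"
                )
            rows.extend(range(csl.start, csl.stop))
            cols.extend(range(fsl.start, fsl.start + n_c))
            vals.extend([1.0] * n_c)
        else:
            # nearest coarse vertex per fine vertex; argmin takes the lowest
            # index on ties
            d2 = ((fu[:, None, :] - cu[None, :, :]) ** 2).sum(axis=2)
            owner = d2.argmin(axis=1)
            counts = np.bincount(owner, minlength=n_c)
            if np.any(counts == 0):
                raise RuntimeError("empty patch in nearest-vertex assignment")
            rows.extend(owner + csl.start)
            cols.extend(np.arange(fsl.start, fsl.stop))
            vals.extend(1.0 / counts[owner])
    w = sp.csr_matrix(
        (vals, (rows, cols)), shape=(coarse.n_vertices, fine.n_vertices)
    )
    return DownsampleMap(w, fine.level, coarse.level, mode)


def downsample_features(dmap: DownsampleMap, fm: FeatureMap) -> FeatureMap:
    """Aggregate a fine-level feature map onto the coarse level."""
    if fm.mesh_level != dmap.source_level:
        raise ValueError(
            f"feature map at level {fm.mesh_level}, map expects {dmap.source_level}"
        )
    if fm.values.shape[0] != dmap.weights.shape[1]:
        raise ValueError(
            f"feature map has {fm.values.shape[0]} rows, "
            f"map expects {dmap.weights.shape[1]}"
        )
    coarse = dmap.weights @ fm.values
    return FeatureMap(fm.scan_id, coarse, dmap.target_level)
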