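"""Spectral graph machinery for mesh-based convolution.

Adjacency -> symmetric-normalized Laplacian -> rescaled Chebyshev basis;
greedy heavy-edge (Graclus-style) coarsening into a binary pooling hierarchy
with fake padding vertices so that pooling is a stride-2 1D operation; and a
degree-preserving random rewiring used as the "random connections" ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


def normalized_laplacian(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """L = I - D^(-1/2) A D^(-1/2); isolated vertices get an identity row."""
    a = sp.csr_matrix(adjacency, dtype=float)
    if (abs(a - a.T) > 1e-12).nnz:
        raise ValueError("adjacency must be symmetric")
    if a.diagonal().any():
        raise ValueError("adjacency must have zero diagonal")
    deg = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    d = sp.diags(dinv)
    lap = sp.eye(a.shape[0], format="csr") - d @ a @ d
    return sp.csr_matrix(lap)


def estimate_lambda_max(laplacian: sp.spmatrix, tol: float = 1e-3) -> float:
    """Largest Laplacian eigenvalue via Lanczos (ARPACK)."""
    n = laplacian.shape[0]
    if n <= 3:
        return float(np.linalg.eigvalsh(laplacian.toarray()).max())
    val = spla.eigsh(laplacian, k=1, which="LM", tol=tol, return_eigenvectors=False)
    return float(val[0])


def chebyshev_basis(
    laplacian: sp.spmatrix, x: np.ndarray, k: int, lambda_max: float = 2.0
) -> np.ndarray:
    """Stack T_0(Lt) X ... T_{K-1}(Lt) X, with Lt = 2 L / lambda_max - I.

    ``x`` may be (n, c) or (batch, n, c); the output prepends an axis of
    length K.  lambda_max defaults to 2, the exact upper bound for a
    normalized Laplacian, so no per-graph estimation is needed.
    """
    if k < 1:
        raise ValueError("Chebyshev order K must be >= 1")
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    lap = sp.csr_matrix(laplacian, dtype=float)
    n = lap.shape[0]
    lt = (2.0 / lambda_max) * lap - sp.eye(n, format="csr")

    squeeze = x.ndim == 2
    xb = x[None] if squeeze else x  # (B, n, c)
    b, _, c = xb.shape

    def matvec(t: np.ndarray) -> np.ndarray:
        # apply Lt along the vertex axis for all batches/channels at once
        flat = np.moveaxis(t, 1, 0).reshape(n, b * c)
        out = lt @ flat
        return np.moveaxis(out.reshape(n, b, c), 0, 1)

    basis = np.empty((k, b, n, c))
    basis[0] = xb
    if k > 1:
        basis[1] = matvec(xb)
    for i in range(2, k):
        basis[i] = 2.0 * matvec(basis[i - 1]) - basis[i - 2]
    if not np.all(np.isfinite(basis)):
        raise FloatingPointError("non-finite values in Chebyshev basis")
    return basis[:, 0] if squeeze else basis


# --------------------------------------------------------------------------
# Graclus-style coarsening with 1D pooling arrangement
# --------------------------------------------------------------------------


@dataclass
class GraphHierarchy:
    """Coarsened Laplacians and the vertex arrangement for 1D pooling.

    laplacians[0] is the finest (permuted, fake-padded) level; each pooling
    step halves the vertex count.  ``perm`` maps position in the permuted
    finest level -> original vertex index (or -1 for a fake vertex);
    ``real_mask[l]`` flags non-fake vertices at level l.  Fake vertices are
    disconnected (identity Laplacian rows) and are replaced by a -inf
    sentinel before max-pooling so they can never win a max.
    """

    laplacians: list[sp.csr_matrix]
    perm: np.ndarray
    real_mask: list[np.ndarray]
    lambda_max: list[float]
    n_real: int

    @property
    def depth(self) -> int:
        return len(self.laplacians) - 1

    def permute_features(self, x: np.ndarray) -> np.ndarray:
        """Rearrange (batch, n_real, c) features into the padded 1D order;
        fake positions are zero-filled (the pooling sentinel handles them)."""
        b, n, c = x.shape
        if n != self.n_real:
            raise ValueError(f"expected {self.n_real} vertices, got {n}")
        out = np.zeros((b, self.perm.size, c), dtype=x.dtype)
        real = self.perm >= 0
        out[:, real, :] = x[:, self.perm[real], :]
        return out


def _heavy_edge_matching(adj: sp.csr_matrix) -> np.ndarray:
    """Greedy matching: visit vertices in ascending index, pair each
    unmatched vertex with the unmatched neighbour maximizing the
    normalized-cut weight w_ij * (1/d_i + 1/d_j); ties -> lowest index.
    Returns cluster ids (parents) in [0, n_coarse)."""
    n = adj.shape[0]
    deg = np.asarray(adj.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_deg = np.where(deg > 0, 1.0 / deg, 0.0)
    cluster = -np.ones(n, dtype=np.int64)
    indptr, indices, data = adj.indptr, adj.indices, adj.data
    cid = 0
    for i in range(n):
        if cluster[i] >= 0:
            continue
        best_j, best_w = -1, -np.inf
        for ptr in range(indptr[i], indptr[i + 1]):
            j = indices[ptr]
            if cluster[j] >= 0 or j == i:
                continue
            w = data[ptr] * (inv_deg[i] + inv_deg[j])
            if w > best_w + 1e-15 or (abs(w - best_w) <= 1e-15 and j < best_j):
                best_j, best_w = j, w
        cluster[i] = cid
        if best_j >= 0:
            cluster[best_j] = cid
        cid += 1
    return cluster


def _coarsen_adjacency(adj: sp.csr_matrix, cluster: np.ndarray) -> sp.csr_matrix:
    n_coarse = int(cluster.max()) + 1
    coo = adj.tocoo()
    rows, cols = cluster[coo.row], cluster[coo.col]
    a = sp.coo_matrix((coo.data, (rows, cols)), shape=(n_coarse, n_coarse)).tocsr()
    a.setdiag(0)
    a.eliminate_zeros()
    return a


def coarsen_graph(
    adjacency: sp.spmatrix, levels: int, lambda_max_mode: str = "bound"
) -> GraphHierarchy:
    """Coarsen ``levels`` times and arrange the finest level for 1D pooling.

    Each coarse vertex pools exactly 2 positions of the level below; vertices
    left unmatched get one fake sibling, and fakes propagate downward in
    pairs, so the permuted finest length is n_coarsest * 2^levels.
    Deterministic: vertices are visited in ascending index everywhere.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    adj0 = sp.csr_matrix(adjacency, dtype=float)
    n_real = adj0.shape[0]

    adjs = [adj0]
    clusters = []
    for _ in range(levels):
        a = adjs[-1]
        if a.shape[0] < 2:
            raise ValueError("graph too small to coarsen further")
        cl = _heavy_edge_matching(a)
        clusters.append(cl)
        adjs.append(_coarsen_adjacency(a, cl))

    # children[l][c] = list of level-l vertex indices pooled into coarse c
    orders: list[np.ndarray] = [np.arange(adjs[-1].shape[0])]
    sizes = [adjs[-1].shape[0]]
    for lvl in range(levels - 1, -1, -1):
        cl = clusters[lvl]
        n_fine = cl.size
        kids: list[list[int]] = [[] for _ in range(int(cl.max()) + 1)]
        for v in range(n_fine):
            kids[cl[v]].append(v)
        next_fake = n_fine
        order = []
        for c in orders[0]:
            if c < len(kids):
                block = kids[c]
                if len(block) == 1:
                    block = [block[0], next_fake]
                    next_fake += 1
            else:  # fake parent -> two fake children
                block = [next_fake, next_fake + 1]
                next_fake += 2
            order.extend(block)
        orders.insert(0, np.asarray(order, dtype=np.int64))
        sizes.insert(0, next_fake)

    padded_sizes = [orders[0].size // (2**l) for l in range(levels + 1)]

    # build padded + permuted Laplacians per level
    laplacians, real_mask, lmax = [], [], []
    for lvl in range(levels + 1):
        a = adjs[lvl]
        n_lvl = a.shape[0]
        n_pad = padded_sizes[lvl]
        order = orders[lvl]
        # position p holds original vertex order[p] (fake if >= n_lvl)
        pos_real = order < n_lvl
        rows = np.flatnonzero(pos_real)
        sel = sp.coo_matrix(
            (np.ones(rows.size), (rows, order[rows])), shape=(n_pad, n_lvl)
        ).tocsr()
        a_pad = sel @ a @ sel.T
        laplacians.append(normalized_laplacian(a_pad))
        real_mask.append(pos_real)
        if lambda_max_mode == "bound":
            lmax.append(2.0)
        else:
            lmax.append(estimate_lambda_max(laplacians[-1]))

    perm = np.where(orders[0] < n_real, orders[0], -1)
    return GraphHierarchy(laplacians, perm, real_mask, lmax, n_real)


def rewire_random(adjacency: sp.spmatrix, seed: int) -> sp.csr_matrix:
    """Degree-preserving double-edge-swap rewiring (10x edge count swaps),
    applied independently per connected component so hemisphere blocks stay
    disjoint.  Graphs with no valid swap (e.g. a triangle) return unchanged."""
    a = sp.csr_matrix(adjacency)
    g = nx.from_scipy_sparse_array(a)
    rng = np.random.default_rng(seed)
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp).copy()
        m = sub.number_of_edges()
        if sub.number_of_nodes() < 4 or m < 2:
            continue
        try:
            nx.double_edge_swap(
                sub,
                nswap=10 * m,
                max_tries=200 * m,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXAlgorithmError:
            pass  # ran out of attempts; keep the swaps performed so far
        g.remove_edges_from(list(g.subgraph(comp).edges()))
        g.add_edges_from(sub.edges())
    out = nx.to_scipy_sparse_array(g, nodelist=range(a.shape[0]), format="csr")
    out = sp.csr_matrix(out, dtype=float)
    out.data[:] = 1.0
    return out
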