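"""Upper-triangle edge indexing shared across modules.

Connectivity matrices are symmetric with zero diagonal; every module that
works per-edge flattens them to the strict upper triangle in row-major
(numpy ``triu_indices``) order. Keeping one canonical order here is what
lets ground-truth masks, NBS t-maps and prediction weight vectors line up.
"""

from __future__ import annotations

import numpy as np


def n_edges(n_nodes: int) -> int:
    """Number of undirected edges on ``n_nodes`` nodes (no self-loops)."""
    return n_nodes * (n_nodes - 1) // 2


def edge_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, canonical order."""
    return np.triu_indices(n_nodes, k=1)


def edge_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """Canonical (i, j) node pairs, i < j."""
    iu, ju = edge_index(n_nodes)
    return list(zip(iu.tolist(), ju.tolist()))


def matrix_to_vec(mat: np.ndarray) -> np.ndarray:
    """Flatten a symmetric matrix (or a stack of them) to edge vectors."""
    mat = np.asarray(mat)
    n = mat.shape[-1]
    iu, ju = edge_index(n)
    return mat[..., iu, ju]


def vec_to_matrix(vec: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`matrix_to_vec`; output symmetric, zero diagonal."""
    vec = np.asarray(vec)
    iu, ju = edge_index(n_nodes)
    out = np.zeros(vec.shape[:-1] + (n_nodes, n_nodes), dtype=vec.dtype)
    out[..., iu, ju] = vec
    out[..., ju, iu] = vec
    return out


def pairs_to_edge_ids(pairs, n_nodes: int) -> np.ndarray:
    """Map (i, j) node pairs to positions in the canonical edge vector."""
    lut = np.full((n_nodes, n_nodes), -1, dtype=np.int64)
    iu, ju = edge_index(n_nodes)
    lut[iu, ju] = np.arange(len(iu))
    lut[ju, iu] = np.arange(len(iu))
    ids = []
    for i, j in pairs:
        if i == j or not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise ValueError(f"invalid edge ({i}, {j}) for {n_nodes} nodes")
        ids.append(lut[i, j])
    return np.asarray(ids, dtype=np.int64)
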