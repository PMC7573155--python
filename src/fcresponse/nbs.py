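"""Network-based statistics on connectivity-difference matrices.

An ordinary least-squares model is fit per edge with the symptom-change
score as the regressor of interest and sex, age, mean connectivity and an
intercept as nuisance terms. Edges whose one-sided t exceeds the value
corresponding to p ≤ 0.001 at the available degrees of freedom form a
suprathreshold graph; its connected components are scored by extent (edge
count) and intensity (summed suprathreshold t excess), and family-wise
error is controlled with a max-statistic permutation null built by
Freedman–Lane residual permutation (the accepted scheme for GLMs with
nuisance covariates; it reduces to simple row permutation when no
covariates are present).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components as _cc

from ._edges import edge_index, n_edges
from .exceptions import DegenerateDataError

__all__ = [
    "EdgeDesign",
    "design_from_study",
    "edge_glm",
    "t_threshold",
    "components",
    "component_stat",
    "nbs_test",
    "NBSResult",
    "Component",
]


@dataclass(frozen=True)
class EdgeDesign:
    """Design matrix for the edge-wise GLM.

    ``X`` has one row per subject; ``contrast`` picks out the regressor of
    interest; ``direction`` (+1/−1) selects the tested tail.
    """

    X: np.ndarray
    contrast: np.ndarray
    direction: int = 1
    names: tuple[str, ...] = ()

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        c = np.asarray(self.contrast, dtype=float)
        if X.ndim != 2 or c.shape != (X.shape[1],):
            raise ValueError("contrast length must match design columns")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateDataError("design matrix is rank deficient")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "contrast", c)


def design_from_study(study, score_changes=None, direction: int = 1) -> EdgeDesign:
    """Standard design: intercept, score change, sex, age, mean connectivity."""
    s = study.score_changes if score_changes is None else np.asarray(score_changes)
    cov = study.covariate_matrix()
    X = np.column_stack([np.ones(len(s)), s, cov])
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return EdgeDesign(
        X=X,
        contrast=contrast,
        direction=direction,
        names=("intercept", "score_change", "sex", "age", "mean_connectivity"),
    )


@dataclass
class EdgeGLMResult:
    t: np.ndarray
    df: int
    degenerate: np.ndarray  # edges with zero residual variance


def edge_glm(delta_stack: np.ndarray, design: EdgeDesign) -> EdgeGLMResult:
    """OLS per edge; t = contrast estimate / SE with df = n − p.

    Edges with an exact linear fit (zero residual variance) get t = ±inf
    and are flagged degenerate rather than raising.
    """
    Y = np.asarray(delta_stack, dtype=float)
    X = design.X
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("delta stack and design row counts differ")
    if n < p + 2:
        raise DegenerateDataError(f"need at least {p + 2} subjects, got {n}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    c = design.contrast
    var_c = float(c @ xtx_inv @ c)
    est = c @ beta
    # an edge fit is degenerate when its residual variance is at rounding
    # level relative to the edge's own scale (exact linear relation)
    scale = (Y**2).mean(axis=0)
    degenerate = sigma2 <= 1e-24 * np.maximum(scale, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / np.sqrt(sigma2 * var_c)
    t[degenerate] = np.sign(est[degenerate]) * np.inf
    return EdgeGLMResult(t=t, df=df, degenerate=degenerate)


def t_threshold(df: int, p: float = 0.001) -> float:
    """One-sided upper-tail t quantile at 1 − p."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.ppf(1.0 - p, df))


@dataclass(frozen=True)
class Component:
    """A connected suprathreshold subnetwork."""

    nodes: frozenset
    edges: tuple[tuple[int, int], ...]

    @property
    def extent(self) -> int:
        return len(self.edges)


def components(adjacency: np.ndarray) -> list[Component]:
    """Maximal node-connected components of a 0/1 suprathreshold graph.

    Two edges belong to the same component iff their nodes are continuously
    linked. Nodes without any suprathreshold edge are excluded. Components
    are returned sorted by their smallest node id.
    """
    adj = np.asarray(adjacency)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj)):
        raise ValueError("adjacency must have zero diagonal")
    iu, ju = np.nonzero(np.triu(adj, k=1))
    if iu.size == 0:
        return []
    n = adj.shape[0]
    g = sparse.coo_matrix(
        (np.ones(iu.size), (iu, ju)), shape=(n, n)
    ).tocsr()
    n_comp, labels = _cc(g, directed=False)
    out: dict[int, list[tuple[int, int]]] = {}
    for i, j in zip(iu.tolist(), ju.tolist()):
        out.setdefault(labels[i], []).append((i, j))
    comps = []
    for edges in out.values():
        nodes = frozenset(i for e in edges for i in e)
        comps.append(Component(nodes=nodes, edges=tuple(sorted(edges))))
    comps.sort(key=lambda c: min(c.nodes))
    return comps


def component_stat(
    component: Component,
    t_map: np.ndarray,
    t_thresh: float,
    mode: str = "extent",
) -> float:
    """Extent (edge count) or intensity (sum of t − threshold) of a component.

    ``t_map`` is a full symmetric matrix of the *signed, direction-applied*
    edge statistics.
    """
    if mode == "extent":
        return float(len(component.edges))
    if mode == "intensity":
        return float(
            sum(t_map[i, j] - t_thresh for i, j in component.edges)
        )
    raise ValueError(f"unknown mode {mode!r}")


def _max_component_stats(
    supra_ids: np.ndarray,
    ts: np.ndarray,
    t_thresh: float,
    iu: np.ndarray,
    ju: np.ndarray,
    n_nodes: int,
) -> tuple[float, float]:
    """Max extent and max intensity over components; (0, 0) if no edges."""
    if supra_ids.size == 0:
        return 0.0, 0.0
    rows = iu[supra_ids]
    cols = ju[supra_ids]
    nodes, compact = np.unique(np.concatenate([rows, cols]), return_inverse=True)
    k = nodes.size
    r = compact[: rows.size]
    c = compact[rows.size :]
    g = sparse.coo_matrix((np.ones(r.size), (r, c)), shape=(k, k))
    _, labels = _cc(g.tocsr(), directed=False)
    edge_labels = labels[r]
    extent = np.bincount(edge_labels)
    excess = ts[supra_ids] - t_thresh
    intensity = np.bincount(edge_labels, weights=excess)
    return float(extent.max()), float(intensity.max())


@dataclass
class NBSResult:
    """Observed components, their statistics, and the permutation null."""

    t: np.ndarray  # signed edge t-map (direction applied), edge order
    t_thresh: float
    df: int
    direction: int
    components: list[Component]
    extent: np.ndarray
    intensity: np.ndarray
    p_extent: np.ndarray
    p_intensity: np.ndarray
    null_max_extent: np.ndarray
    null_max_intensity: np.ndarray
    alpha: float
    n_perm: int
    seed: int
    n_nodes: int
    scheme: str = "freedman-lane"
    flags: dict = field(default_factory=dict)

    def significant(self, stat: str = "extent", alpha: float | None = None):
        """Indices of components significant at ``alpha`` for a statistic."""
        a = self.alpha if alpha is None else alpha
        p = self.p_extent if stat == "extent" else self.p_intensity
        return [i for i in range(len(self.components)) if p[i] <= a]

    def significant_edge_mask(
        self, stat: str = "extent", alpha: float | None = None
    ) -> np.ndarray:
        """Boolean edge mask (canonical order) of the significant components."""
        from ._edges import pairs_to_edge_ids

        mask = np.zeros(n_edges(self.n_nodes), dtype=bool)
        for i in self.significant(stat, alpha):
            ids = pairs_to_edge_ids(self.components[i].edges, self.n_nodes)
            mask[ids] = True
        return mask


def nbs_test(
    delta_stack: np.ndarray,
    design: EdgeDesign,
    n_nodes: int,
    p_thresh: float = 0.001,
    alpha: float = 0.10,
    n_perm: int = 10000,
    seed: int = 0,
) -> NBSResult:
    """Full NBS inference for one contrast direction.

    Permutation null: fit the reduced model (design without the contrast
    column), permute its residual rows, re-add the reduced fit, re-run the
    edge GLM and record the maximum component extent and intensity
    (Freedman–Lane). FWER p per observed component is the +1-smoothed
    fraction of null maxima at or above its statistic.
    """
    Y = np.asarray(delta_stack, dtype=float)
    n = Y.shape[0]
    if Y.shape[1] != n_edges(n_nodes):
        raise ValueError("delta stack width does not match n_nodes")
    flags: dict = {}
    if n_perm < 100:
        warnings.warn("n_perm < 100: permutation p-values are coarse")
        flags["low_n_perm"] = True

    obs = edge_glm(Y, design)
    tcrit = t_threshold(obs.df, p_thresh)
    iu, ju = edge_index(n_nodes)
    ts = design.direction * obs.t

    supra_ids = np.nonzero(ts >= tcrit)[0]
    adj = np.zeros((n_nodes, n_nodes), dtype=int)
    adj[iu[supra_ids], ju[supra_ids]] = 1
    adj += adj.T
    comps = components(adj)
    t_mat = np.zeros((n_nodes, n_nodes))
    t_mat[iu, ju] = ts
    t_mat += t_mat.T
    extent = np.array(
        [component_stat(c, t_mat, tcrit, "extent") for c in comps]
    )
    intensity = np.array(
        [component_stat(c, t_mat, tcrit, "intensity") for c in comps]
    )

    # Freedman-Lane: reduced model = all nuisance columns (contrast removed)
    keep = np.abs(design.contrast) < 1e-12
    Z = design.X[:, keep]
    if Z.shape[1]:
        gamma, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        fitted = Z @ gamma
    else:
        fitted = np.zeros_like(Y)
    resid = Y - fitted

    rng = np.random.default_rng(seed)
    null_ext = np.empty(n_perm)
    null_int = np.empty(n_perm)
    X = design.X
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = xtx_inv @ X.T
    c = design.contrast
    var_c = float(c @ xtx_inv @ c)
    df = obs.df
    for b in range(n_perm):
        perm = rng.permutation(n)
        Yb = fitted + resid[perm]
        beta = proj @ Yb
        rb = Yb - X @ beta
        sigma2 = (rb**2).sum(axis=0) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            tb = design.direction * (c @ beta) / np.sqrt(sigma2 * var_c)
        ids = np.nonzero(tb >= tcrit)[0]
        null_ext[b], null_int[b] = _max_component_stats(
            ids, tb, tcrit, iu, ju, n_nodes
        )

    def pval(obs_vals, null_max):
        return np.array(
            [
                (1.0 + np.count_nonzero(null_max >= v)) / (1.0 + n_perm)
                for v in obs_vals
            ]
        )

    return NBSResult(
        t=ts,
        t_thresh=tcrit,
        df=obs.df,
        direction=design.direction,
        components=comps,
        extent=extent,
        intensity=intensity,
        p_extent=pval(extent, null_ext),
        p_intensity=pval(intensity, null_int),
        null_max_extent=null_ext,
        null_max_intensity=null_int,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        n_nodes=n_nodes,
        flags=flags,
    )
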