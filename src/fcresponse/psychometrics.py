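"""Exploratory factor analysis of questionnaire scores.

Pipeline: sampling-adequacy screening (KMO overall, MSA per item) with
iterative removal of the least adequate item, factor count by the Kaiser
criterion, principal-axis extraction, varimax rotation and Anderson–Rubin
scoring — the classical SPSS-style route for summarizing depression-rating
items (HAM-D, BDI) into orthogonal symptom factors. Post-treatment scores
are *projected* with the weights and standardization learned on the
pre-treatment sample, never re-fit, so treatment response cannot leak into
the factor definition.

Item tables are plain pandas DataFrames (rows = subjects, columns = items,
integer scores). Correlations are Pearson on the raw integer scores.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, SingularMatrixError

__all__ = [
    "compute_kmo",
    "kaiser_count",
    "principal_axis_factor",
    "varimax",
    "anderson_rubin_weights",
    "fit_factor_model",
    "score_subjects",
    "impute_post_linear",
    "dichotomize",
    "FactorModel",
    "PAFResult",
    "ClinicalOutcome",
]

_COND_LIMIT = 1e12


def _check_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be a square correlation matrix")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have unit diagonal")
    return R


def compute_kmo(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser–Meyer–Olkin sampling adequacy and per-item MSA.

    Built from the anti-image (negative partial) correlations
    ``a_ij = -inv(R)_ij / sqrt(inv(R)_ii inv(R)_jj)``:

        KMO = sum r_ij^2 / (sum r_ij^2 + sum a_ij^2)   over i != j,

    and MSA_i the same with sums restricted to row i. Values near 1 mean
    partial correlations are small relative to raw ones, i.e., the
    correlation structure is factorable.
    """
    R = _check_corr(R)
    if np.linalg.cond(R) > _COND_LIMIT:
        raise SingularMatrixError(
            "correlation matrix is singular; remove collinear items "
            "before computing sampling adequacy"
        )
    inv = np.linalg.inv(R)
    d = np.sqrt(np.diag(inv))
    a = -inv / np.outer(d, d)
    np.fill_diagonal(a, 0.0)
    r = R - np.diag(np.diag(R))
    r2 = (r**2).sum(axis=1)
    a2 = (a**2).sum(axis=1)
    msa = r2 / (r2 + a2)
    kmo = r2.sum() / (r2.sum() + a2.sum())
    return float(kmo), msa


def kaiser_count(R: np.ndarray) -> int:
    """Number of eigenvalues of R strictly greater than 1."""
    R = _check_corr(R)
    return int((np.linalg.eigvalsh(R) > 1.0).sum())


@dataclass
class PAFResult:
    """Principal-axis extraction output with convergence diagnostics."""

    loadings: np.ndarray  # items × factors, unrotated
    communalities: np.ndarray
    converged: bool
    n_iter: int
    heywood_items: tuple[int, ...] = ()

    @property
    def heywood(self) -> bool:
        return bool(self.heywood_items)


def principal_axis_factor(
    R: np.ndarray,
    n_factors: int,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> PAFResult:
    """Iterated principal-axis factoring on the reduced correlation matrix.

    Communalities start at the squared multiple correlations
    ``1 - 1/diag(R^-1)`` and are re-estimated from the top eigenpairs of the
    reduced matrix until the largest change falls below ``tol``. The default
    convergence convention (1e-3 within 100 iterations) follows the classic
    statistical-package behavior; the communality fixed-point iteration
    converges only geometrically, so far stricter tolerances would flag
    perfectly well-behaved data as non-convergent. Non-convergence and
    Heywood cases (communality ≥ 1) are *flagged*, not raised: the fitting
    loop treats them as a signal to drop another item.
    """
    R = _check_corr(R)
    p = R.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError(f"n_factors must be in [1, {p - 1}], got {n_factors}")
    if np.linalg.cond(R) > _COND_LIMIT:
        raise SingularMatrixError("singular correlation matrix")
    h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    converged = False
    it = 0
    loadings = np.zeros((p, n_factors))
    for it in range(1, max_iter + 1):
        reduced = R.copy()
        np.fill_diagonal(reduced, h2)
        w, v = np.linalg.eigh(reduced)
        idx = np.argsort(w)[::-1][:n_factors]
        lam = np.clip(w[idx], 0.0, None)
        loadings = v[:, idx] * np.sqrt(lam)
        h2_new = (loadings**2).sum(axis=1)
        delta = np.max(np.abs(h2_new - h2))
        h2 = h2_new
        if delta < tol:
            converged = True
            break
    # deterministic column signs: largest-|loading| entry positive
    for j in range(n_factors):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    heywood = tuple(np.nonzero(h2 >= 1.0)[0].tolist())
    return PAFResult(
        loadings=loadings,
        communalities=h2,
        converged=converged and not heywood,
        n_iter=it,
        heywood_items=heywood,
    )


def varimax(
    loadings: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
    kaiser_normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix T).

    Maximizes the varimax criterion over orthogonal T (SVD algorithm), with
    Kaiser row normalization by default. ``rotated = loadings @ T`` holds
    exactly, so row sums of squared loadings (communalities) are preserved.
    One factor: identity rotation.
    """
    lam = np.asarray(loadings, dtype=float)
    p, k = lam.shape
    if k < 2:
        return lam.copy(), np.eye(k)
    h = np.sqrt((lam**2).sum(axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    a = (lam / h_safe[:, None] if kaiser_normalize else lam).copy()
    # Kaiser's pairwise planar rotations with the closed-form angle; unlike
    # the gradient/SVD fixed-point scheme this cannot stall on symmetric
    # starting configurations
    T = np.eye(k)
    for _ in range(max_iter):
        old = varimax_criterion(a)
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = a[:, i], a[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                num = 2.0 * (u @ v) - 2.0 * A * B / p
                den = (u @ u - v @ v) - (A**2 - B**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                a[:, [i, j]] = a[:, [i, j]] @ rot
                T[:, [i, j]] = T[:, [i, j]] @ rot
        if varimax_criterion(a) - old < tol:
            break
    rotated = lam @ T
    # deterministic signs, applied to T so rotated == loadings @ T stays true
    for j in range(k):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            T[:, j] = -T[:, j]
            rotated[:, j] = -rotated[:, j]
    return rotated, T


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: sum of column variances of squared loadings."""
    sq = np.asarray(loadings, float) ** 2
    return float((sq.var(axis=0)).sum())


def anderson_rubin_weights(
    R: np.ndarray,
    loadings: np.ndarray,
    uniquenesses: np.ndarray,
) -> np.ndarray:
    """Anderson–Rubin score weights W (items × factors).

    Bartlett-type weights symmetrically orthogonalized through R:
    ``W = Psi^-1 L M^(-1/2)`` with ``M = L' Psi^-1 R Psi^-1 L``. Scores
    ``S = Z W`` computed on the fitting sample (Z standardized with the same
    convention as R) then have sample covariance exactly the identity.
    """
    R = _check_corr(R)
    lam = np.asarray(loadings, float)
    psi = np.asarray(uniquenesses, float)
    if np.any(psi <= 0):
        raise DegenerateDataError("uniquenesses must be positive")
    if np.linalg.cond(R) > _COND_LIMIT:
        raise SingularMatrixError("singular correlation matrix")
    pinv_lam = lam / psi[:, None]
    m = pinv_lam.T @ R @ pinv_lam
    w_eig, v_eig = np.linalg.eigh(m)
    if np.any(w_eig <= 0):
        raise DegenerateDataError("Anderson-Rubin matrix not positive definite")
    m_inv_sqrt = (v_eig / np.sqrt(w_eig)) @ v_eig.T
    return pinv_lam @ m_inv_sqrt


@dataclass
class FactorModel:
    """Fitted factor solution plus everything needed to score new tables."""

    all_items: list[str]
    retained_items: list[str]
    dropped_items: list[tuple[str, float]]  # (item, MSA at removal)
    n_factors: int
    loadings: pd.DataFrame  # retained items × factors (rotated)
    rotation: np.ndarray  # factors × factors orthogonal
    score_weights: pd.DataFrame  # retained items × factors
    communalities: pd.Series
    kmo: float
    msa: pd.Series
    variance_explained: float
    item_means: pd.Series  # pre-sample means of retained items
    item_sds: pd.Series  # pre-sample SDs (ddof=1)
    flags: dict = field(default_factory=dict)

    def factor_names(self) -> list[str]:
        return list(self.loadings.columns)

    def to_json(self) -> str:
        payload = {
            "all_items": self.all_items,
            "retained_items": self.retained_items,
            "dropped_items": self.dropped_items,
            "n_factors": self.n_factors,
            "loadings": self.loadings.to_dict(orient="index"),
            "rotation": self.rotation.tolist(),
            "score_weights": self.score_weights.to_dict(orient="index"),
            "communalities": self.communalities.to_dict(),
            "kmo": self.kmo,
            "msa": self.msa.to_dict(),
            "variance_explained": self.variance_explained,
            "item_means": self.item_means.to_dict(),
            "item_sds": self.item_sds.to_dict(),
            "flags": self.flags,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FactorModel":
        d = json.loads(text)
        factors = [f"F{j + 1}" for j in range(d["n_factors"])]
        loadings = pd.DataFrame.from_dict(d["loadings"], orient="index")
        loadings = loadings.loc[d["retained_items"], factors]
        weights = pd.DataFrame.from_dict(d["score_weights"], orient="index")
        weights = weights.loc[d["retained_items"], factors]
        return cls(
            all_items=d["all_items"],
            retained_items=d["retained_items"],
            dropped_items=[tuple(x) for x in d["dropped_items"]],
            n_factors=d["n_factors"],
            loadings=loadings,
            rotation=np.asarray(d["rotation"]),
            score_weights=weights,
            communalities=pd.Series(d["communalities"]).loc[d["retained_items"]],
            kmo=d["kmo"],
            msa=pd.Series(d["msa"]),
            variance_explained=d["variance_explained"],
            item_means=pd.Series(d["item_means"]).loc[d["retained_items"]],
            item_sds=pd.Series(d["item_sds"]).loc[d["retained_items"]],
            flags=d.get("flags", {}),
        )


def fit_factor_model(
    pre_items: pd.DataFrame,
    kmo_min: float = 0.5,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> FactorModel:
    """Fit the full factor pipeline on a pre-treatment item table.

    Loop: compute KMO/MSA on the Pearson correlation matrix of the remaining
    items; while KMO ≤ ``kmo_min``, drop the item with the lowest MSA (ties
    broken by original item order). Once adequacy is reached, determine the
    factor count by the Kaiser criterion and extract by principal axis; if
    extraction fails to converge (or hits a Heywood case), drop the item
    with the next-lowest MSA and start over. Varimax-rotate and build
    Anderson–Rubin score weights. The removal trail is kept in the model.
    """
    if pre_items.shape[1] < 4:
        raise DegenerateDataError("need at least 4 items")
    all_items = list(pre_items.columns)
    items = list(all_items)
    dropped: list[tuple[str, float]] = []

    def drop_lowest(msa: pd.Series):
        # idxmin on a Series keeps the first minimum -> original item order
        worst = msa.idxmin()
        dropped.append((worst, float(msa[worst])))
        items.remove(worst)

    while True:
        if len(items) < 4:
            raise DegenerateDataError(
                f"item-removal loop exhausted the table; trail: {dropped}"
            )
        data = pre_items[items].astype(float)
        R = data.corr().to_numpy()
        kmo, msa_vals = compute_kmo(R)
        msa = pd.Series(msa_vals, index=items)
        if kmo <= kmo_min:
            drop_lowest(msa)
            continue
        k = kaiser_count(R)
        if k < 1:
            raise DegenerateDataError(
                "Kaiser criterion retained zero factors"
            )
        paf = principal_axis_factor(R, k, max_iter=max_iter, tol=tol)
        if not paf.converged:
            drop_lowest(msa)
            continue
        break

    rotated, T = varimax(paf.loadings)
    h2 = paf.communalities
    weights = anderson_rubin_weights(R, rotated, 1.0 - h2)

    factors = [f"F{j + 1}" for j in range(k)]
    flags = {}
    if paf.heywood_items:
        flags["heywood_items"] = [items[i] for i in paf.heywood_items]
    return FactorModel(
        all_items=all_items,
        retained_items=items,
        dropped_items=dropped,
        n_factors=k,
        loadings=pd.DataFrame(rotated, index=items, columns=factors),
        rotation=T,
        score_weights=pd.DataFrame(weights, index=items, columns=factors),
        communalities=pd.Series(h2, index=items),
        kmo=kmo,
        msa=msa,
        variance_explained=float(h2.sum() / len(items)),
        item_means=data.mean(),
        item_sds=data.std(ddof=1),
        flags=flags,
    )


def score_subjects(
    model: FactorModel, items: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Factor scores and sum score for an item table.

    Standardization uses the *pre-sample* means/SDs stored in the model, so
    post-treatment tables are projected rather than re-fit. The sum score is
    the plain sum over all original items (including any dropped from the
    factor solution — items are dropped only to optimize factors, the
    clinical total keeps its standard definition).
    """
    missing = [c for c in model.retained_items if c not in items.columns]
    if missing:
        raise KeyError(f"item table is missing retained items: {missing}")
    z = (
        items[model.retained_items].astype(float) - model.item_means
    ) / model.item_sds
    scores = pd.DataFrame(
        z.to_numpy() @ model.score_weights.to_numpy(),
        index=items.index,
        columns=model.factor_names(),
    )
    missing_sum = [c for c in model.all_items if c not in items.columns]
    if missing_sum:
        raise KeyError(f"item table is missing items for the sum: {missing_sum}")
    total = items[model.all_items].sum(axis=1)
    return scores, total


def impute_post_linear(prev_visit: int, next_visit: int) -> int:
    """Linear interpolation between adjacent visits, rounded up."""
    return math.ceil((prev_visit + next_visit) / 2)


@dataclass(frozen=True)
class ClinicalOutcome:
    """Standard clinical dichotomizations of a total-score pair."""

    pre_sum: int
    post_sum: int
    remission: bool
    response: bool


def dichotomize(pre_sum: int, post_sum: int) -> ClinicalOutcome:
    """Remission: post total ≤ 7. Response: reduction ≥ 50% of the pre total."""
    if pre_sum <= 0:
        raise DegenerateDataError("response undefined for pre_sum <= 0")
    return ClinicalOutcome(
        pre_sum=pre_sum,
        post_sum=post_sum,
        remission=post_sum <= 7,
        response=(pre_sum - post_sum) / pre_sum >= 0.5,
    )
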