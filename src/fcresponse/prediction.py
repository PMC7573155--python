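"""Cross-validated prediction of symptom change from connectivity differences.

Procedure per training set: every edge's verum−placebo connectivity
difference is correlated with the symptom-change score (partial Pearson,
controlling sex, age and mean connectivity when covariates are on); the
absolute correlations, scaled by their training-set standard deviation, are
the edge weights; each subject's FC predictor is the weighted average of
their difference matrix over the selected edges; a robust (Tukey bisquare)
linear regression of score change on the FC predictor (plus covariates) is
fit on the training set and applied to the held-out subjects.

Three edge-selection strategies: the full-sample NBS components (circular
by construction — kept to demonstrate double dipping), the NBS t threshold
recomputed on the training set only, and no threshold at all. Two
resampling schemes: leave-one-out CV (pooled held-out correlation) and
3-fold CV without role reversal (one random test fold per redraw, median
correlation over redraws).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._edges import n_edges, vec_to_matrix
from .exceptions import DegenerateDataError
from .nbs import EdgeDesign, NBSResult, edge_glm, t_threshold

__all__ = [
    "WeightVector",
    "edge_weights",
    "select_edges",
    "fc_predictor",
    "fit_response_model",
    "ResponseModel",
    "loocv",
    "repeated_3fold",
    "insample_circular",
    "sidak_adjust",
    "median_weight_matrix",
    "top_nodes_edges",
    "roc_metrics",
    "RocMetrics",
    "CVResult",
]


# ---------------------------------------------------------------------------
# edge weights and the FC predictor
# ---------------------------------------------------------------------------


@dataclass
class WeightVector:
    """Per-edge weights on one training set."""

    weights: np.ndarray  # full-length edge vector, zero outside the mask
    mask: np.ndarray  # boolean selection mask
    r_partial: np.ndarray  # raw (partial) correlations on masked edges' slots
    scale_sd: float  # SD of absolute correlations used for scaling
    signed: bool
    train_ids: np.ndarray | None = None
    flags: dict = field(default_factory=dict)


def _residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


def edge_weights(
    delta_stack: np.ndarray,
    score_change: np.ndarray,
    covariates: np.ndarray | None = None,
    signed: bool = False,
    mask: np.ndarray | None = None,
    train_ids: np.ndarray | None = None,
) -> WeightVector:
    """Training-set edge weights: scaled absolute partial correlations.

    Partial correlation of each edge's difference with the score change,
    controlling the covariates (plain Pearson when none — the reduced
    models); weight = |r| / SD(all |r| within the selection), sample SD.
    Signed mode keeps the sign of r but uses the same scale.
    """
    Y = np.asarray(delta_stack, dtype=float)
    s = np.asarray(score_change, dtype=float)
    n, m = Y.shape
    if s.shape != (n,):
        raise ValueError("score_change length mismatch")
    if s.std() == 0:
        raise DegenerateDataError("zero-variance score change")
    if mask is None:
        mask = np.ones(m, dtype=bool)
    C = np.ones((n, 1))
    if covariates is not None:
        C = np.column_stack([C, np.asarray(covariates, dtype=float)])
    ys = _residualize(s, C)
    if ys.std() <= 1e-12 * max(1.0, s.std()):
        raise DegenerateDataError(
            "score change fully explained by covariates; "
            "partial correlations undefined"
        )
    Yr = _residualize(Y[:, mask], C)
    num = Yr.T @ ys
    den = np.linalg.norm(Yr, axis=0) * np.linalg.norm(ys)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    r = np.clip(r, -1.0, 1.0)

    a = np.abs(r)
    flags = {}
    sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
    if sd == 0.0:
        flags["unscaled"] = True
        scaled = r if signed else a
        sd_used = 1.0
    else:
        scaled = (r if signed else a) / sd
        sd_used = sd
    w = np.zeros(m)
    w[mask] = scaled
    rfull = np.zeros(m)
    rfull[mask] = r
    return WeightVector(
        weights=w,
        mask=np.asarray(mask, bool).copy(),
        r_partial=rfull,
        scale_sd=sd_used,
        signed=signed,
        train_ids=None if train_ids is None else np.asarray(train_ids),
        flags=flags,
    )


def select_edges(
    strategy: str,
    n_edges_total: int,
    nbs_result: NBSResult | None = None,
    t_map: np.ndarray | None = None,
    t_thresh: float | None = None,
    direction: int = 1,
    stat: str = "extent",
    alpha: float | None = None,
) -> np.ndarray:
    """Edge-selection mask for one of the three strategies.

    ``"nbs"``: edges of the (full-sample) NBS significant components —
    deliberately circular, for the double-dipping demonstration.
    ``"threshold"``: edges whose training-set t passes the threshold in the
    contrast direction. ``"all"``: every edge.
    """
    if strategy == "all":
        return np.ones(n_edges_total, dtype=bool)
    if strategy == "threshold":
        if t_map is None or t_thresh is None:
            raise ValueError("strategy 'threshold' needs t_map and t_thresh")
        return (direction * np.asarray(t_map)) >= t_thresh
    if strategy == "nbs":
        if nbs_result is None:
            raise ValueError("strategy 'nbs' needs an NBSResult")
        mask = nbs_result.significant_edge_mask(stat=stat, alpha=alpha)
        if mask.size != n_edges_total:
            raise ValueError("NBSResult node count does not match")
        return mask
    raise ValueError(f"unknown strategy {strategy!r}")


def fc_predictor(delta: np.ndarray, weights: WeightVector) -> np.ndarray:
    """Weighted average of the difference matrix over the selected edges.

    Accepts a single edge vector or a (subjects × edges) stack. Invariant to
    uniform rescaling of the weights, so the SD scaling affects reported
    weight magnitudes, never predictions.
    """
    d = np.atleast_2d(np.asarray(delta, dtype=float))
    mask = weights.mask
    if not mask.any():
        raise DegenerateDataError("empty edge selection: no prediction")
    w = weights.weights[mask]
    denom = w.sum()
    if denom == 0:
        raise DegenerateDataError("weights sum to zero: no prediction")
    out = d[:, mask] @ w / denom
    return out if np.asarray(delta).ndim == 2 else float(out[0])


# ---------------------------------------------------------------------------
# robust regression
# ---------------------------------------------------------------------------


@dataclass
class ResponseModel:
    """Bisquare-weighted linear model of score change on the FC predictor."""

    coef: np.ndarray  # intercept first
    irls_weights: np.ndarray
    scale: float
    converged: bool
    n_iter: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.coef[0] + X @ self.coef[1:]


def fit_response_model(
    predictors: np.ndarray,
    y: np.ndarray,
    tuning: float = 4.685,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> ResponseModel:
    """IRLS with the Tukey bisquare weight function.

    Initialized from ordinary least squares; the scale is re-estimated every
    iteration as MAD/0.6745 of the current residuals. The 4.685 tuning
    constant gives 95% efficiency under Gaussian errors. A perfect linear
    fit (zero residual scale) returns the least-squares solution directly.
    Non-convergence returns the last iterate, flagged.
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    if X.shape[0] == 1 and X.size == len(y):
        X = X.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    p = A.shape[1]
    if n <= p + 1:
        raise DegenerateDataError(f"need more than {p + 1} observations")
    if np.any(X.std(axis=0) == 0):
        raise DegenerateDataError("constant predictor column")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    converged = False
    it = 0
    w = np.ones(n)
    scale = 0.0
    for it in range(1, max_iter + 1):
        resid = y - A @ beta
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = mad / 0.6745
        if scale <= 1e-12 * max(1.0, np.abs(y).max()):
            converged = True  # essentially exact fit
            break
        u = resid / (tuning * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0 or np.count_nonzero(w) <= p:
            warnings.warn("bisquare downweighted almost all points")
            break
        Aw = A * w[:, None]
        beta_new = np.linalg.solve(A.T @ Aw, Aw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol * max(
            1.0, np.max(np.abs(beta))
        ):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return ResponseModel(
        coef=beta, irls_weights=w, scale=scale, converged=converged, n_iter=it
    )


# ---------------------------------------------------------------------------
# cross-validation schemes
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Output of one cross-validated prediction run."""

    scheme: str  # "loocv" | "repeated3fold"
    strategy: str
    with_covariates: bool
    signed: bool
    predictions: np.ndarray  # pooled held-out predictions (LOOCV) or last
    actuals: np.ndarray
    r: float  # pooled r (LOOCV) or median r over redraws (3CV)
    p: float  # matching two-sided Pearson p (median p for 3CV)
    r_per_redraw: np.ndarray | None = None
    p_per_redraw: np.ndarray | None = None
    pooled_predictions: np.ndarray | None = None  # per-subject mean over redraws
    weight_stack: np.ndarray | None = None  # folds/redraws × edges
    n_skipped: int = 0
    seed: int | None = None
    flags: dict = field(default_factory=dict)

    @property
    def median_r(self) -> float:
        if self.r_per_redraw is not None:
            return float(np.median(self.r_per_redraw))
        return self.r


def _prepare_target(study, target):
    y = study.score_changes if target is None else np.asarray(target, float)
    if y.shape != (study.n_subjects,):
        raise ValueError("target length must equal the subject count")
    return y


def _fold_fit_predict(
    delta, y, cov, train, test, strategy, nbs_result, p_thresh, direction, signed
):
    """Fit weights + robust model on ``train``; return test predictions and
    the full-length weight vector, or None when the fold is degenerate."""
    cov_tr = None if cov is None else cov[train]
    m = delta.shape[1]
    if strategy == "threshold":
        n_nodes = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        Xcols = [np.ones(train.size), y[train]]
        if cov is not None:
            Xcols.append(cov_tr)
        X = np.column_stack(Xcols)
        contrast = np.zeros(X.shape[1])
        contrast[1] = 1.0
        design = EdgeDesign(X=X, contrast=contrast, direction=direction)
        res = edge_glm(delta[train], design)
        tcrit = t_threshold(res.df, p_thresh)
        mask = select_edges(
            "threshold", m, t_map=res.t, t_thresh=tcrit, direction=direction
        )
    elif strategy == "nbs":
        mask = select_edges("nbs", m, nbs_result=nbs_result)
    else:
        mask = select_edges("all", m)
    if not mask.any():
        return None
    wv = edge_weights(
        delta[train], y[train], covariates=cov_tr, signed=signed, mask=mask,
        train_ids=train,
    )
    fc_tr = fc_predictor(delta[train], wv)
    fc_te = fc_predictor(delta[test], wv)
    Xtr = fc_tr if cov is None else np.column_stack([fc_tr, cov_tr])
    Xte = (
        np.atleast_2d(fc_te).T
        if cov is None
        else np.column_stack([fc_te, cov[test]])
    )
    if np.std(fc_tr) == 0:
        return None
    model = fit_response_model(Xtr, y[train])
    pred = model.predict(Xte)
    return pred, wv.weights


def loocv(
    study,
    target=None,
    strategy: str = "all",
    with_covariates: bool = True,
    signed: bool = False,
    nbs_result: NBSResult | None = None,
    p_thresh: float = 0.001,
    direction: int = 1,
    store_weights: bool = True,
) -> CVResult:
    """Leave-one-out CV; r is the Pearson correlation of the n pooled
    held-out predictions with the actual changes."""
    y = _prepare_target(study, target)
    n = study.n_subjects
    if n < 10:
        raise DegenerateDataError("LOOCV needs at least 10 subjects")
    delta = study.delta_stack
    cov = study.covariate_matrix() if with_covariates else None
    preds = np.full(n, np.nan)
    weights = []
    skipped = 0
    for i in range(n):
        train = np.array([j for j in range(n) if j != i])
        test = np.array([i])
        out = _fold_fit_predict(
            delta, y, cov, train, test, strategy, nbs_result, p_thresh,
            direction, signed,
        )
        if out is None:
            skipped += 1
            continue
        preds[i], w = out[0][0], out[1]
        if store_weights:
            weights.append(w)
    ok = ~np.isnan(preds)
    if ok.sum() < 3:
        raise DegenerateDataError("too many degenerate folds for LOOCV")
    r, p = stats.pearsonr(preds[ok], y[ok])
    return CVResult(
        scheme="loocv",
        strategy=strategy,
        with_covariates=with_covariates,
        signed=signed,
        predictions=preds,
        actuals=y,
        r=float(r),
        p=float(p),
        weight_stack=np.array(weights) if weights else None,
        n_skipped=skipped,
    )


def repeated_3fold(
    study,
    target=None,
    strategy: str = "all",
    with_covariates: bool = True,
    signed: bool = False,
    nbs_result: NBSResult | None = None,
    p_thresh: float = 0.001,
    direction: int = 1,
    n_redraws: int = 1000,
    seed: int = 0,
    store_weights: bool = True,
) -> CVResult:
    """Repeated 3-fold CV without role reversal.

    Per redraw the subjects are randomly split into three folds; one fold,
    chosen at random, is the test set and the other two train — the test
    set is never the larger share and folds are not rotated. The summary is
    the median per-redraw correlation.
    """
    y = _prepare_target(study, target)
    n = study.n_subjects
    if n < 12:
        raise DegenerateDataError("3-fold CV needs at least 12 subjects")
    delta = study.delta_stack
    cov = study.covariate_matrix() if with_covariates else None
    rng = np.random.default_rng(seed)
    rs, ps = [], []
    weights = []
    skipped = 0
    preds = actual = np.empty(0)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for _ in range(n_redraws):
        order = rng.permutation(n)
        folds = np.array_split(order, 3)
        test = folds[rng.integers(3)]
        train = np.setdiff1d(order, test)
        out = _fold_fit_predict(
            delta, y, cov, train, test, strategy, nbs_result, p_thresh,
            direction, signed,
        )
        if out is None:
            skipped += 1
            continue
        pred, w = out
        if np.std(pred) == 0 or np.std(y[test]) == 0:
            skipped += 1
            continue
        r, p = stats.pearsonr(pred, y[test])
        rs.append(r)
        ps.append(p)
        preds, actual = pred, y[test]
        pred_sum[test] += pred
        pred_cnt[test] += 1
        if store_weights:
            weights.append(w)
    if not rs:
        raise DegenerateDataError("all redraws degenerate")
    rs = np.asarray(rs)
    ps = np.asarray(ps)
    return CVResult(
        scheme="repeated3fold",
        strategy=strategy,
        with_covariates=with_covariates,
        signed=signed,
        predictions=preds,
        actuals=actual,
        r=float(np.median(rs)),
        p=float(np.median(ps)),
        r_per_redraw=rs,
        p_per_redraw=ps,
        pooled_predictions=np.where(pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan),
        weight_stack=np.array(weights) if weights else None,
        n_skipped=skipped,
        seed=seed,
    )


def insample_circular(
    study,
    target=None,
    nbs_result: NBSResult | None = None,
    scheme: str = "loocv",
    **kwargs,
) -> CVResult:
    """Strategy-A CV with edges fixed from full-sample NBS components.

    An obvious case of double dipping — the held-out subjects already
    influenced the edge selection. Provided, and always labeled circular,
    purely to demonstrate the inflation against the honest strategies.
    """
    if nbs_result is None:
        raise ValueError("insample_circular requires a full-sample NBSResult")
    runner = loocv if scheme == "loocv" else repeated_3fold
    res = runner(
        study, target=target, strategy="nbs", nbs_result=nbs_result, **kwargs
    )
    res.flags["circular"] = True
    return res


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiplicity adjustment 1 − (1 − p)^m, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, -np.expm1(m * np.log1p(-p)))) if p < 1 else 1.0


def median_weight_matrix(cv: CVResult, n_nodes: int) -> np.ndarray:
    """Per-edge median weight across folds/redraws, as a full matrix.

    Edges not selected in a fold contribute weight 0, so an edge selected in
    fewer than half the redraws has median 0 — the typical picture for
    thresholded 3-fold CV.
    """
    if cv.weight_stack is None or len(cv.weight_stack) == 0:
        raise ValueError("CVResult carries no stored weights")
    med = np.median(cv.weight_stack, axis=0)
    return vec_to_matrix(med, n_nodes)


def top_nodes_edges(
    weight_matrix: np.ndarray, k: int = 10
) -> tuple[np.ndarray, list[tuple[tuple[int, int], float]]]:
    """Top-k nodes by adjacent-weight sum and top-k single edges.

    Ties are broken by index (lower node/edge first).
    """
    W = np.asarray(weight_matrix, dtype=float)
    n = W.shape[0]
    sums = W.sum(axis=1)
    node_order = np.lexsort((np.arange(n), -sums))
    top_nodes = node_order[: min(k, n)]
    iu, ju = np.triu_indices(n, k=1)
    vals = W[iu, ju]
    edge_order = np.lexsort((np.arange(vals.size), -vals))
    top_edges = [
        ((int(iu[e]), int(ju[e])), float(vals[e]))
        for e in edge_order[: min(k, vals.size)]
    ]
    return top_nodes, top_edges


@dataclass
class RocMetrics:
    """Post-hoc classification metrics of threshold-free predictions."""

    auc_remission: float
    auc_response: float
    bac_remission: float
    bac_response: float
    flags: dict = field(default_factory=dict)


def _auc(score: np.ndarray, label: np.ndarray) -> float:
    """Mann-Whitney AUC of a continuous score against a binary label,
    ties counted one half."""
    pos = label.astype(bool)
    n1, n0 = pos.sum(), (~pos).sum()
    ranks = stats.rankdata(score)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _bac(pred_label: np.ndarray, label: np.ndarray) -> float:
    pos = label.astype(bool)
    sens = np.mean(pred_label[pos])
    spec = np.mean(~pred_label[~pos].astype(bool))
    return float((sens + spec) / 2)


def roc_metrics(
    predicted_reduction: np.ndarray,
    pre_sum: np.ndarray,
    remission: np.ndarray,
    response: np.ndarray,
) -> RocMetrics:
    """AUC and balanced accuracy of remission/response from continuous
    predicted score reductions.

    AUC is the rank (Mann–Whitney) statistic of the predicted reduction
    against each outcome. For balanced accuracy the clinical cutoffs are
    applied to the predictions themselves: predicted post = pre −
    predicted reduction; predicted remission iff predicted post ≤ 7,
    predicted response iff predicted reduction ≥ half the pre total.
    """
    pred = np.asarray(predicted_reduction, dtype=float)
    pre = np.asarray(pre_sum, dtype=float)
    rem = np.asarray(remission, dtype=bool)
    resp = np.asarray(response, dtype=bool)
    flags = {}

    def safe_auc(label, name):
        if label.all() or not label.any():
            flags[name] = "single-class outcome; AUC undefined"
            return float("nan")
        return _auc(pred, label)

    pred_post = pre - pred
    pred_rem = pred_post <= 7
    pred_resp = pred >= 0.5 * pre

    def safe_bac(pl, label, name):
        if label.all() or not label.any():
            flags[name] = "single-class outcome; BAC undefined"
            return float("nan")
        return _bac(pl, label)

    return RocMetrics(
        auc_remission=safe_auc(rem, "auc_remission"),
        auc_response=safe_auc(resp, "auc_response"),
        bac_remission=safe_bac(pred_rem, rem, "bac_remission"),
        bac_response=safe_bac(pred_resp, resp, "bac_response"),
        flags=flags,
    )
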