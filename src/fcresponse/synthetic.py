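"""Synthetic questionnaire, covariate and connectivity data with known truth.

The study design being emulated: depressed patients are scanned twice under a
drug (verum) and a saline (placebo) challenge, yielding one node-by-node
Fisher-z connectivity matrix per condition per subject; depression severity
is rated on multi-item questionnaires before and after several weeks of
treatment. The generators here produce

* item tables with a planted orthogonal factor structure (so the factor
  pipeline can be checked against ground truth),
* per-subject verum/placebo connectivity matrices in which the verum minus
  placebo difference on a planted, connected edge set correlates with the
  symptom-change score at a controlled effect size, and
* a small 4-D NIfTI fixture with planted ROI signals and nuisance components
  for exercising the time-series processing chain.

Everything is deterministic under the spec's seed and every generator returns
its ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._edges import matrix_to_vec, n_edges, pairs_to_edge_ids, vec_to_matrix
from .exceptions import InvalidSpecError


def simple_structure_loadings(
    n_items: int,
    n_factors: int,
    primary: float = 0.75,
    cross: float = 0.0,
) -> np.ndarray:
    """Loading matrix with items assigned round-robin to factors.

    Each item loads ``primary`` on exactly one factor and ``cross`` on the
    others — the idealized simple structure varimax aims for.
    """
    lam = np.full((n_items, n_factors), cross, dtype=float)
    for i in range(n_items):
        lam[i, i % n_factors] = primary
    return lam


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    The defaults mirror the emulated design: a HAM-D-like 17-item
    questionnaire with six latent symptom factors, and a two-condition
    connectivity study. ``effect_rho`` is the population correlation between
    the verum−placebo connectivity difference on each planted edge and the
    per-subject symptom-change score; ``background_sd`` is the z-unit scale
    of both the placebo matrices and the condition-difference noise.
    """

    n_subjects: int = 30
    n_nodes: int = 60
    n_items: int = 17
    n_factors: int = 6
    loading_matrix: np.ndarray | None = None
    item_noise_sd: float = 0.6
    planted_edges: tuple[tuple[int, int], ...] = ()
    effect_rho: float = 0.0
    background_sd: float = 0.3
    covariate_effects: tuple[float, float] = (0.0, 0.0)
    seed: int = 0
    item_range: tuple[int, int] = (0, 4)
    post_factor_shift: tuple[float, ...] | None = None
    factor_change_sd: float = 1.0
    age_range: tuple[float, float] = (20.0, 55.0)

    def __post_init__(self):
        if self.loading_matrix is not None:
            lam = np.asarray(self.loading_matrix, dtype=float)
            if lam.shape != (self.n_items, self.n_factors):
                raise InvalidSpecError(
                    f"loading_matrix shape {lam.shape} != "
                    f"({self.n_items}, {self.n_factors})"
                )
            if np.linalg.matrix_rank(lam) < self.n_factors:
                raise InvalidSpecError("loading_matrix is rank deficient")
            object.__setattr__(self, "loading_matrix", lam)
        if not -1.0 <= self.effect_rho <= 1.0:
            raise InvalidSpecError("effect_rho must lie in [-1, 1]")
        if self.item_noise_sd < 0 or self.background_sd <= 0:
            raise InvalidSpecError("noise SDs must be positive")
        if self.planted_edges:
            self._validate_planted()

    def _validate_planted(self):
        g = nx.Graph()
        for i, j in self.planted_edges:
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes) or i == j:
                raise InvalidSpecError(f"planted edge ({i}, {j}) out of range")
            g.add_edge(i, j)
        if not nx.is_connected(g):
            raise InvalidSpecError(
                "planted_edges must induce a single connected component"
            )

    def loadings(self) -> np.ndarray:
        if self.loading_matrix is not None:
            return self.loading_matrix
        return simple_structure_loadings(self.n_items, self.n_factors)


def planted_component(
    n_edges_planted: int, n_nodes: int, start: int = 0
) -> tuple[tuple[int, int], ...]:
    """A connected planted edge set: a hub-and-spokes star at ``start``.

    A star of k edges touches k + 1 nodes and is one connected component;
    because every edge shares the hub, any subset of its edges is still
    connected — the planted effect models one coherent subnetwork around a
    hub region, not a chain whose detected pieces could fall apart.
    """
    if start + n_edges_planted >= n_nodes:
        raise InvalidSpecError("star does not fit on the node set")
    return tuple(
        (start, start + 1 + k) for k in range(n_edges_planted)
    )


# ---------------------------------------------------------------------------
# questionnaire generation
# ---------------------------------------------------------------------------


@dataclass
class QuestionnaireData:
    """Pre/post item tables plus the latent ground truth behind them."""

    pre: pd.DataFrame
    post: pd.DataFrame
    pre_continuous: pd.DataFrame
    post_continuous: pd.DataFrame
    factors_pre: np.ndarray
    factors_post: np.ndarray
    item_range: tuple[int, int]

    @property
    def factor_change(self) -> np.ndarray:
        """True per-subject latent factor change (post − pre)."""
        return self.factors_post - self.factors_pre

    @property
    def item_ids(self) -> list[str]:
        return list(self.pre.columns)


def _discretize(x: np.ndarray, item_range: tuple[int, int]) -> np.ndarray:
    lo, hi = item_range
    mid = (lo + hi) / 2.0
    vals = np.rint(mid + x)
    return np.clip(vals, lo, hi).astype(int)


def gen_questionnaire(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> QuestionnaireData:
    """Generate pre- and post-treatment item tables.

    Pre items are ``loadings @ factors + noise`` with orthogonal
    standard-normal latent factors, discretized by rounding and clipping to
    the declared item range (the continuous values are returned as well for
    calibration tests). Post items come from shifted latent factors:
    ``F_post = F_pre + shift + innovation`` so that true factor-change
    values exist for every subject.
    """
    if spec.n_subjects < 3 * spec.n_factors:
        raise InvalidSpecError(
            f"need n_subjects >= 3 * n_factors "
            f"({spec.n_subjects} < {3 * spec.n_factors})"
        )
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lam = spec.loadings()
    n, k = spec.n_subjects, spec.n_factors

    f_pre = rng.standard_normal((n, k))
    noise = rng.standard_normal((n, spec.n_items)) * spec.item_noise_sd
    x_pre = f_pre @ lam.T + noise

    shift = (
        np.full(k, -0.8)
        if spec.post_factor_shift is None
        else np.asarray(spec.post_factor_shift, dtype=float)
    )
    innovation = rng.standard_normal((n, k)) * spec.factor_change_sd
    f_post = f_pre + shift + innovation
    noise_post = rng.standard_normal((n, spec.n_items)) * spec.item_noise_sd
    x_post = f_post @ lam.T + noise_post

    items = [f"item{j + 1:02d}" for j in range(spec.n_items)]
    subjects = [f"s{j + 1:03d}" for j in range(n)]

    def frame(a):
        return pd.DataFrame(a, index=subjects, columns=items)

    return QuestionnaireData(
        pre=frame(_discretize(x_pre, spec.item_range)),
        post=frame(_discretize(x_post, spec.item_range)),
        pre_continuous=frame(x_pre),
        post_continuous=frame(x_post),
        factors_pre=f_pre,
        factors_post=f_post,
        item_range=spec.item_range,
    )


# ---------------------------------------------------------------------------
# connectivity study generation
# ---------------------------------------------------------------------------


@dataclass
class StudySet:
    """One analysis bundle: per-subject condition matrices plus covariates.

    ``verum``/``placebo`` are (n_subjects, n_nodes, n_nodes) stacks of
    symmetric zero-diagonal z-matrices. ``truth_edge_mask`` marks the
    planted edges in canonical upper-triangle order.
    """

    verum: np.ndarray
    placebo: np.ndarray
    covariates: pd.DataFrame
    score_changes: np.ndarray
    truth_edge_mask: np.ndarray
    n_nodes: int

    @property
    def n_subjects(self) -> int:
        return self.verum.shape[0]

    @property
    def delta_stack(self) -> np.ndarray:
        """Verum − placebo differences as a (subjects × edges) stack."""
        return matrix_to_vec(self.verum - self.placebo)

    @property
    def mean_connectivity(self) -> np.ndarray:
        """Per-subject mean z over all edges, pooled over both conditions."""
        zv = matrix_to_vec(self.verum)
        zp = matrix_to_vec(self.placebo)
        return np.concatenate([zv, zp], axis=1).mean(axis=1)

    def covariate_matrix(self) -> np.ndarray:
        """Columns sex, age, mean connectivity — the standard nuisance set."""
        return np.column_stack(
            [
                self.covariates["sex"].to_numpy(float),
                self.covariates["age"].to_numpy(float),
                self.mean_connectivity,
            ]
        )


def _correlated(target_corr: float, anchor: np.ndarray, rng) -> np.ndarray:
    z = (anchor - anchor.mean()) / anchor.std()
    eps = rng.standard_normal(anchor.shape)
    return target_corr * z + np.sqrt(max(0.0, 1 - target_corr**2)) * eps


def gen_covariates(
    spec: SyntheticSpec,
    score_changes: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Balanced binary sex and uniform age, optionally associated with the
    score change at the correlations in ``spec.covariate_effects``."""
    n = spec.n_subjects
    c_age, c_sex = spec.covariate_effects
    lo, hi = spec.age_range
    if c_age:
        latent = _correlated(c_age, score_changes, rng)
        age = lo + (hi - lo) * (
            np.argsort(np.argsort(latent)) + 0.5
        ) / n
    else:
        age = rng.uniform(lo, hi, size=n)
    sex = np.zeros(n, dtype=int)
    sex[: n // 2] = 1
    if c_sex:
        order = np.argsort(_correlated(c_sex, score_changes, rng))
        sex = sex[np.argsort(order)]
    else:
        rng.shuffle(sex)
    return pd.DataFrame(
        {"age": age, "sex": sex},
        index=[f"s{j + 1:03d}" for j in range(n)],
    )


def gen_connectivity_study(
    spec: SyntheticSpec,
    score_changes: np.ndarray,
    rng: np.random.Generator | None = None,
) -> StudySet:
    """Generate per-subject verum and placebo connectivity z-matrices.

    Placebo matrices are symmetric background noise with zero diagonal. The
    verum matrix adds a condition-difference term: i.i.d. noise of the same
    scale on every edge, and on the planted edges a component constructed so
    that the population correlation between the edge's verum−placebo
    difference and ``score_changes`` equals ``spec.effect_rho``. The planted
    effect thus enters only the verum condition, and non-planted edges keep
    nonzero difference variance so edge-wise regressions are well defined.
    """
    n = spec.n_subjects
    if n <= 0:
        raise InvalidSpecError("n_subjects must be positive")
    score_changes = np.asarray(score_changes, dtype=float)
    if score_changes.shape != (n,):
        raise InvalidSpecError(
            f"score_changes length {score_changes.shape} != n_subjects {n}"
        )
    if spec.effect_rho != 0 and score_changes.std() == 0:
        raise InvalidSpecError(
            "effect_rho requested with zero-variance score_changes"
        )
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng

    m = n_edges(spec.n_nodes)
    sd = spec.background_sd
    placebo_vec = rng.standard_normal((n, m)) * sd
    delta_vec = rng.standard_normal((n, m)) * sd

    mask = np.zeros(m, dtype=bool)
    if spec.planted_edges:
        ids = pairs_to_edge_ids(spec.planted_edges, spec.n_nodes)
        mask[ids] = True
        rho = spec.effect_rho
        s = (score_changes - score_changes.mean()) / score_changes.std()
        eps = rng.standard_normal((n, ids.size))
        delta_vec[:, ids] = sd * (
            rho * s[:, None] + np.sqrt(1 - rho**2) * eps
        )

    placebo = vec_to_matrix(placebo_vec, spec.n_nodes)
    verum = vec_to_matrix(placebo_vec + delta_vec, spec.n_nodes)
    covariates = gen_covariates(spec, score_changes, rng)
    return StudySet(
        verum=verum,
        placebo=placebo,
        covariates=covariates,
        score_changes=score_changes,
        truth_edge_mask=mask,
        n_nodes=spec.n_nodes,
    )


def gen_null_study(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> StudySet:
    """Global-null study: standard-normal score changes, no planted effect."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    scores = rng.standard_normal(spec.n_subjects)
    null_spec = (
        spec
        if not spec.planted_edges
        else SyntheticSpec(
            **{
                **_spec_dict(spec),
                "planted_edges": (),
                "effect_rho": 0.0,
            }
        )
    )
    return gen_connectivity_study(null_spec, scores, rng)


def gen_effect_study(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> StudySet:
    """Planted-effect study with standard-normal score changes."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    scores = rng.standard_normal(spec.n_subjects)
    return gen_connectivity_study(spec, scores, rng)


def _spec_dict(spec: SyntheticSpec) -> dict:
    return {f: getattr(spec, f) for f in spec.__dataclass_fields__}


# ---------------------------------------------------------------------------
# NIfTI fixture
# ---------------------------------------------------------------------------


@dataclass
class NiftiFixture:
    """4-D volume with planted ROI signals, nuisance components and masks."""

    img: "object"  # nibabel Nifti1Image; typed loosely to keep import lazy
    roi_signals: np.ndarray  # (n_rois, n_frames) ground truth
    nuisance_signals: np.ndarray  # (n_nuisance, n_frames)
    wm_mask: np.ndarray  # boolean grids
    csf_mask: np.ndarray
    tr: float

    @property
    def data(self) -> np.ndarray:
        return np.asarray(self.img.dataobj)


def centered_affine(grid_shape: Sequence[int], spacing: float = 2.0) -> np.ndarray:
    """Affine for an isotropic grid with mm origin at the grid center."""
    shape = np.asarray(grid_shape, dtype=float)
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * spacing
    aff[:3, 3] = -spacing * (shape - 1) / 2.0
    return aff


def gen_nifti_fixture(
    n_frames: int,
    grid_shape: tuple[int, int, int],
    tr: float,
    roi_centers_mm: np.ndarray,
    *,
    roi_signals: np.ndarray | None = None,
    nuisance_signals: np.ndarray | None = None,
    nuisance_roi_coupling: np.ndarray | None = None,
    noise_sd: float = 0.0,
    n_tissue_voxels: int = 40,
    seed: int = 0,
) -> NiftiFixture:
    """Build a small 4-D NIfTI volume with known signal content.

    Voxels inside 10 mm-diameter spheres around the ROI centers carry the
    (given or generated) ROI signals; two disjoint tissue masks ("wm" and
    "csf") outside the spheres carry linear mixtures of the nuisance
    signals; optional coupling leaks the nuisance into the ROI voxels too,
    which is what the simultaneous-cleaning test exercises. White noise is
    added everywhere at ``noise_sd``.
    """
    import nibabel as nib

    from .connectivity import GridSpec, build_sphere_rois

    rng = np.random.default_rng(seed)
    grid = GridSpec(shape=tuple(grid_shape), affine=centered_affine(grid_shape))
    rois = build_sphere_rois(np.asarray(roi_centers_mm, float), grid)
    n_rois = len(rois.voxel_indices)

    if roi_signals is None:
        raw = rng.standard_normal((n_rois, n_frames))
        kernel = np.hanning(9)
        kernel /= kernel.sum()
        roi_signals = np.apply_along_axis(
            lambda s: np.convolve(s, kernel, mode="same"), 1, raw
        )
        roi_signals = (
            roi_signals - roi_signals.mean(1, keepdims=True)
        ) / roi_signals.std(1, keepdims=True)
    roi_signals = np.asarray(roi_signals, dtype=float)
    if nuisance_signals is None:
        nuisance_signals = np.empty((0, n_frames))
    nuisance_signals = np.atleast_2d(np.asarray(nuisance_signals, dtype=float))

    data = np.zeros(tuple(grid_shape) + (n_frames,), dtype=float)
    sphere = np.zeros(grid_shape, dtype=bool)
    for vox in rois.voxel_indices:
        sphere[tuple(vox.T)] = True
    for r, vox in enumerate(rois.voxel_indices):
        data[tuple(vox.T)] += roi_signals[r]

    free = np.argwhere(~sphere)
    rng.shuffle(free)
    half = n_tissue_voxels // 2
    wm_vox = free[:half]
    csf_vox = free[half : 2 * half]
    wm_mask = np.zeros(grid_shape, dtype=bool)
    csf_mask = np.zeros(grid_shape, dtype=bool)
    wm_mask[tuple(wm_vox.T)] = True
    csf_mask[tuple(csf_vox.T)] = True

    if nuisance_signals.shape[0]:
        for vox_list in (wm_vox, csf_vox):
            load = rng.uniform(0.5, 1.5, size=(len(vox_list), nuisance_signals.shape[0]))
            data[tuple(vox_list.T)] += load @ nuisance_signals
        if nuisance_roi_coupling is not None:
            coupling = np.atleast_2d(np.asarray(nuisance_roi_coupling, float))
            # coupling[q, r]: weight of nuisance q in ROI r's voxels
            for r, vox in enumerate(rois.voxel_indices):
                data[tuple(vox.T)] += coupling[:, r] @ nuisance_signals

    if noise_sd > 0:
        data += rng.standard_normal(data.shape) * noise_sd

    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms((2.0, 2.0, 2.0, tr))
    return NiftiFixture(
        img=img,
        roi_signals=roi_signals,
        nuisance_signals=nuisance_signals,
        wm_mask=wm_mask,
        csf_mask=csf_mask,
        tr=tr,
    )
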