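"""Two-class OPLS-DA with VIP scores, cross-validated Q2 and permutation test.

Orthogonal projections to latent structures: variation in X orthogonal
to the class vector y is peeled off component by component (Trygg-Wold
deflation), then a single predictive component is fitted to what
remains. With ``n_orth=0`` this reduces to one-component PLS1-DA.

Feature influence is summarised by VIP (variable importance in
projection) on the predictive component, normalised so that the mean
squared VIP over features equals 1; VIP > 1 marks influential features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix
from .screen import DiffTable


@dataclass
class OplsModel:
    classes: tuple[str, str]  # encoded -1, +1 in this order
    feature_ids: list[str]
    sample_ids: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    w: np.ndarray  # predictive weights, unit norm
    p_load: np.ndarray  # predictive loadings
    q_load: float  # y loading of the predictive component
    t: np.ndarray  # predictive scores
    w_orth: np.ndarray  # features x n_orth
    p_orth: np.ndarray
    t_orth: np.ndarray  # samples x n_orth
    r2y: float
    q2: float
    vip: pd.Series
    n_orth: int
    n_folds: int
    seed: int


def _nipals_opls(x: np.ndarray, y: np.ndarray, n_orth: int):
    """Core O-PLS on pre-scaled x (samples x features) and centered y."""
    xd = x.copy()
    w_orth, p_orth, t_orth = [], [], []
    for _ in range(n_orth):
        w = xd.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        t = xd @ w
        p = xd.T @ t / (t @ t)
        wo = p - (w @ p) * w
        nrm = np.linalg.norm(wo)
        if nrm < 1e-12:  # no orthogonal variation left
            break
        wo /= nrm
        to = xd @ wo
        po = xd.T @ to / (to @ to)
        xd = xd - np.outer(to, po)
        w_orth.append(wo)
        p_orth.append(po)
        t_orth.append(to)
    w = xd.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = xd @ w
    p = xd.T @ t / (t @ t)
    q = (y @ t) / (t @ t)
    stack = lambda vs, n: (np.column_stack(vs) if vs else np.zeros((n, 0)))
    return (
        w,
        p,
        q,
        t,
        stack(w_orth, x.shape[1]),
        stack(p_orth, x.shape[1]),
        stack(t_orth, x.shape[0]),
    )


def _predict_scores(x_new: np.ndarray, w, w_orth, p_orth) -> np.ndarray:
    """Predictive scores for pre-scaled new observations."""
    xd = x_new.copy()
    for k in range(w_orth.shape[1]):
        to = xd @ w_orth[:, k]
        xd = xd - np.outer(to, p_orth[:, k])
    return xd @ w


def _fold_assignment(y_sign: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Class-interleaved fold labels: each class cycles through folds."""
    folds = np.empty(len(y_sign), dtype=int)
    for cls in (-1, 1):
        idx = np.flatnonzero(y_sign == cls)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def _fit_arrays(
    x_raw: np.ndarray, y_sign: np.ndarray, n_orth: int, n_folds: int, rng
):
    """Fit + cross-validate on raw arrays; returns fit pieces, r2y, q2."""
    x_mean = x_raw.mean(axis=0)
    x_sd = x_raw.std(axis=0, ddof=1)
    xs = (x_raw - x_mean) / x_sd
    y_mean = float(y_sign.mean())
    y = y_sign - y_mean

    w, p, q, t, w_o, p_o, t_o = _nipals_opls(xs, y, n_orth)
    rss = float(np.sum((y - q * t) ** 2))
    tss = float(np.sum(y**2))
    r2y = 1.0 - rss / tss

    folds = _fold_assignment(y_sign, n_folds, rng)
    press = 0.0
    for f in sorted(set(folds)):
        test = folds == f
        train = ~test
        mu = x_raw[train].mean(axis=0)
        sd = x_raw[train].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        xtr = (x_raw[train] - mu) / sd
        ytr_mean = y_sign[train].mean()
        ytr = y_sign[train] - ytr_mean
        cw, _, cq, _, cwo, cpo, _ = _nipals_opls(xtr, ytr, n_orth)
        xte = (x_raw[test] - mu) / sd
        t_te = _predict_scores(xte, cw, cwo, cpo)
        yhat = ytr_mean + cq * t_te
        press += float(np.sum((y_sign[test] - yhat) ** 2))
    tss_full = float(np.sum((y_sign - y_sign.mean()) ** 2))
    q2 = 1.0 - press / tss_full
    return (x_mean, x_sd, y_mean, w, p, q, t, w_o, p_o, t_o, r2y, q2)


def _two_class_xy(matrix: OmicsMatrix):
    mat = matrix.to_log2()
    classes = tuple(sorted(set(mat.groups)))
    if len(classes) != 2:
        raise ValueError(f"OPLS-DA needs exactly two groups, got {classes}")
    x_raw = mat.values.to_numpy(float).T
    zero_var = mat.values.std(axis=1, ddof=1) == 0
    if zero_var.any():
        bad = list(mat.values.index[zero_var])
        raise ValueError(f"zero-variance features must be removed before OPLS-DA: {bad}")
    y_sign = np.where(np.asarray(mat.groups) == classes[1], 1.0, -1.0)
    for cls, want in zip(classes, (-1.0, 1.0)):
        if np.sum(y_sign == want) < 3:
            raise ValueError(f"group {cls!r} has fewer than 3 samples")
    return mat, classes, x_raw, y_sign


def fit_oplsda(
    matrix: OmicsMatrix, n_orth: int = 1, n_folds: int = 7, seed: int = 0
) -> OplsModel:
    """Fit a 1(+n_orth) component OPLS-DA model to a two-group matrix.

    X is mean-centered and unit-variance scaled; the class vector is
    encoded -1/+1 (lexicographically smaller group is -1). Q2 comes from
    ``n_folds``-fold cross-validation with class-interleaved, seeded
    fold assignment.
    """
    mat, classes, x_raw, y_sign = _two_class_xy(matrix)
    rank = np.linalg.matrix_rank(
        (x_raw - x_raw.mean(axis=0)) / x_raw.std(axis=0, ddof=1)
    )
    if n_orth >= rank:
        raise ValueError(f"n_orth={n_orth} must be < rank(X)={rank}")

    rng = np.random.default_rng(seed)
    (x_mean, x_sd, y_mean, w, p, q, t, w_o, p_o, t_o, r2y, q2) = _fit_arrays(
        x_raw, y_sign, n_orth, n_folds, rng
    )
    vip = pd.Series(
        np.sqrt(len(w)) * np.abs(w) / np.linalg.norm(w),
        index=mat.values.index.copy(),
        name="vip",
    )
    return OplsModel(
        classes=classes,
        feature_ids=list(mat.values.index),
        sample_ids=list(mat.values.columns),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        w=w,
        p_load=p,
        q_load=q,
        t=t,
        w_orth=w_o,
        p_orth=p_o,
        t_orth=t_o,
        r2y=r2y,
        q2=q2,
        vip=vip,
        n_orth=n_orth,
        n_folds=n_folds,
        seed=seed,
    )


def screen_metabolites(
    model: OplsModel,
    diff: DiffTable,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> set[str]:
    """Features with VIP > threshold AND univariate p < threshold."""
    model_feats = set(model.feature_ids)
    diff_feats = set(diff.table.index)
    if model_feats != diff_feats:
        delta = sorted(model_feats.symmetric_difference(diff_feats))
        raise ValueError(f"feature sets differ between model and diff table: {delta}")
    vip = model.vip.reindex(diff.table.index)
    keep = (vip > vip_threshold) & (diff.table["p"] < p_threshold)
    return set(diff.table.index[keep])


def vip_criterion(
    diff: DiffTable,
    model: OplsModel,
    vip_threshold: float = 1.0,
) -> DiffTable:
    """DiffTable whose significance flag is the joint VIP/p criterion.

    Used for metabolite layers, where calling is VIP > 1 AND p < alpha
    rather than the fold-change rule.
    """
    selected = screen_metabolites(model, diff, vip_threshold, diff.p_threshold)
    table = diff.table.copy()
    table["vip"] = model.vip.reindex(table.index)
    table["significant"] = table.index.isin(selected)
    return _dc_replace(diff, table=table)


@dataclass
class PermutationResult:
    observed_r2y: float
    observed_q2: float
    table: pd.DataFrame  # one row per permutation: r2y, q2
    p_empirical: float
    n_perm: int
    seed: int


def validate_permutation(
    matrix: OmicsMatrix,
    n_orth: int = 1,
    n_perm: int = 200,
    n_folds: int = 7,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of the OPLS-DA class separation.

    Class labels are shuffled ``n_perm`` times; R2Y and Q2 are recorded
    per refit and the empirical p-value for the observed Q2 is
    (1 + #{perm Q2 >= observed}) / (n_perm + 1).
    """
    if n_perm < 20:
        warnings.warn(
            f"n_perm={n_perm} is small; the empirical p-value is coarse",
            stacklevel=2,
        )
    _, _, x_raw, y_sign = _two_class_xy(matrix)
    rng = np.random.default_rng(seed)
    *_, r2y_obs, q2_obs = _fit_arrays(x_raw, y_sign, n_orth, n_folds, rng)

    rows = []
    for _ in range(n_perm):
        y_perm = rng.permutation(y_sign)
        *_, r2y_p, q2_p = _fit_arrays(x_raw, y_perm, n_orth, n_folds, rng)
        rows.append((r2y_p, q2_p))
    table = pd.DataFrame(rows, columns=["r2y", "q2"])
    p_emp = (1 + int(np.sum(table["q2"].to_numpy() >= q2_obs))) / (n_perm + 1)
    return PermutationResult(
        observed_r2y=r2y_obs,
        observed_q2=q2_obs,
        table=table,
        p_empirical=p_emp,
        n_perm=n_perm,
        seed=seed,
    )
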