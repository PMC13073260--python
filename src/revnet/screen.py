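"""Two-group differential screening and PCA group-separation checks.

Differential calling uses Welch's unequal-variance t-test on log2-scale
abundances with the conventional thresholds |log2FC| > 1 and p < 0.05.
Significance is assessed on the raw p-value; Benjamini-Hochberg q-values
are reported alongside for transparency but not used for calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import OmicsMatrix


@dataclass
class DiffTable:
    """Per-feature differential statistics for one two-group contrast.

    ``table`` is indexed by feature id with columns ``log2fc``, ``p``,
    ``q`` and ``significant``; ``contrast`` is (group, reference), i.e.
    log2fc > 0 means higher in ``contrast[0]``.
    """

    contrast: tuple[str, str]
    table: pd.DataFrame
    fc_threshold: float
    p_threshold: float

    @property
    def significant_features(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")


def screen(
    matrix: OmicsMatrix,
    contrast: tuple[str, str],
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    equal_var: bool = False,
) -> DiffTable:
    """Welch (default) or Student two-sample t-test per feature.

    log2fc is the difference of group means on the log2 scale
    (contrast group minus reference). Zero-variance features with equal
    group means get p = 1 by convention; with unequal means the p-value
    underflows to the smallest positive float.
    """
    group, reference = contrast
    mat = matrix.to_log2()
    a_cols = mat.samples_in(group)
    b_cols = mat.samples_in(reference)
    for name, cols in ((group, a_cols), (reference, b_cols)):
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has {len(cols)} samples; need >= 2")
    a = mat.values[a_cols].to_numpy(float)
    b = mat.values[b_cols].to_numpy(float)

    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)

    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(log2fc, 0.0)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = np.finfo(float).tiny
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    q = multipletests(p, method="fdr_bh")[1]
    significant = (np.abs(log2fc) > fc_threshold) & (p < p_threshold)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q, "significant": significant},
        index=mat.values.index.copy(),
    )
    return DiffTable(
        contrast=(group, reference),
        table=table,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def pca_scores(
    matrix: OmicsMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample principal-component scores of the feature-centered matrix.

    Returns (scores, explained_variance_ratio): scores is samples x PCs
    from the SVD of the column (per-feature mean) centered data;
    fractions are non-increasing and sum to <= 1.
    """
    mat = matrix.to_log2()
    x = mat.values.to_numpy(float).T  # samples x features
    n_samples = x.shape[0]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    centered = x - x.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise ValueError("matrix is constant across samples; PCA undefined")
    max_comp = min(centered.shape[1], n_samples - 1)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds max {max_comp}")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    scores = u[:, :n_components] * s[:n_components]
    ratio = (s[:n_components] ** 2) / total
    frame = pd.DataFrame(
        scores,
        index=mat.values.columns.copy(),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, ratio
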