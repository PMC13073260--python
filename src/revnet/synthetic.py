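"""Synthetic three-group multi-omics data and interactomes with planted truth.

The generator emulates a control / disease-model / treated animal study
with five samples per group per layer: a subset of features is perturbed
in the model group, and a sub-subset of those is restored to control
levels by treatment. Abundances are log-normal (additive Gaussian noise
on the log2 scale). Interactomes are stochastic block models with planted
dense communities so that module detection has a ground truth.

Also ships a packaged fixture transcribing the 61 treatment-reverted
metabolites (name, biochemical category, and the two trend arrows) used
as an in-package worked example.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import OmicsMatrix

#: (block size, within-block edge probability, between-block edge probability)
Block = tuple[int, float, float]


@dataclass
class SyntheticSpec:
    """Parameters of the planted three-group world.

    Defaults follow the emulated study design: 5 samples per group,
    log2-scale effects with log-normal noise.
    """

    n_features: int = 200
    n_per_group: int = 5
    frac_disease: float = 0.2
    frac_reversed: float = 0.5
    effect_log2: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0
    layer: str = "transcript"
    feature_prefix: str = "F"
    interactome_blocks: list[Block] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if not 0.0 <= self.frac_disease <= 1.0:
            raise ValueError("frac_disease must lie in [0, 1]")
        if not 0.0 <= self.frac_reversed <= 1.0:
            raise ValueError("frac_reversed must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for i, blk in enumerate(self.interactome_blocks):
            size, p_in, p_out = blk
            if size < 1:
                raise ValueError(f"interactome_blocks[{i}]: size must be >= 1")
            if not (0.0 <= p_in <= 1.0 and 0.0 <= p_out <= 1.0):
                raise ValueError(f"interactome_blocks[{i}]: probabilities must lie in [0, 1]")


def generate_dataset(spec: SyntheticSpec) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Simulate one omics layer plus its planted truth table.

    Disease features are the first ``round(frac_disease * n_features)``
    features and the reversed ones the first ``round(frac_reversed * ...)``
    of those; keeping the planted sets deterministic makes truth tables
    comparable across layers generated with different seeds. Effect signs
    and noise are drawn from the seeded generator.

    Returns
    -------
    (matrix, truth)
        ``matrix`` is log2-scale, 3 x n_per_group samples. ``truth`` is
        indexed by feature id with boolean columns ``disease`` and
        ``reversed`` and the signed planted effect ``effect_mc``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_features
    n_disease = int(round(spec.frac_disease * n))
    n_reversed = int(round(spec.frac_reversed * n_disease))

    width = max(4, len(str(n)))
    feats = [f"{spec.feature_prefix}{i + 1:0{width}d}" for i in range(n)]
    groups_order = ("control", "model", "treated")
    samples = [f"{g}_{j + 1}" for g in groups_order for j in range(spec.n_per_group)]
    glabels = pd.Series(
        [g for g in groups_order for _ in range(spec.n_per_group)], index=samples
    )

    baseline = rng.normal(8.0, 1.0, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    effect = np.zeros(n)
    effect[:n_disease] = sign[:n_disease] * spec.effect_log2
    reversed_flag = np.zeros(n, dtype=bool)
    reversed_flag[:n_reversed] = True

    means = np.empty((n, 3 * spec.n_per_group))
    ctrl = baseline
    model = baseline + effect
    treated = np.where(reversed_flag, ctrl, model)  # restored vs persistent effect
    for k, mu in enumerate((ctrl, model, treated)):
        means[:, k * spec.n_per_group : (k + 1) * spec.n_per_group] = mu[:, None]

    values = means + rng.normal(0.0, spec.noise_sd, size=means.shape)
    matrix = OmicsMatrix(
        values=pd.DataFrame(values, index=feats, columns=samples),
        groups=glabels,
        layer=spec.layer,
    )
    truth = pd.DataFrame(
        {
            "disease": effect != 0.0,
            "reversed": reversed_flag & (effect != 0.0),
            "effect_mc": effect,
        },
        index=pd.Index(feats, name="feature_id"),
    )
    return matrix, truth


def generate_interactome(spec: SyntheticSpec, feature_ids: list[str]) -> nx.Graph:
    """Stochastic block model over ``feature_ids`` with planted dense blocks.

    Blocks occupy consecutive runs of ``feature_ids`` starting at the
    front; leftover nodes form a sparse background community whose edge
    probability is the mean of the declared between-block probabilities.
    The pairwise edge probability between two distinct communities is the
    mean of their between-block probabilities.
    """
    sizes = [b[0] for b in spec.interactome_blocks]
    if sum(sizes) > len(feature_ids):
        raise ValueError(
            f"interactome_blocks sizes sum to {sum(sizes)} but only "
            f"{len(feature_ids)} feature_ids were supplied"
        )
    p_in = [b[1] for b in spec.interactome_blocks]
    p_out = [b[2] for b in spec.interactome_blocks]
    n_rest = len(feature_ids) - sum(sizes)
    if n_rest > 0:
        bg = float(np.mean(p_out)) if p_out else 0.0
        sizes = sizes + [n_rest]
        p_in = p_in + [bg]
        p_out = p_out + [bg]

    b = len(sizes)
    pmat = np.empty((b, b))
    for i in range(b):
        for j in range(b):
            pmat[i, j] = p_in[i] if i == j else 0.5 * (p_out[i] + p_out[j])

    rng = np.random.default_rng(spec.seed)
    g = nx.Graph()
    g.add_nodes_from(feature_ids)
    membership = np.repeat(np.arange(b), sizes)
    ids = np.asarray(feature_ids, dtype=object)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if rng.random() < pmat[membership[i], membership[j]]:
                g.add_edge(ids[i], ids[j])
    return g


# --- packaged fixture ---------------------------------------------------

@dataclass(frozen=True)
class MetaboliteTableRow:
    """One reverted metabolite: name, category, and the two trend arrows."""

    name: str
    category: str
    trend_mc: str  # model vs control
    trend_tm: str  # treated vs model

    def __post_init__(self) -> None:
        for attr in ("trend_mc", "trend_tm"):
            v = getattr(self, attr)
            if v not in ("up", "down"):
                raise ValueError(f"{attr} must be 'up' or 'down', got {v!r}")


def load_table1_fixture() -> list[MetaboliteTableRow]:
    """Load the packaged 61-row reverted-metabolite table."""
    ref = importlib.resources.files("revnet.data") / "table1_reverted_metabolites.tsv"
    rows: list[MetaboliteTableRow] = []
    with ref.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["name", "category", "trend_model_vs_control", "trend_pa_vs_model"]
        if header != expected:
            raise ValueError(f"fixture line 1: expected columns {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"fixture line {lineno}: expected 4 fields, got {len(parts)}")
            try:
                rows.append(MetaboliteTableRow(*parts))
            except ValueError as exc:
                raise ValueError(f"fixture line {lineno}: {exc}") from exc
    return rows
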