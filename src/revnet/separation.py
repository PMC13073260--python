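"""Network separation score S_AB between module pairs on a shared interactome.

For node sets A and B on one graph, with hop-count shortest paths d(.,.),

    <d_AA> = mean over a in A of min_{a' in A, a' != a} d(a, a')
    <d_AB> = mean over v in A ∪ B of min_{u in other set, u != v} d(v, u)
    S_AB   = <d_AB> - (<d_AA> + <d_BB>) / 2

Every node's contribution, in both the within and the between term, is
its distance to the nearest *other* node of the target set (a node never
serves as its own nearest neighbor). This makes S_AA = 0 an exact
identity for any module, so S_AB is calibrated against self-separation:
S_AB < 0 means each module's nodes sit closer to the other module than
its own members sit to each other — the two modules interleave in one
network neighborhood (topological synergy). The most synergistic
gene/protein module pair is the argmin over the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import Module


def _check_nodes(g: nx.Graph, nodes, what: str) -> None:
    missing = sorted(v for v in nodes if v not in g)
    if missing:
        raise ValueError(f"{what} nodes absent from graph: {missing}")


def _nearest(g: nx.Graph, source, targets: set) -> float:
    """Hop distance from ``source`` to the nearest node of ``targets``."""
    if source in targets:
        return 0.0
    seen = {source}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for v in frontier:
            for u in g[v]:
                if u in seen:
                    continue
                if u in targets:
                    return float(d)
                seen.add(u)
                nxt.append(u)
        frontier = nxt
    return float("inf")


def within_distance(g: nx.Graph, module_nodes) -> float:
    """Mean distance from each module node to its nearest other member.

    A singleton module returns 0 by convention (keeps S_AA = 0
    degenerate-safe and never inflates synergy).
    """
    nodes = sorted(set(module_nodes))
    _check_nodes(g, nodes, "module")
    if len(nodes) < 1:
        raise ValueError("module must contain at least one node")
    if len(nodes) == 1:
        return 0.0
    node_set = set(nodes)
    dists = [_nearest(g, v, node_set - {v}) for v in nodes]
    return float(np.mean(dists))


def between_distance(g: nx.Graph, module_a, module_b) -> float:
    """Mean, over A ∪ B, of each node's distance to the nearest node of
    the other set other than itself.

    A node shared by both sets is matched to the closest *distinct*
    member of the other set (0 only when the other set has no distinct
    member), which keeps S_AA = 0 exactly when A = B.
    """
    a = set(module_a)
    b = set(module_b)
    _check_nodes(g, a, "module A")
    _check_nodes(g, b, "module B")

    def _contrib(v, other):
        targets = other - {v}
        if not targets:
            return 0.0
        return _nearest(g, v, targets)

    dists = [_contrib(v, b) for v in sorted(a)]
    dists += [_contrib(v, a) for v in sorted(b)]
    return float(np.mean(dists))


def separation(g: nx.Graph, module_a, module_b) -> float:
    """S_AB = <d_AB> - (<d_AA> + <d_BB>) / 2; symmetric in its arguments."""
    return between_distance(g, module_a, module_b) - 0.5 * (
        within_distance(g, module_a) + within_distance(g, module_b)
    )


@dataclass
class SeparationResult:
    """Pairwise S_AB matrix between two module sets.

    ``s_ab``/``d_ab`` are DataFrames indexed by A-labels x B-labels;
    ``d_aa``/``d_bb`` the within-module terms. ``best_pair`` is the
    argmin of ``s_ab`` (ties: smaller A label index, then B).
    ``unevaluable`` lists modules that lost more than half their members
    when the analysis was restricted to the largest connected component.
    """

    s_ab: pd.DataFrame
    d_ab: pd.DataFrame
    d_aa: pd.Series
    d_bb: pd.Series
    best_pair: tuple[str, str]
    best_value: float
    dropped_nodes: dict = field(default_factory=dict)
    unevaluable: list = field(default_factory=list)


def separation_matrix(
    g: nx.Graph, modules_a: list[Module], modules_b: list[Module]
) -> SeparationResult:
    """Full S_AB matrix between gene modules (A) and protein modules (B).

    Distances are undefined across connected components, so the analysis
    graph is restricted to its largest connected component; module
    members outside it are dropped (logged in ``dropped_nodes``) and a
    module losing >50% of its members is flagged unevaluable and
    excluded from the matrix rather than given an imputed distance.
    """
    if not modules_a or not modules_b:
        raise ValueError("both module sets must be non-empty")
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    lcc = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    core = g.subgraph(lcc)

    dropped: dict = {}
    unevaluable: list = []
    kept_a: list[tuple[str, set]] = []
    kept_b: list[tuple[str, set]] = []
    for side, modules, kept in (("A", modules_a, kept_a), ("B", modules_b, kept_b)):
        for m in modules:
            inside = set(m.members) & lcc
            lost = sorted(set(m.members) - inside)
            if lost:
                dropped[m.label] = lost
            if len(inside) <= 0.5 * len(m.members) or not inside:
                unevaluable.append(m.label)
            else:
                kept.append((m.label, inside))
    if not kept_a or not kept_b:
        raise ValueError(
            f"no evaluable module pairs: unevaluable modules {unevaluable}"
        )

    d_aa = pd.Series({lab: within_distance(core, nodes) for lab, nodes in kept_a})
    d_bb = pd.Series({lab: within_distance(core, nodes) for lab, nodes in kept_b})
    a_labels = [lab for lab, _ in kept_a]
    b_labels = [lab for lab, _ in kept_b]
    d_ab = pd.DataFrame(index=a_labels, columns=b_labels, dtype=float)
    s_ab = pd.DataFrame(index=a_labels, columns=b_labels, dtype=float)
    for lab_a, nodes_a in kept_a:
        for lab_b, nodes_b in kept_b:
            dab = between_distance(core, nodes_a, nodes_b)
            d_ab.at[lab_a, lab_b] = dab
            s_ab.at[lab_a, lab_b] = dab - 0.5 * (d_aa[lab_a] + d_bb[lab_b])

    vals = s_ab.to_numpy(float)
    i, j = np.unravel_index(np.argmin(vals), vals.shape)  # row-major: A first
    best = (a_labels[i], b_labels[j])
    return SeparationResult(
        s_ab=s_ab,
        d_ab=d_ab,
        d_aa=d_aa,
        d_bb=d_bb,
        best_pair=best,
        best_value=float(vals[i, j]),
        dropped_nodes=dropped,
        unevaluable=unevaluable,
    )
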