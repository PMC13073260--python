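"""Interactome I/O, MCODE-style dense-module detection, and hub ranking.

The interactome is an undirected simple graph (``networkx.Graph``) over
feature identifiers, typically a STRING-style protein-protein
interaction export read from a TSV edge list. Module detection follows
the MCODE scheme: k-core-based vertex weighting, seeded greedy complex
growth, and 2-core post-processing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Module:
    """A detected dense module: labelled, scored node subset."""

    label: str
    members: tuple[str, ...]  # sorted
    score: float  # density x size of the module subgraph
    seed: str

    def __len__(self) -> int:
        return len(self.members)


def read_edgelist(path, min_score: float | None = None) -> nx.Graph:
    """Read a TSV edge list (``u<TAB>v[<TAB>score]``, ``#`` comments).

    Self-loops are dropped (count logged); duplicate edges collapse
    naturally. With ``min_score`` given, edges whose third column is
    below it are removed; a missing or non-numeric score is then a parse
    error naming the line.
    """
    g = nx.Graph()
    n_loops = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            u, v = parts[0], parts[1]
            score = None
            if len(parts) >= 3 and parts[2] != "":
                try:
                    score = float(parts[2])
                except ValueError:
                    if min_score is not None:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric score {parts[2]!r}"
                        ) from None
            if min_score is not None:
                if score is None:
                    raise ValueError(f"{path}:{lineno}: score column required")
                if score < min_score:
                    continue
            if u == v:
                n_loops += 1
                continue
            if score is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, score=score)
    if n_loops:
        logger.info("dropped %d self-loop(s) while reading %s", n_loops, path)
    return g


def write_edgelist(g: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            if "score" in data:
                fh.write(f"{u}\t{v}\t{data['score']}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def induced_subnetwork(g: nx.Graph, features) -> nx.Graph:
    """Subgraph induced by ``features`` ∩ nodes; absentees are logged."""
    features = set(features)
    present = features & set(g.nodes)
    n_missing = len(features) - len(present)
    if n_missing:
        logger.info("%d feature(s) absent from the interactome", n_missing)
    return g.subgraph(present).copy()


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weights(g: nx.Graph, degree_cutoff: int) -> dict:
    """MCODE vertex weight: highest k-core number of the closed
    neighborhood times the density of that k-core (the core-clustering
    coefficient). Vertices below the degree cutoff weigh 0."""
    weights = {}
    for v in g.nodes:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = set(g[v]) | {v}
        h = g.subgraph(nbhd)
        core = nx.core_number(h)
        kmax = max(core.values())
        core_nodes = [n for n, c in core.items() if c >= kmax]
        weights[v] = kmax * _density(h.subgraph(core_nodes))
    return weights


def mcode(
    g: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.5,
    label_prefix: str = "A",
) -> list[Module]:
    """Detect dense modules by the three-stage MCODE procedure.

    1. vertex weighting (see :func:`_vertex_weights`);
    2. complex prediction: seed at the highest-weight unvisited vertex
       and grow breadth-first up to ``max_depth``, admitting a neighbor
       when its weight is >= (1 - node_score_cutoff) x seed weight and
       it attaches to at least ``k_core`` current members (single-edge
       bridges between dense regions therefore do not chain complexes);
    3. post-processing: complexes lacking a ``k_core``-core are
       discarded; haircut trims to the 2-core; fluff optionally adds
       neighbors whose closed-neighborhood density exceeds
       ``fluff_density``.

    Modules are reported in descending score order (score = density x
    size), labelled ``{label_prefix}1..``; all ties break on sorted node
    ids so the result is independent of node insertion order.
    """
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise ValueError(f"graph has self-loops: {loops[:5]}")
    weights = _vertex_weights(g, degree_cutoff)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    visited: set = set()
    raw_complexes: list[tuple[set, str]] = []

    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for v in sorted(frontier):
                for u in sorted(g[v]):
                    if u in visited or u in members:
                        continue
                    if weights[u] < threshold:
                        continue
                    attach = sum(1 for x in g[u] if x in members)
                    if len(members) >= k_core and attach < k_core:
                        continue
                    members.add(u)
                    visited.add(u)
                    nxt.append(u)
            frontier = nxt
            depth += 1
        raw_complexes.append((members, seed))

    modules = []
    for members, seed in raw_complexes:
        sub = g.subgraph(members)
        core = nx.k_core(sub, k_core)
        if core.number_of_nodes() == 0:
            continue  # no k-core: not a complex
        kept = set(members)
        if haircut:
            kept = set(nx.k_core(sub, 2).nodes)
            if not kept:
                continue
        if fluff:
            for v in sorted(set().union(*(set(g[m]) for m in kept)) - kept):
                nbhd = set(g[v]) | {v}
                if _density(g.subgraph(nbhd)) > fluff_density:
                    kept.add(v)
        sub = g.subgraph(kept)
        if not nx.is_connected(sub):
            # keep the component containing the seed (fluff/haircut safe)
            comp = nx.node_connected_component(sub, seed) if seed in kept else max(
                nx.connected_components(sub), key=lambda c: (len(c), sorted(c))
            )
            kept = set(comp)
            sub = g.subgraph(kept)
        modules.append((kept, seed, _density(sub) * len(kept)))

    modules.sort(key=lambda m: (-m[2], tuple(sorted(m[0]))))
    return [
        Module(
            label=f"{label_prefix}{i + 1}",
            members=tuple(sorted(m[0])),
            score=m[2],
            seed=m[1],
        )
        for i, m in enumerate(modules)
    ]


def hub_rank(g: nx.Graph, module: Module, top_k: int = 7) -> list[str]:
    """Top-``top_k`` module members by degree within the module subgraph.

    Ties break lexicographically; returns min(top_k, module size) nodes.
    """
    missing = [v for v in module.members if v not in g]
    if missing:
        raise ValueError(f"module nodes absent from graph: {missing}")
    sub = g.subgraph(module.members)
    ranked = sorted(sub.nodes, key=lambda v: (-sub.degree(v), v))
    return ranked[:top_k]


def write_modules_tsv(modules: list[Module], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("module_label\tnode\tscore\n")
        for m in modules:
            for v in m.members:
                fh.write(f"{m.label}\t{v}\t{m.score:.6g}\n")
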