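"""Hypergeometric over-representation analysis over GMT gene-set collections.

For a query of n features drawn from a universe of N, a set with K
members in the universe and k of them in the query is scored by the
upper-tail hypergeometric probability P(X >= k); q-values are
Benjamini-Hochberg over all tested sets. Set collections are user
input (GMT files); no database content is bundled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .screen import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset]
    universe: frozenset | None = None

    def default_universe(self) -> frozenset:
        if self.universe is not None:
            return self.universe
        out: set = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``set_name<TAB>description<TAB>member...``."""
    sets: dict[str, frozenset] = {}
    n_dups = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, _desc, *members = parts
            members = [m for m in members if m]
            n_dups += len(members) - len(set(members))
            sets[name] = frozenset(members)
    if n_dups:
        logger.info("deduplicated %d repeated member(s) while reading %s", n_dups, path)
    return GeneSetCollection(sets=sets)


def ora(
    query,
    collection: GeneSetCollection,
    universe=None,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of the collection.

    All counts are taken after intersecting query and sets with the
    universe (default: the union of all collection members), so features
    outside the universe never affect any record. Rows are sorted by
    (p, term); columns: term, k, K, n, N, p, q.
    """
    uni = frozenset(universe) if universe is not None else collection.default_universe()
    if not uni:
        raise ValueError("universe is empty")
    q_set = frozenset(query) & uni
    n = len(q_set)
    big_n = len(uni)

    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term] & uni
        big_k = len(members)
        k = len(q_set & members)
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "k": k, "K": big_k, "n": n, "N": big_n, "p": min(p, 1.0)})
    frame = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(frame):
        frame["q"] = bh_adjust(frame["p"].to_numpy())
        frame = frame.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        frame["q"] = []
    return frame
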