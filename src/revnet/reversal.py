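"""Treatment-reversal screening: the central feature-selection step.

A feature is "reverted" when it is significantly dysregulated in the
disease contrast (model vs control) and significantly changed in the
opposite direction in the treatment contrast (treated vs model). Both
contrasts use their layer's own calling criterion (fold-change/p for
transcripts and proteins, VIP/p for metabolites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screen import DiffTable


@dataclass(frozen=True)
class RevertedFeature:
    feature_id: str
    log2fc_mc: float  # model vs control
    p_mc: float
    log2fc_tm: float  # treated vs model
    p_tm: float
    direction: str  # up_then_down | down_then_up


def find_reverted(
    diff_mc: DiffTable,
    diff_tm: DiffTable,
    min_restoration: float = 0.0,
) -> list[RevertedFeature]:
    """Features significant in both contrasts with opposite fold-change signs.

    ``diff_mc`` must contrast (model, control) style and ``diff_tm``
    (treated, model) style: the reference of the treatment contrast has
    to equal the perturbed group of the disease contrast. The optional
    stricter criterion ``min_restoration`` additionally requires
    |log2fc_tm| >= min_restoration * |log2fc_mc| (0 disables it).

    Output is sorted by |log2fc_mc| descending, ties broken by feature id.
    """
    if diff_tm.contrast[1] != diff_mc.contrast[0]:
        raise ValueError(
            "contrast mismatch: treatment contrast must be referenced against the "
            f"disease group; got disease {diff_mc.contrast} and treatment {diff_tm.contrast}"
        )
    if set(diff_mc.table.index) != set(diff_tm.table.index):
        delta = sorted(set(diff_mc.table.index) ^ set(diff_tm.table.index))
        raise ValueError(f"feature universes differ between tables: {delta}")

    tm = diff_tm.table.reindex(diff_mc.table.index)
    mc = diff_mc.table
    opposite = np.sign(mc["log2fc"]) * np.sign(tm["log2fc"]) == -1
    keep = mc["significant"] & tm["significant"] & opposite
    if min_restoration > 0:
        keep &= tm["log2fc"].abs() >= min_restoration * mc["log2fc"].abs()

    out = [
        RevertedFeature(
            feature_id=f,
            log2fc_mc=float(mc.at[f, "log2fc"]),
            p_mc=float(mc.at[f, "p"]),
            log2fc_tm=float(tm.at[f, "log2fc"]),
            p_tm=float(tm.at[f, "p"]),
            direction="up_then_down" if mc.at[f, "log2fc"] > 0 else "down_then_up",
        )
        for f in mc.index[keep]
    ]
    out.sort(key=lambda r: (-abs(r.log2fc_mc), r.feature_id))
    return out


def reversal_summary(
    reverted: list[RevertedFeature],
    categories: dict[str, str] | None = None,
) -> dict:
    """Counts by direction and (optionally) category composition.

    Category percentages are category count / total reverted x 100,
    reported to one decimal place. An empty input yields zero counts.
    """
    n = len(reverted)
    summary = {
        "n_total": n,
        "n_up_then_down": sum(r.direction == "up_then_down" for r in reverted),
        "n_down_then_up": sum(r.direction == "down_then_up" for r in reverted),
    }
    if categories is not None:
        counts: dict[str, int] = {}
        for r in reverted:
            cat = categories.get(r.feature_id, "uncategorized")
            counts[cat] = counts.get(cat, 0) + 1
        summary["by_category"] = [
            {
                "category": cat,
                "count": cnt,
                "percent": round(100.0 * cnt / n, 1) if n else 0.0,
            }
            for cat, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
    return summary


def category_composition(rows) -> pd.DataFrame:
    """Category counts and one-decimal percentages for fixture-style rows.

    ``rows`` are objects with ``category`` attributes (e.g. the packaged
    reverted-metabolite table).
    """
    counts: dict[str, int] = {}
    for r in rows:
        counts[r.category] = counts.get(r.category, 0) + 1
    total = len(rows)
    frame = pd.DataFrame(
        [
            {"category": c, "count": k, "percent": round(100.0 * k / total, 1)}
            for c, k in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
    )
    return frame


def count_opposite_trends(rows) -> int:
    """Number of rows whose two trend arrows point in opposite directions."""
    return sum(1 for r in rows if r.trend_mc != r.trend_tm)
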