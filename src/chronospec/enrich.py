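"""Two-sided Fisher exact enrichment against a fixed background universe.

The background is always the expressed-gene universe of the experiment;
target sets are intersected with it before testing ("expressed in the
sample"). The two-sided p follows the "sum of all tables with
probability <= observed" convention of the exact test. Odds ratios use
the Haldane 0.5 continuity correction only when a cell is zero (flagged).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .experiment import GeneSetCollection

__all__ = ["fisher_enrich", "enrich_matrix"]


def fisher_enrich(query: Iterable[str], target: Iterable[str], background: Iterable[str]) -> dict:
    """Fisher exact test of query vs target membership over the background.

    Table: a = |query & target|, b = |query - target|, c = |target - query|,
    d = the rest. Returns the table, the odds ratio, the two-sided p, and
    the direction of the (unthresholded) association.
    """
    bg = frozenset(background)
    if not bg:
        raise ValueError("empty background universe")
    q = frozenset(query) & bg
    t = frozenset(target) & bg
    a = len(q & t)
    b = len(q - t)
    c = len(t - q)
    d = len(bg) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = (a == 0) or (b == 0) or (c == 0) or (d == 0)
    if haldane:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return {
        "a": a, "b": b, "c": c, "d": d,
        "odds_ratio": float(orr),
        "p": float(p),
        "haldane": haldane,
    }


def enrich_matrix(
    queries: GeneSetCollection,
    targets: GeneSetCollection,
    background: Iterable[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """All query x target Fisher tests; BH within each query across targets.

    ``direction`` is ``enriched`` (OR > 1, q < 0.05), ``depleted``
    (OR < 1, q < 0.05) or ``ns``. Row count is |queries| x |targets|.
    """
    bg = frozenset(background)
    cols = ["query", "target", "a", "b", "c", "d", "odds_ratio", "p", "q", "direction", "haldane"]
    rows = []
    for qname in queries:
        for tname in targets:
            r = fisher_enrich(queries[qname], targets[tname], bg)
            r["query"] = qname
            r["target"] = tname
            rows.append(r)
    if not rows:
        return pd.DataFrame(columns=cols)
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for qname in queries:
        mask = table["query"] == qname
        table.loc[mask, "q"] = multipletests(table.loc[mask, "p"], method="fdr_bh")[1]
    table["direction"] = np.where(
        (table["q"] < q_threshold) & (table["odds_ratio"] > 1), "enriched",
        np.where((table["q"] < q_threshold) & (table["odds_ratio"] < 1), "depleted", "ns"),
    )
    return table[cols]
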