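"""Gene-set over-representation for consensus modules.

Upper-tail hypergeometric test of each gene set against a query module
within an explicit background universe, with Benjamini-Hochberg FDR
across the tested sets, plus a heat-map-ready table of -log10(p) values
for sets significant in at least one module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["GeneSetCollection", "hypergeom_enrich", "enrich_heatmap_table"]


class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    def __init__(self, sets: dict[str, set[str]], universe: set[str] | None = None):
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        self.universe = set(universe)
        self.sets = {
            name: set(members) & self.universe for name, members in sets.items()
        }
        self.sets = {name: s for name, s in self.sets.items() if s}

    def __len__(self) -> int:
        return len(self.sets)


def _bh(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


def hypergeom_enrich(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Rank gene sets by upper-tail hypergeometric over-representation.

    With universe size N, set size K and query size n (after restriction
    to the universe), p = P[X >= overlap] for X ~ Hypergeom(N, K, n).
    Returns rows sorted by p with BH-FDR across the tested sets.
    """
    query = set(query)
    mapped = query & collection.universe
    if not mapped:
        raise ValueError(
            f"no query gene maps to the universe; unmapped: {sorted(query)}"
        )
    N, n = len(collection.universe), len(mapped)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        overlap = mapped & members
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            (name, k, ";".join(sorted(overlap)), K, n, N, min(max(p, 0.0), 1.0))
        )
    table = pd.DataFrame(
        rows,
        columns=["set", "overlap", "overlap_genes", "set_size", "query_size",
                 "universe_size", "p"],
    )
    table["fdr"] = _bh(table["p"].to_numpy())
    return table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)


def enrich_heatmap_table(
    results: dict[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Module x gene-set matrix of -log10(p), filtered for display.

    Only sets significant (p < alpha) in at least one module are kept, so
    every retained row carries at least one significance mark; the
    companion ``<set>_sig`` columns flag the marked cells.
    """
    if not results:
        raise ValueError("no enrichment results supplied")
    sets = sorted({s for df in results.values() for s in df["set"]})
    modules = list(results)
    p = pd.DataFrame(1.0, index=sets, columns=modules)
    for cm, df in results.items():
        p.loc[df["set"].to_numpy(), cm] = df["p"].to_numpy()
    keep = (p < alpha).any(axis=1)
    p = p.loc[keep]
    out = -np.log10(p)
    for cm in modules:
        out[f"{cm}_sig"] = p[cm] < alpha
    out.index.name = "set"
    return out
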