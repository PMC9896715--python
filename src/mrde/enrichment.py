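"""Hypergeometric over-representation analysis against GMT gene sets.

For a query list of n genes drawn from a background of N genes, a set with K
background members and overlap k is scored with the upper tail
P(X >= k), X ~ Hypergeometric(N, K, n), computed in log space; BH FDR is
applied across sets and a set is enriched when fdr < alpha.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .survstats import bh_fdr


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) (inclusive of k)."""
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy computes the tail stably in log space
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def enrich(
    query_genes,
    gene_sets: GeneSetCollection,
    background_genes,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of the query in each gene set, BH across sets.

    Query and set members are intersected with the background first; the
    number of query genes dropped for being outside the background is
    reported in the frame's ``attrs``.
    """
    background = set(background_genes)
    query = set(query_genes)
    dropped = len(query - background)
    query &= background
    if not query:
        raise ValueError("query is empty after intersection with the background")
    N, n = len(background), len(query)
    rows = []
    for name in gene_sets.names():
        members = gene_sets.members(name) & background
        if not members:
            continue
        overlap = sorted(query & members)
        k, K = len(overlap), len(members)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append((name, k, K, n, N, p, ",".join(overlap)))
    table = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size", "background_size",
                       "p", "overlap_genes"]
    )
    if len(table):
        table["fdr"] = bh_fdr(table["p"].to_numpy())
        table["enriched"] = table["fdr"] < fdr_alpha
        table = table.sort_values(["fdr", "p", "set_name"]).reset_index(drop=True)
    else:
        table["fdr"] = []
        table["enriched"] = []
    table.attrs["query_dropped"] = dropped
    return table
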