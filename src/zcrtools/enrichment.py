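"""Gene-list comparison and hypergeometric over-representation testing.

`compare_gene_sets` partitions two gene lists (shared / A-only / B-only,
as percentages of the union). `hypergeom_enrichment` runs a one-sided
upper-tail hypergeometric test per annotation term with Benjamini-Hochberg
FDR adjustment across tested terms — the classic over-representation
analysis (the direction reported by GO tools such as clusterProfiler).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class SetPartition:
    n_shared: int
    n_a_only: int
    n_b_only: int

    @property
    def union(self) -> int:
        return self.n_shared + self.n_a_only + self.n_b_only

    @property
    def pct_shared(self) -> float:
        return round(100.0 * self.n_shared / self.union, 1)

    @property
    def pct_a_only(self) -> float:
        return round(100.0 * self.n_a_only / self.union, 1)

    @property
    def pct_b_only(self) -> float:
        return round(100.0 * self.n_b_only / self.union, 1)


def compare_gene_sets(a: set[str], b: set[str]) -> SetPartition:
    """Partition two gene-id sets into shared / A-only / B-only counts."""
    if not a and not b:
        raise ValueError("both gene sets are empty")
    return SetPartition(
        n_shared=len(a & b), n_a_only=len(a - b), n_b_only=len(b - a)
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for a hypergeometric draw of n from N with K successes."""
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    query: set[str],
    term_map: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Over-representation test of ``query`` against each term's gene set.

    Term gene sets are intersected with the universe first. Terms with no
    overlap with the query (k = 0) are omitted; q-values are BH-adjusted
    over the tested terms. Rows are sorted by (q, p).
    """
    if not universe:
        raise ValueError("universe is empty")
    stray = query - universe
    if stray:
        raise ValueError(
            f"query genes outside the universe: {sorted(stray)[:10]}"
        )
    N = len(universe)
    n = len(query)
    rows = []
    for term, genes in term_map.items():
        term_genes = genes & universe
        k = len(query & term_genes)
        if k == 0:
            continue
        K = len(term_genes)
        rows.append(
            {
                "term_id": term, "k": k, "K": K, "n": n, "N": N,
                "p": hypergeom_pvalue(k, n, K, N),
            }
        )
    df = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df
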