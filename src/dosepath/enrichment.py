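"""Gene-set over-representation analysis.

One-sided Fisher's exact (hypergeometric upper tail) p-values for each
set against a query gene list, with Benjamini-Hochberg step-up
adjustment across sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["fisher_enrichment", "bh_adjust", "hypergeom_tail"]


def hypergeom_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the over-representation p."""
    if not (0 <= k <= min(big_k, n)):
        raise ValueError("inconsistent counts")
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * M / j over ascending-sorted p, clipped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def fisher_enrichment(
    query, collection: dict, universe, ease: bool = False
) -> pd.DataFrame:
    """Over-representation of each set in a query gene list.

    Each set is intersected with the universe before testing; the
    query must be a subset of the universe.  ``ease=True`` applies the
    conservative EASE variant that discounts one overlapping gene
    (p computed at k-1).  Returns one row per set sorted by p, with BH
    FDR attached.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n = len(query)
    big_n = len(universe)
    rows = []
    for name, members in collection.items():
        genes = set(members) & universe
        k = len(genes & query)
        big_k = len(genes)
        if n == 0 or big_k == 0:
            p = 1.0
        else:
            k_eff = max(k - 1, 0) if ease else k
            p = hypergeom_tail(k_eff, big_n, big_k, n)
        rows.append((name, k, big_k, n, big_n, p))
    result = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p"]
    ).set_index("set")
    result["fdr"] = bh_adjust(result["p"].to_numpy())
    return result.sort_values("p", kind="mergesort")
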