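"""Signed pathway-activity scoring over the dose series.

A pathway's activity in a sample is the linear combination of its
genes' log2 expression ratios with weight +1, multiplied by -1 for
genes acting as repressors.  Raw activities are z-scored per pathway
across samples, screened by a random-gene-set permutation FDR, and the
surviving pathways are hierarchically clustered.
"""

from __future__ import annotations

from zlib import crc32

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from dosepath.enrichment import bh_adjust

__all__ = [
    "pathway_activity",
    "activity_matrix",
    "normalize_activities",
    "activity_fdr",
    "cluster_activities",
]


def pathway_activity(expr: pd.DataFrame, gene_set: dict) -> tuple:
    """Per-sample signed activity of one gene set.

    ``gene_set`` maps gene -> weight in {+1, -1}.  Genes absent from
    the matrix are skipped; returns (activity Series, coverage), where
    coverage is the fraction of set genes present.
    """
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    weights = np.array([gene_set[g] for g in present], dtype=float)
    values = expr.loc[present].to_numpy(dtype=float)
    activity = pd.Series(weights @ values, index=expr.columns)
    return activity, len(present) / len(gene_set)


def activity_matrix(expr: pd.DataFrame, collection: dict) -> pd.DataFrame:
    """Raw pathway x sample activity matrix for a whole collection."""
    rows = {}
    for name, gene_set in collection.items():
        rows[name], _ = pathway_activity(expr, gene_set)
    out = pd.DataFrame(rows).T
    out.index.name = "pathway"
    return out


def normalize_activities(raw: pd.DataFrame) -> tuple:
    """Per-pathway z-score across samples (population sd).

    Zero-variance pathways are set to all-zero; returns
    (normalized matrix, list of flagged zero-variance pathways).
    """
    if raw.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    x = raw.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population sd
    flat = np.isclose(sd[:, 0], 0.0)
    sd[flat] = 1.0
    z = (x - mu) / sd
    z[flat] = 0.0
    flagged = list(raw.index[flat])
    return pd.DataFrame(z, index=raw.index, columns=raw.columns), flagged


def activity_fdr(
    expr: pd.DataFrame,
    collection: dict,
    n_permutations: int = 1000,
    seed: int = 0,
    statistic: str = "max_abs",
) -> pd.DataFrame:
    """Permutation significance screen for pathway activities.

    The test statistic per pathway is the maximum absolute raw
    activity across samples (``statistic='top_dose'`` uses the
    absolute activity at the last, highest-dose sample instead).  The
    null resamples size-matched random gene sets from the matrix's
    gene universe carrying the same sign multiset.  The pre-adjustment
    p is (null >= observed count)/n_permutations; the FDR column is
    its BH adjustment across pathways.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if statistic not in ("max_abs", "top_dose"):
        raise ValueError("statistic must be 'max_abs' or 'top_dose'")
    x = expr.to_numpy(dtype=float)
    n_genes = x.shape[0]
    index = pd.Index(expr.index)

    def stat(act: np.ndarray) -> np.ndarray:
        if statistic == "max_abs":
            return np.max(np.abs(act), axis=-1)
        return np.abs(act[..., -1])

    rows = []
    for name, gene_set in collection.items():
        if len(gene_set) > n_genes:
            raise ValueError(f"set {name!r} larger than the gene universe")
        present = [g for g in gene_set if g in index]
        if not present:
            raise ValueError(f"no gene of set {name!r} in the matrix")
        pos = index.get_indexer(present)
        weights = np.array([gene_set[g] for g in present], dtype=float)
        observed = stat(weights @ x[pos])
        # size- and sign-matched random sets: the same weight multiset
        # applied to freshly drawn genes each round; the null stream is
        # derived from the set's content so identical sets share it
        content = crc32(repr(sorted(gene_set.items())).encode())
        rng = np.random.default_rng([seed, content])
        k = len(present)
        draws = np.empty((n_permutations, k), dtype=int)
        for b in range(n_permutations):
            draws[b] = rng.choice(n_genes, size=k, replace=False)
        null_act = np.einsum("k,bks->bs", weights, x[draws])
        null_stat = stat(null_act)
        p = float(np.mean(null_stat >= observed))
        rows.append((name, k, float(observed), p))

    out = pd.DataFrame(
        rows, columns=["pathway", "n_present", "statistic", "p"]
    ).set_index("pathway")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def cluster_activities(
    normalized: pd.DataFrame,
    linkage_method: str = "average",
    metric: str = "correlation",
) -> dict:
    """Agglomerative clustering of pathways on their activity profiles.

    Returns the leaf order, the scipy linkage matrix, a two-group cut,
    and each group's mean dose-trend sign (+1 rising with dose, -1
    falling), which reproduces the two reciprocal sub-clusters a
    dose-response design induces.
    """
    if normalized.shape[0] < 2:
        raise ValueError("need at least 2 pathways to cluster")
    z = linkage(normalized.to_numpy(dtype=float), method=linkage_method,
                metric=metric)
    order = [normalized.index[i] for i in leaves_list(z)]
    labels = fcluster(z, t=2, criterion="maxclust")
    trend = {}
    ranks = np.arange(normalized.shape[1], dtype=float)
    for group in np.unique(labels):
        rows = normalized.to_numpy()[labels == group]
        slope = np.polyfit(ranks, rows.mean(axis=0), 1)[0]
        trend[int(group)] = int(np.sign(slope)) if slope != 0 else 0
    return {
        "order": order,
        "linkage": z,
        "labels": pd.Series(labels, index=normalized.index, name="cluster"),
        "trend_sign": trend,
    }
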