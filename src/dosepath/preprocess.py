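"""Microarray-style preprocessing for a dose-series experiment.

The chain is: eliminate probes whose foreground signal is below a
multiple of the local background, quantile-normalise the surviving
intensity columns, compute log2 treated/control ratios against the
single vehicle-control column, then collapse duplicate probes to genes
by averaging their ratios.  Differential genes are selected by a
fold-change threshold in at least one dose sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "filter_low_signal",
    "quantile_normalize",
    "collapse_probes",
    "compute_log_ratios",
    "select_differential",
    "preprocess_intensities",
]


def filter_low_signal(
    foreground: pd.DataFrame,
    background: pd.DataFrame,
    factor: float = 1.4,
    mode: str = "all",
) -> tuple:
    """Drop probes whose signal is below ``factor`` x local background.

    ``mode='all'`` (default) keeps a probe only if foreground >=
    factor * background in every sample; ``mode='any'`` keeps it if the
    criterion holds in at least one sample.  Returns the retained
    foreground submatrix and the number of eliminated probes.
    """
    if foreground.empty:
        raise ValueError("empty intensity matrix")
    if factor < 0:
        raise ValueError("factor must be non-negative")
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    ok = foreground.to_numpy() >= factor * background.loc[
        foreground.index, foreground.columns
    ].to_numpy()
    keep = ok.all(axis=1) if mode == "all" else ok.any(axis=1)
    return foreground.loc[keep], int((~keep).sum())


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of sorted means.

    Each column's sorted values are replaced by the row-wise mean of
    all columns' sorted values; within-column rank order is preserved.
    Ties receive the average of the sorted-mean values across the tied
    ranks.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to quantile normalize")
    x = matrix.to_numpy(dtype=float)
    sorted_means = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        ranks = rankdata(col, method="average")  # 1-based, .5 on ties
        # linear interpolation on the sorted-mean vector handles tied
        # pairs exactly; larger tie groups get the group-mean value
        order = np.argsort(col, kind="mergesort")
        group_vals = pd.Series(sorted_means).groupby(
            pd.Series(col[order]).rank(method="average").to_numpy()
        ).mean()
        out[:, j] = group_vals.loc[ranks].to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def compute_log_ratios(
    treated: pd.DataFrame, control: pd.Series
) -> pd.DataFrame:
    """log2(treated / control) per probe (or gene) per dose sample."""
    t = treated.to_numpy(dtype=float)
    c = control.loc[treated.index].to_numpy(dtype=float)
    if (c <= 0).any():
        bad = treated.index[np.nonzero(c <= 0)[0][0]]
        raise ValueError(f"non-positive control intensity for {bad!r}")
    if (t <= 0).any():
        i, j = np.argwhere(t <= 0)[0]
        raise ValueError(
            f"non-positive intensity for {treated.index[i]!r} "
            f"in sample {treated.columns[j]!r}"
        )
    return pd.DataFrame(
        np.log2(t / c[:, None]), index=treated.index, columns=treated.columns
    )


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: dict) -> pd.DataFrame:
    """Average duplicate probes per gene; unmapped probes are dropped."""
    genes = matrix.index.map(probe_to_gene.get)
    keep = genes.notna()
    collapsed = matrix.loc[keep].groupby(genes[keep]).mean()
    collapsed.index.name = "gene"
    return collapsed


def select_differential(expr: pd.DataFrame, fold_threshold: float = 2.0) -> list:
    """Genes with |log2 ratio| >= log2(threshold) in at least one sample."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    cut = np.log2(fold_threshold)
    mask = (expr.abs() >= cut).any(axis=1)
    return list(expr.index[mask])


def preprocess_intensities(
    foreground: pd.DataFrame,
    background: pd.DataFrame,
    probe_to_gene: dict,
    control_column: str,
    bg_factor: float = 1.4,
    bg_mode: str = "all",
) -> pd.DataFrame:
    """Full chain: filter -> quantile normalize -> ratio -> collapse."""
    kept, _ = filter_low_signal(foreground, background, bg_factor, bg_mode)
    norm = quantile_normalize(kept)
    treated = norm.drop(columns=[control_column])
    ratios = compute_log_ratios(treated, norm[control_column])
    return collapse_probes(ratios, probe_to_gene)
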