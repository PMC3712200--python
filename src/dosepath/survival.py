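"""Univariate Cox screening and the pattern-vs-hazard reciprocity test.

Each gene's expression is screened against survival with a univariate
Cox proportional-hazards fit (Newton-Raphson on the partial likelihood,
Breslow tie handling) whose p-value comes, by default, from a
subject-permutation null of the coefficient.  Screened genes carrying a
dose-pattern label are cross-tabulated as pattern (down/up) against
hazard-ratio direction (>1 / <1) and the 2x2 table is tested with a
two-sided Fisher exact test, quantifying whether dose-downregulated
genes are preferentially high-risk and upregulated genes protective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

__all__ = [
    "ContingencyResult",
    "cox_univariate",
    "permutation_p",
    "select_survival_genes",
    "cross_tabulate",
    "fisher_exact_2x2",
    "load_pattern_survival_table",
    "screen_genes",
]

_MAX_ITER = 50
_SCORE_TOL = 1e-8


def _newton_cox(time, event, x) -> np.ndarray:
    """Univariate Cox coefficients for each column of ``x``.

    Breslow tie handling: tied event times share one risk set.
    Vectorised over columns so a permutation null costs one call.
    """
    time = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=bool)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != time.size:
        x = x.T
    order = np.argsort(time, kind="mergesort")
    t_s, d_s, x_s = time[order], d[order], x[order]
    # index of the first subject sharing each (tied) time
    first = np.searchsorted(t_s, t_s, side="left")
    ev_rows = first[d_s]
    x_ev_sum = x_s[d_s].sum(axis=0)

    def revcumsum(a):
        return np.cumsum(a[::-1], axis=0)[::-1]

    m = x.shape[1]
    beta = np.zeros(m)
    active = np.ones(m, dtype=bool)
    for _ in range(_MAX_ITER):
        bx = np.clip(beta[None, :] * x_s, -500, 500)
        w = np.exp(bx)
        r0 = revcumsum(w)[ev_rows]
        r1 = revcumsum(x_s * w)[ev_rows]
        r2 = revcumsum(x_s**2 * w)[ev_rows]
        mean = r1 / r0
        score = x_ev_sum - mean.sum(axis=0)
        info = (r2 / r0 - mean**2).sum(axis=0)
        step = np.where(info > 0, score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = np.where(active, beta + step, beta)
        active = active & (np.abs(score) >= _SCORE_TOL)
        if not active.any():
            break
    return beta


def cox_univariate(
    expression,
    time,
    event,
    p_method: str = "permutation",
    n_permutations: int = 10000,
    seed: int = 0,
    standardize: bool = True,
) -> tuple:
    """Univariate Cox fit for one gene: (beta, hazard_ratio, p).

    The covariate is z-scored by default so the hazard ratio is per
    standard deviation of expression.  ``p_method`` is ``'permutation'``
    (subject-to-expression assignment permuted, two-sided on |beta|) or
    ``'wald'``.
    """
    x = np.asarray(expression, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if not np.isfinite(x).all():
        raise ValueError("covariate must be finite")
    if np.isclose(x.std(), 0.0):
        warnings.warn("zero-variance covariate; hazard ratio fixed at 1")
        return 0.0, 1.0, 1.0
    if standardize:
        x = (x - x.mean()) / x.std()
    beta = float(_newton_cox(time, event, x[:, None])[0])
    if p_method == "permutation":
        p = permutation_p(
            x, time, event, n_permutations=n_permutations, seed=seed,
            beta_obs=beta,
        )
    elif p_method == "wald":
        se = _wald_se(time, event, x, beta)
        p = float(2 * chi2.sf((beta / se) ** 2, 1)) if se > 0 else 1.0
    else:
        raise ValueError("p_method must be 'permutation' or 'wald'")
    return beta, float(np.exp(beta)), p


def _wald_se(time, event, x, beta) -> float:
    time = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=bool)
    order = np.argsort(time, kind="mergesort")
    t_s, d_s, x_s = time[order], d[order], np.asarray(x, float)[order]
    first = np.searchsorted(t_s, t_s, side="left")
    w = np.exp(np.clip(beta * x_s, -500, 500))
    r0 = np.cumsum(w[::-1])[::-1][first[d_s]]
    r1 = np.cumsum((x_s * w)[::-1])[::-1][first[d_s]]
    r2 = np.cumsum((x_s**2 * w)[::-1])[::-1][first[d_s]]
    info = float((r2 / r0 - (r1 / r0) ** 2).sum())
    return 1.0 / np.sqrt(info) if info > 0 else 0.0


def permutation_p(
    expression,
    time,
    event,
    n_permutations: int = 10000,
    seed: int = 0,
    beta_obs: float | None = None,
) -> float:
    """Two-sided permutation p for the univariate Cox coefficient.

    Null coefficients are refit with the subject-to-expression
    assignment permuted; p = fraction of |beta_null| >= |beta_obs|,
    floored at 1/n_permutations.
    """
    x = np.asarray(expression, dtype=float)
    if beta_obs is None:
        beta_obs = float(_newton_cox(time, event, x[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((x.size, n_permutations))
    for b in range(n_permutations):
        perms[:, b] = x[rng.permutation(x.size)]
    beta_null = _newton_cox(time, event, perms)
    frac = float(np.mean(np.abs(beta_null) >= abs(beta_obs)))
    return max(frac, 1.0 / n_permutations)


def select_survival_genes(table: pd.DataFrame, alpha: float = 0.05):
    """Genes whose screening p-value is below ``alpha``."""
    return set(table.index[table["p"] < alpha])


@dataclass
class ContingencyResult:
    """2x2 cross-tabulation of dose pattern vs hazard-ratio direction.

    Rows: down-/up-pattern; columns: hazard ratio > 1 / < 1.
    """

    counts: np.ndarray
    odds_ratio: float
    p: float
    excluded_unit_hr: int = 0


def fisher_exact_2x2(counts) -> tuple:
    """Two-sided Fisher exact test on a 2x2 table.

    The two-sided p sums the probabilities of all tables with the same
    margins whose hypergeometric probability does not exceed the
    observed table's (with a 1e-7 relative tolerance for float ties) —
    the minimum-likelihood convention.  Returns
    (odds_ratio = ad/bc, p).
    """
    t = np.asarray(counts, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("counts must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    row1, col1 = a + b, a + c
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return odds, min(p, 1.0)


def cross_tabulate(table: pd.DataFrame, alpha: float = 0.05) -> ContingencyResult:
    """Cross-tabulate screened pattern genes by hazard-ratio direction.

    Keeps genes with pattern in {down, up} and screening p < alpha;
    genes with hazard ratio exactly 1 are excluded with a warning.
    Cell layout: a = down & HR>1, b = down & HR<1, c = up & HR>1,
    d = up & HR<1; odds ratio = ad/bc.
    """
    if table.empty:
        raise ValueError("empty survival table")
    sub = table[table["pattern"].isin(["down", "up"]) & (table["p"] < alpha)]
    unit = sub["hazard_ratio"] == 1.0
    if unit.any():
        warnings.warn(f"excluding {int(unit.sum())} gene(s) with hazard ratio 1")
    sub = sub[~unit]
    counts = np.array(
        [
            [
                int(((sub["pattern"] == r) & (sub["hazard_ratio"] > 1)).sum()),
                int(((sub["pattern"] == r) & (sub["hazard_ratio"] < 1)).sum()),
            ]
            for r in ("down", "up")
        ]
    )
    odds, p = fisher_exact_2x2(counts)
    return ContingencyResult(counts, odds, p, excluded_unit_hr=int(unit.sum()))


def load_pattern_survival_table() -> pd.DataFrame:
    """Packaged gene-level screening table for the dose-pattern genes.

    Columns: pattern (down/up), fold (log2 ratio at the top dose),
    p (survival screening p-value), hazard_ratio; indexed by gene
    symbol.  Curated from a published lung-carcinoma survival screen of
    the dose-pattern genes; used as in-repo test data for the
    cross-tabulation chain.
    """
    with resources.files("dosepath").joinpath("data/table3.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", index_col="gene")
    return table


def screen_genes(
    clinical: pd.DataFrame,
    genes,
    pattern_labels: dict | None = None,
    p_method: str = "permutation",
    n_permutations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Univariate Cox screen over many genes of a survival cohort.

    ``clinical`` must carry ``time`` and ``event`` columns plus one
    column per gene.  Returns a table (gene-indexed) with beta,
    hazard_ratio, p and the optional pattern label.
    """
    rng = np.random.default_rng(seed)
    time = clinical["time"].to_numpy()
    event = clinical["event"].to_numpy()
    rows = []
    for g in genes:
        beta, hr, p = cox_univariate(
            clinical[g].to_numpy(), time, event,
            p_method=p_method, n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        rows.append((g, beta, hr, p))
    out = pd.DataFrame(
        rows, columns=["gene", "beta", "hazard_ratio", "p"]
    ).set_index("gene")
    if pattern_labels is not None:
        out["pattern"] = [pattern_labels.get(g, "none") for g in out.index]
    return out
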