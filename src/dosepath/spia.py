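"""Topology-based signaling pathway impact analysis.

Combines two independent lines of evidence per pathway: P_NDE, the
hypergeometric over-representation of differential genes on the
pathway, and P_PERT, a bootstrap probability for the pathway's total
net perturbation accumulation tA.  Perturbation factors PF solve
PF = dE + B.PF, where B is the pathway's signed influence matrix with
each column normalised by the source gene's outgoing-edge count, and
dE holds the log2 fold-changes of the pathway's differential genes.
The two probabilities are merged with Fisher's product rule into a
global P_G, then classified against Bonferroni and FDR thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dosepath.enrichment import bh_adjust, hypergeom_tail
from dosepath.synthetic import PathwayTopology

__all__ = [
    "SpiaResult",
    "p_nde",
    "perturbation_factors",
    "p_pert",
    "combine_global",
    "classify",
    "run_spia",
]

_SOLVE_TOL = 1e-8


@dataclass
class SpiaResult:
    pathway: str
    n_de: int
    t_a: float
    p_nde: float
    p_pert: float
    p_g: float
    significance: str = "ns"  # bonferroni | fdr | ns
    analyzable: bool = True


def p_nde(
    n_de_on_pathway: int, pathway_size: int, n_de_total: int, universe_size: int
) -> float:
    """Hypergeometric upper-tail over-representation probability."""
    if n_de_on_pathway > min(pathway_size, n_de_total):
        raise ValueError("inconsistent counts")
    if max(pathway_size, n_de_total) > universe_size:
        raise ValueError("counts exceed universe size")
    return hypergeom_tail(n_de_on_pathway, universe_size, pathway_size, n_de_total)


def perturbation_factors(topology: PathwayTopology, delta_e) -> tuple:
    """Solve PF = dE + B.PF; return (PF, tA).

    tA is the summed net accumulation sum(PF - dE).  Raises
    ``np.linalg.LinAlgError`` when (I - B) is singular; callers treat
    such pathways as unanalyzable.
    """
    b = topology.b_matrix
    de = np.asarray(delta_e, dtype=float)
    n = b.shape[0]
    if de.shape != (n,):
        raise ValueError("delta_e length must match pathway size")
    pf = np.linalg.solve(np.eye(n) - b, de)
    residual = np.max(np.abs((np.eye(n) - b) @ pf - de)) if n else 0.0
    if residual > _SOLVE_TOL:
        raise np.linalg.LinAlgError(
            f"ill-conditioned topology: solve residual {residual:.2e}"
        )
    acc = pf - de
    return pf, float(acc.sum())


def p_pert(
    topology: PathwayTopology,
    delta_e_observed,
    all_gene_log_ratios,
    n_boot: int = 3000,
    seed: int = 0,
) -> tuple:
    """Bootstrap probability for the observed net accumulation tA.

    Null tA values come from placing the observed number of
    differential genes at random pathway positions with fold-changes
    resampled (with replacement) from the pool of all differential-gene
    log-ratios.  P_PERT is the two-sided tail around the null median,
    floored at 1/n_boot.  Returns (p_pert, tA_observed).
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap rounds")
    de = np.asarray(delta_e_observed, dtype=float)
    n_de = int(np.count_nonzero(de))
    _, ta_obs = perturbation_factors(topology, de)
    if n_de == 0:
        return 1.0, ta_obs

    rng = np.random.default_rng(seed)
    pool = np.asarray(all_gene_log_ratios, dtype=float)
    if pool.size == 0:
        raise ValueError("empty resampling pool")
    n = len(topology.genes)
    # tA is linear in dE: tA = w.dE with w the column sums of
    # (I - B)^-1 - I, so the bootstrap reduces to resampled dot products
    m = np.linalg.inv(np.eye(n) - topology.b_matrix)
    w = (m - np.eye(n)).sum(axis=0)
    ta_null = np.empty(n_boot)
    for b in range(n_boot):
        pos = rng.choice(n, size=n_de, replace=False)
        vals = rng.choice(pool, size=n_de, replace=True)
        ta_null[b] = w[pos] @ vals
    med = np.median(ta_null)
    tail = np.mean(np.abs(ta_null - med) >= np.abs(ta_obs - med))
    return float(max(tail, 1.0 / n_boot)), ta_obs


def combine_global(p_nde_value: float, p_pert_value: float) -> float:
    """Fisher product combination: P_G = c - c*ln(c), c = p1*p2.

    Equals the chi-square(4 df) upper tail at -2 ln c.
    """
    if not (0 < p_nde_value <= 1 and 0 < p_pert_value <= 1):
        raise ValueError("probabilities must lie in (0, 1]")
    c = p_nde_value * p_pert_value
    if c == 1.0:
        return 1.0
    return float(c - c * np.log(c))


def classify(results: list, alpha: float = 0.01) -> list:
    """Annotate analyzable results with significance classes.

    ``bonferroni`` if P_G <= alpha/M, else ``fdr`` if the BH-adjusted
    P_G <= alpha, else ``ns``.  Unanalyzable pathways keep class 'ns'
    and are excluded from M.
    """
    analyzable = [r for r in results if r.analyzable]
    if not analyzable:
        return results
    m = len(analyzable)
    adj = bh_adjust([r.p_g for r in analyzable])
    for r, q in zip(analyzable, adj):
        if r.p_g <= alpha / m:
            r.significance = "bonferroni"
        elif q <= alpha:
            r.significance = "fdr"
        else:
            r.significance = "ns"
    return results


def run_spia(
    topologies: dict,
    de_log_ratios: dict,
    universe,
    n_boot: int = 3000,
    alpha: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Impact analysis over a collection of pathway topologies.

    ``topologies`` maps pathway name -> PathwayTopology;
    ``de_log_ratios`` maps differential gene -> log2 fold-change;
    ``universe`` is the background gene set.  Pathways with no
    differential genes or a singular (I - B) are reported with
    ``analyzable = False`` and excluded from classification.
    """
    universe = set(universe)
    de_genes = set(de_log_ratios)
    pool = np.array(list(de_log_ratios.values()), dtype=float)
    rng = np.random.default_rng(seed)
    results = []
    for name, topo in topologies.items():
        genes = [g for g in topo.genes if g in universe]
        size = len(genes)
        on_path = [g for g in topo.genes if g in de_genes]
        n_de = len(on_path)
        de_vec = np.array(
            [de_log_ratios.get(g, 0.0) for g in topo.genes], dtype=float
        )
        res = SpiaResult(name, n_de, np.nan, 1.0, 1.0, 1.0)
        if n_de == 0:
            res.analyzable = False
            results.append(res)
            continue
        try:
            res.p_pert, res.t_a = p_pert(
                topo, de_vec, pool, n_boot=n_boot,
                seed=int(rng.integers(2**31 - 1)),
            )
        except np.linalg.LinAlgError:
            res.analyzable = False
            results.append(res)
            continue
        res.p_nde = p_nde(n_de, size, len(de_genes & universe), len(universe))
        res.p_g = combine_global(res.p_nde, res.p_pert)
        results.append(res)
    classify(results, alpha=alpha)
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "N_DE": [r.n_de for r in results],
            "tA": [r.t_a for r in results],
            "P_NDE": [r.p_nde for r in results],
            "P_PERT": [r.p_pert for r in results],
            "P_G": [r.p_g for r in results],
            "class": [r.significance for r in results],
            "analyzable": [r.analyzable for r in results],
        }
    ).set_index("pathway")
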