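"""Synthetic data generators for the dose-response pipeline.

Every input the analysis consumes can be generated here with planted
structure: a dose-series expression matrix with monotone up/down gene
groups, overlapping signed gene sets, signed directed pathway
topologies, and survival cohorts whose hazard depends on chosen genes.
All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DoseDesign",
    "PlantedTruth",
    "PathwayTopology",
    "generate_dose_expression",
    "generate_gene_sets",
    "generate_topology",
    "generate_survival",
    "raw_from_log_ratios",
    "generate_reciprocal_study",
]


@dataclass(frozen=True)
class DoseDesign:
    """Ordered dose series; the first level is the vehicle control (0).

    Parameters
    ----------
    dose_levels : tuple of float
        Strictly increasing concentrations (µg/mL); first entry must be 0.
    replicate_count : int
        Arrays per dose level.  Default 1: a single array per dose,
        which is the design the pipeline's defaults assume.
    """

    dose_levels: tuple = (0.0, 1.25, 5.0, 20.0)
    replicate_count: int = 1

    def __post_init__(self):
        levels = tuple(float(d) for d in self.dose_levels)
        if len(levels) < 3:
            raise ValueError("need at least 3 dose levels (control + 2 doses)")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("dose_levels must be strictly increasing")
        if levels[0] != 0.0:
            raise ValueError("first dose level must be the vehicle control (0)")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be positive")
        object.__setattr__(self, "dose_levels", levels)

    @property
    def treated_levels(self) -> tuple:
        return self.dose_levels[1:]

    @property
    def sample_labels(self) -> list:
        """Column labels for the treated samples, in dose order."""
        labels = []
        for d in self.treated_levels:
            name = f"{d:g}"
            if self.replicate_count == 1:
                labels.append(name)
            else:
                labels.extend(f"{name}_r{i + 1}" for i in range(self.replicate_count))
        return labels


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth gene partition for a planted simulation.

    ``up_genes`` rise monotonically with dose to ``effect_size`` log2
    units at the top dose, ``down_genes`` mirror them, ``null_genes``
    have expectation zero.  The three sets must partition the universe.
    """

    up_genes: frozenset
    down_genes: frozenset
    null_genes: frozenset
    effect_size: float = 3.0
    noise_sd: float = 0.5

    def __post_init__(self):
        up = frozenset(self.up_genes)
        down = frozenset(self.down_genes)
        null = frozenset(self.null_genes)
        if up & down or up & null or down & null:
            raise ValueError("up/down/null gene sets must be disjoint")
        if not (up | down | null):
            raise ValueError("empty gene universe")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", down)
        object.__setattr__(self, "null_genes", null)

    @property
    def universe(self) -> list:
        return sorted(self.up_genes | self.down_genes | self.null_genes)


@dataclass
class PathwayTopology:
    """Signed, directed gene-gene influence structure for one pathway.

    ``beta`` holds raw edge signs (rows = targets, columns = sources,
    entries in {-1, 0, +1}); ``b_matrix`` is ``beta`` with each column
    divided by that source gene's outgoing-edge count (zero columns stay
    zero), the normalisation used by pathway impact analysis.
    """

    genes: list
    beta: np.ndarray
    b_matrix: np.ndarray = field(default=None)
    spectral_radius: float = field(default=None)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        n = len(self.genes)
        if self.beta.shape != (n, n):
            raise ValueError("beta must be square over the pathway genes")
        if self.b_matrix is None:
            out_deg = np.count_nonzero(self.beta, axis=0).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                b = np.where(out_deg > 0, self.beta / out_deg, 0.0)
            self.b_matrix = b
        if self.spectral_radius is None:
            if n:
                self.spectral_radius = float(np.max(np.abs(np.linalg.eigvals(self.b_matrix))))
            else:
                self.spectral_radius = 0.0


def _profile_means(design: DoseDesign, effect_size: float) -> np.ndarray:
    # linear in dose rank, anchored at 0 for the control, reaching
    # effect_size at the top dose
    n_treated = len(design.treated_levels)
    ranks = np.arange(1, n_treated + 1, dtype=float)
    per_level = effect_size * ranks / n_treated
    return np.repeat(per_level, design.replicate_count)


def generate_dose_expression(
    design: DoseDesign, truth: PlantedTruth, seed: int
) -> pd.DataFrame:
    """Simulate a genes x treated-samples matrix of log2 ratios.

    Planted up genes have expected profiles linear in dose rank scaled
    to ``truth.effect_size`` at the top dose; down genes are the mirror
    image; null genes have expectation 0.  I.i.d. Gaussian noise with
    sd ``truth.noise_sd`` is added everywhere.
    """
    rng = np.random.default_rng(seed)
    genes = truth.universe
    labels = design.sample_labels
    means = np.zeros((len(genes), len(labels)))
    profile = _profile_means(design, truth.effect_size)
    up_mask = np.array([g in truth.up_genes for g in genes])
    down_mask = np.array([g in truth.down_genes for g in genes])
    means[up_mask] = profile
    means[down_mask] = -profile
    values = means + rng.normal(0.0, truth.noise_sd, size=means.shape)
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=labels)


def generate_gene_sets(
    universe: list,
    n_sets: int,
    size_range: tuple,
    overlap_fraction: float,
    repressor_fraction: float,
    seed: int,
    prefix: str = "SET",
) -> dict:
    """Generate overlapping signed gene sets over a gene universe.

    Returns a mapping ``set name -> {gene: sign}`` with signs in
    {+1, -1}; each gene is a repressor (-1) with probability
    ``repressor_fraction``.  Overlap is induced by drawing a fraction of
    each set from a small shared core pool sized like one set, so the
    expected pairwise shared-gene (Jaccard) fraction approximates
    ``overlap_fraction``.  With ``overlap_fraction == 0`` and enough
    capacity, the sets are made exactly disjoint.
    """
    lo, hi = int(size_range[0]), int(size_range[1])
    if n_sets <= 0:
        raise ValueError("n_sets must be positive")
    if lo > hi or lo < 1:
        raise ValueError("invalid size_range")
    if hi > len(universe):
        raise ValueError("size_range exceeds universe size")
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sizes = rng.integers(lo, hi + 1, size=n_sets)

    members: list = []
    if overlap_fraction == 0 and int(sizes.sum()) <= len(universe):
        pool = list(rng.permutation(universe))
        start = 0
        for s in sizes:
            members.append(pool[start : start + int(s)])
            start += int(s)
    else:
        # For two sets each drawing a fraction f of its members from a
        # shared core of size ~ one set, expected Jaccard is
        # f^2 / (2 - f^2); invert for f.
        f = float(np.sqrt(2 * overlap_fraction / (1 + overlap_fraction)))
        core_size = max(1, int(round(sizes.mean())))
        core = rng.choice(len(universe), size=core_size, replace=False)
        core_genes = [universe[i] for i in core]
        rest = [g for g in universe if g not in set(core_genes)]
        for s in sizes:
            n_core = min(int(round(f * int(s))), core_size)
            # small universes: top up from the core when the non-core
            # remainder cannot supply the rest of the set
            n_core = max(n_core, int(s) - len(rest))
            chosen = list(rng.choice(core_genes, size=n_core, replace=False))
            chosen += list(rng.choice(rest, size=int(s) - n_core, replace=False))
            members.append(chosen)

    collection = {}
    for i, genes in enumerate(members):
        signs = np.where(rng.random(len(genes)) < repressor_fraction, -1, 1)
        collection[f"{prefix}{i + 1:03d}"] = {
            g: int(w) for g, w in zip(genes, signs)
        }
    return collection


def generate_topology(
    gene_set: list, edge_density: float, activation_prob: float, seed: int
) -> PathwayTopology:
    """Random signed directed topology over a pathway's genes.

    Each ordered pair (no self loops) carries an edge with probability
    ``edge_density``; the edge is activating (+1) with probability
    ``activation_prob``, else inhibiting (-1).
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene_set must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(genes)
    present = rng.random((n, n)) < edge_density
    np.fill_diagonal(present, False)
    signs = np.where(rng.random((n, n)) < activation_prob, 1.0, -1.0)
    beta = np.where(present, signs, 0.0)
    return PathwayTopology(genes=genes, beta=beta)


def generate_survival(
    expression: pd.DataFrame | None,
    risk_genes: dict,
    baseline_hazard: float,
    censor_rate: float,
    n_subjects: int,
    seed: int,
    extra_genes: list | None = None,
) -> pd.DataFrame:
    """Simulate a survival cohort under an exponential hazards model.

    Event times are exponential with per-subject rate
    ``baseline_hazard * exp(sum coefficient * expression)``.  Censoring
    is by an independent exponential whose rate is calibrated so that
    the expected censored fraction equals ``censor_rate`` under zero
    coefficients.  If ``expression`` is None, per-subject gene values
    are drawn i.i.d. standard normal for the risk genes plus any
    ``extra_genes``.

    Returns a DataFrame indexed by subject with columns ``time``,
    ``event`` (1 = death observed) and one column per gene.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if n_subjects < 20:
        raise ValueError("need at least 20 subjects")
    rng = np.random.default_rng(seed)

    if expression is None:
        genes = list(risk_genes) + [
            g for g in (extra_genes or []) if g not in risk_genes
        ]
        expr = pd.DataFrame(
            rng.standard_normal((n_subjects, len(genes))),
            index=[f"S{i + 1:04d}" for i in range(n_subjects)],
            columns=genes,
        )
    else:
        expr = expression.copy()
        if len(expr) != n_subjects:
            raise ValueError("expression rows must match n_subjects")

    coef = np.zeros(expr.shape[1])
    for j, g in enumerate(expr.columns):
        coef[j] = risk_genes.get(g, 0.0)
    rate = baseline_hazard * np.exp(expr.to_numpy() @ coef)
    event_time = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_hazard = baseline_hazard * censor_rate / (1 - censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard, size=n_subjects)
    else:
        censor_time = np.full(n_subjects, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    out = pd.DataFrame({"time": time, "event": event}, index=expr.index)
    out.index.name = "subject"
    return pd.concat([out, expr], axis=1)


def raw_from_log_ratios(
    expr: pd.DataFrame,
    control_intensity: float = 1000.0,
    probes_per_gene: int = 2,
    background: float = 100.0,
    seed: int = 0,
) -> tuple:
    """Back out a probe-level intensity matrix from log2 ratios.

    Convenience for exercising the preprocessing chain on synthetic
    data: each gene gets ``probes_per_gene`` duplicate probes with a
    log-normal baseline abundance around ``control_intensity`` in the
    control column, treated columns at ``control * 2**ratio``, and a
    constant local background.  The per-probe baseline spread makes
    the columns quantile-comparable, the regime quantile normalization
    assumes.

    Returns ``(foreground, background, probe_to_gene)`` with the
    control column first.
    """
    rng = np.random.default_rng(seed)
    probes, rows, mapping = [], [], {}
    for gene, ratios in expr.iterrows():
        base = control_intensity * np.exp2(rng.normal(0, 1.5))
        for p in range(probes_per_gene):
            probe = f"{gene}_p{p + 1}"
            probes.append(probe)
            mapping[probe] = gene
            jitter = rng.normal(0, 0.01, size=len(ratios))
            treated = base * np.exp2(ratios.to_numpy() + jitter)
            rows.append(np.concatenate([[base], treated]))
    cols = ["control"] + list(expr.columns)
    fg = pd.DataFrame(rows, index=pd.Index(probes, name="probe"), columns=cols)
    bg = pd.DataFrame(background, index=fg.index, columns=cols)
    return fg, bg, mapping


def generate_reciprocal_study(
    seed: int,
    n_genes: int = 3000,
    frac_up: float = 0.1,
    frac_down: float = 0.1,
    effect_size: float = 3.0,
    noise_sd: float = 0.5,
    n_sets_per_family: int = 10,
    n_null_sets: int = 20,
    set_size_range: tuple = (20, 60),
    design: DoseDesign | None = None,
) -> dict:
    """Generate the full planted reciprocal study design.

    Builds an expression matrix with monotone down and up gene blocks,
    a "metabolic-like" gene-set family drawn from the down genes, a
    "signaling-like" family drawn from the up genes, and null sets
    drawn from unaffected genes — the desk-scale analogue of a
    dose-response study where metabolic pathways lose and signaling
    pathways gain activity with dose.

    Returns a dict with keys ``design``, ``truth``, ``expr``,
    ``collection`` (signed gene sets) and ``set_family``
    (set name -> 'metabolic' | 'signaling' | 'null').
    """
    design = design or DoseDesign()
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    n_up = int(frac_up * n_genes)
    n_down = int(frac_down * n_genes)
    perm = rng.permutation(genes)
    up = frozenset(perm[:n_up])
    down = frozenset(perm[n_up : n_up + n_down])
    null = frozenset(perm[n_up + n_down :])
    truth = PlantedTruth(up, down, null, effect_size=effect_size, noise_sd=noise_sd)
    expr = generate_dose_expression(design, truth, seed=seed)

    child = rng.integers(0, 2**31 - 1, size=3)

    def clamp(pool):
        lo, hi = set_size_range
        return min(int(lo), len(pool)), min(int(hi), len(pool))

    metabolic = generate_gene_sets(
        sorted(down), n_sets_per_family, clamp(down), 0.3, 0.0,
        seed=int(child[0]), prefix="MET",
    )
    signaling = generate_gene_sets(
        sorted(up), n_sets_per_family, clamp(up), 0.3, 0.0,
        seed=int(child[1]), prefix="SIG",
    )
    null_sets = generate_gene_sets(
        sorted(null), n_null_sets, clamp(null), 0.0, 0.0,
        seed=int(child[2]), prefix="NUL",
    )
    collection = {**metabolic, **signaling, **null_sets}
    family = {}
    for name in collection:
        family[name] = (
            "metabolic" if name.startswith("MET")
            else "signaling" if name.startswith("SIG")
            else "null"
        )
    return {
        "design": design,
        "truth": truth,
        "expr": expr,
        "collection": collection,
        "set_family": family,
    }
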