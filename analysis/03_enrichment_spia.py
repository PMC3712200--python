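"""Gene-set enrichment and topology-based pathway impact analysis.

Tests every gene set for over-representation in the Down- and
Up-pattern gene lists (one-sided Fisher with BH FDR), then runs the
impact analysis over the planted pathway topologies: hypergeometric
P_NDE, bootstrap perturbation P_PERT (n = 3,000) and the combined
global P_G classified at Bonferroni/FDR 1%.

Writes enrichment and impact tables under results/pathways/.
"""

import sys
from pathlib import Path

from dosepath import enrichment, io, preprocess, spia

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 17
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "pathways"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    expr = io.read_matrix(ROOT / "data" / "expression_log2_ratios.tsv")
    collection = io.read_gmt(ROOT / "data" / "gene_sets.gmt")
    universe = list(expr.index)

    for label in ("down", "up"):
        query = io.read_gene_list(ROOT / "patterns" / f"{label}_pattern.txt")
        res = enrichment.fisher_enrichment(query, collection, universe)
        io.write_matrix(res, OUT / f"enrichment_{label}.tsv")
        sig = res[res["fdr"] < 0.01]
        print(f"{label}-pattern: {len(sig)} sets enriched at FDR < 0.01 "
              f"(top: {', '.join(sig.index[:3])})")

    differential = preprocess.select_differential(expr, fold_threshold=2.0)
    top_dose = expr.columns[-1]
    de_ratios = expr.loc[differential, top_dose].to_dict()
    topo_dir = ROOT / "data" / "topologies"
    topologies = {
        path.stem: io.read_topology(path) for path in sorted(topo_dir.glob("*.tsv"))
    }
    impact = spia.run_spia(
        topologies, de_ratios, universe, n_boot=3000, alpha=0.01, seed=SEED
    )
    io.write_matrix(impact, OUT / "impact_analysis.tsv")
    counts = impact["class"].value_counts().to_dict()
    print(f"impact analysis over {len(impact)} pathways: {counts}")
    print(f"written under {OUT}")


if __name__ == "__main__":
    main()
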