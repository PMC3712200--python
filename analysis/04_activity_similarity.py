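"""Pathway-activity scoring, FDR screen, and similarity clustering.

Computes each pathway's signed activity per dose sample, screens
pathways with the random-gene-set permutation FDR (n = 1,000,
FDR < 0.05), z-scores and hierarchically clusters the survivors, then
builds the Jaccard similarity matrix of the screened pathways and
clusters it with top-dose activities merged onto the ordered output.

Writes activity, FDR, cluster and similarity tables under
results/activity/.
"""

import sys
from pathlib import Path

import pandas as pd

from dosepath import activity, io, similarity

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 17
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "activity"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    expr = io.read_matrix(ROOT / "data" / "expression_log2_ratios.tsv")
    collection = io.read_gmt(ROOT / "data" / "gene_sets.gmt")

    screen = activity.activity_fdr(
        expr, collection, n_permutations=1000, seed=SEED
    )
    io.write_matrix(screen, OUT / "activity_fdr.tsv")
    significant = list(screen.index[screen["fdr"] < 0.05])
    print(f"activity screen: {len(significant)}/{len(collection)} pathways "
          f"at FDR < 0.05")

    raw = activity.activity_matrix(expr, {n: collection[n] for n in significant})
    norm, flagged = activity.normalize_activities(raw)
    io.write_matrix(raw, OUT / "activity_raw.tsv")
    io.write_matrix(norm, OUT / "activity_normalized.tsv")

    clusters = activity.cluster_activities(norm)
    pd.DataFrame(
        {"cluster": clusters["labels"].loc[clusters["order"]]}
    ).to_csv(OUT / "activity_clusters.tsv", sep="\t")
    print(f"two activity sub-clusters with dose-trend signs "
          f"{clusters['trend_sign']}")

    j = similarity.jaccard_matrix({n: collection[n] for n in significant})
    sim = similarity.cluster_similarity(j, norm)
    io.write_matrix(sim["matrix"], OUT / "similarity_ordered.tsv")
    merged = pd.DataFrame(
        {"cluster": sim["labels"].loc[sim["order"]], "activity": sim["activity"]}
    )
    merged.to_csv(OUT / "similarity_clusters.tsv", sep="\t")
    by_cluster = merged.groupby("cluster")["activity"].mean()
    print("mean top-dose activity by similarity cluster:")
    print(by_cluster.to_string())
    print(f"written under {OUT}")


if __name__ == "__main__":
    main()
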