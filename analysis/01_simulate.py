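"""Generate the synthetic study inputs.

Emulates the study design the downstream analyses assume: a 4-point
dose series (0, 1.25, 5, 20 µg/mL, one array per dose) over 3,000
genes with 10% planted monotone-up and 10% monotone-down genes
(effect 3 log2 units at the top dose, noise sd 0.5), a metabolic-like
gene-set family over the down genes, a signaling-like family over the
up genes, null gene sets, random signed topologies for the planted
pathways, and a 130-subject survival cohort in which a sample of down
genes is high-risk and a sample of up genes protective.

Writes expression TSV, signed GMT, topology TSVs and the clinical TSV
under results/data/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from dosepath import io, synthetic

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 17
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    study = synthetic.generate_reciprocal_study(seed=SEED, n_genes=3000)
    expr, truth = study["expr"], study["truth"]
    io.write_matrix(expr, OUT / "expression_log2_ratios.tsv")
    io.write_gmt(study["collection"], OUT / "gene_sets.gmt")
    (OUT / "set_families.json").write_text(json.dumps(study["set_family"], indent=1))
    io.write_gene_list(sorted(truth.up_genes), OUT / "truth_up.txt")
    io.write_gene_list(sorted(truth.down_genes), OUT / "truth_down.txt")

    rng = np.random.default_rng(SEED + 1)
    topo_dir = OUT / "topologies"
    topo_dir.mkdir(exist_ok=True)
    for name, members in study["collection"].items():
        if study["set_family"][name] == "null":
            continue
        topo = synthetic.generate_topology(
            sorted(members), edge_density=0.08, activation_prob=0.8,
            seed=int(rng.integers(2**31 - 1)),
        )
        io.write_topology(topo, topo_dir / f"{name}.tsv")

    # survival cohort: 10 down genes high-risk, 10 up genes protective;
    # |coefficient| 0.5 keeps the log-hazard spread realistic
    down = sorted(truth.down_genes)[:10]
    up = sorted(truth.up_genes)[:10]
    risk = {g: 0.5 for g in down} | {g: -0.5 for g in up}
    cohort = synthetic.generate_survival(
        None, risk, baseline_hazard=0.1, censor_rate=0.2,
        n_subjects=130, seed=SEED + 2,
    )
    cohort.to_csv(OUT / "clinical.tsv", sep="\t")

    print(f"expression: {expr.shape[0]} genes x {expr.shape[1]} dose samples")
    print(f"gene sets: {len(study['collection'])} "
          f"({sum(1 for f in study['set_family'].values() if f != 'null')} planted)")
    print(f"survival cohort: {len(cohort)} subjects, "
          f"{int(cohort['event'].sum())} events")
    print(f"written under {OUT}")


if __name__ == "__main__":
    main()
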