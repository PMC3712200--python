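"""Mine dose-dependent expression patterns.

Selects differential genes (|log2 ratio| >= 1 in at least one dose),
assigns every gene to its best-correlated model profile, computes
per-profile permutation significance (1,000 rounds) and unions the
significant monotone profiles into the Down- and Up-pattern gene sets.

Writes the per-profile summary and the two pattern gene lists under
results/patterns/.
"""

import sys
from pathlib import Path

from dosepath import io, patterns, preprocess

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 17
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "patterns"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    expr = io.read_matrix(ROOT / "data" / "expression_log2_ratios.tsv")
    differential = preprocess.select_differential(expr, fold_threshold=2.0)
    print(f"differential genes (2-fold in >=1 sample): {len(differential)}")

    cfg = patterns.PatternConfig(n_permutations=1000, seed=SEED)
    assignment = patterns.mine_patterns(expr, cfg)
    down, up = patterns.build_patterns(assignment, fdr_threshold=0.001)

    table = assignment.profile_table.sort_values("fdr")
    io.write_matrix(table, OUT / "profile_summary.tsv")
    io.write_gene_list(sorted(down), OUT / "down_pattern.txt")
    io.write_gene_list(sorted(up), OUT / "up_pattern.txt")

    n_sig = int((table["fdr"] < 0.001).sum())
    print(f"profiles: {len(table)} mined, {n_sig} significant (FDR < 0.001)")
    print(f"Down-pattern: {len(down)} genes; Up-pattern: {len(up)} genes")
    print(f"written under {OUT}")


if __name__ == "__main__":
    main()
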