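"""Plain-text readers and writers for the pipeline's file formats.

Expression matrices and tables are tab-separated; gene sets use a
GMT-style format with one set per line (name, description, members),
where a member may carry a sign suffix ``GENE|+1`` or ``GENE|-1``
marking activators and repressors.  Topologies are 3-column TSV edge
lists (source, target, sign).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_topology",
    "write_topology",
    "read_gene_list",
    "write_gene_list",
]


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_gmt(path) -> dict:
    """Read sign-annotated GMT; members without a suffix default to +1."""
    collection: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, members = parts[0], parts[2:]
            signed = {}
            for m in members:
                if not m:
                    continue
                if "|" in m:
                    gene, sign = m.rsplit("|", 1)
                    signed[gene] = int(sign)
                else:
                    signed[m] = 1
            collection[name] = signed
    return collection


def write_gmt(collection: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            cells = [name, description]
            cells += [f"{g}|{s:+d}" for g, s in members.items()]
            fh.write("\t".join(cells) + "\n")


def read_topology(path, genes: list | None = None):
    """Read a (source, target, sign) edge list into a PathwayTopology.

    ``genes`` fixes the node order and universe; by default the sorted
    union of endpoints is used.
    """
    from dosepath.synthetic import PathwayTopology

    edges = pd.read_csv(path, sep="\t")
    edges.columns = [c.lower() for c in edges.columns]
    if genes is None:
        genes = sorted(set(edges["source"]) | set(edges["target"]))
    idx = {g: i for i, g in enumerate(genes)}
    beta = np.zeros((len(genes), len(genes)))
    for _, row in edges.iterrows():
        beta[idx[row["target"]], idx[row["source"]]] = float(row["sign"])
    return PathwayTopology(genes=list(genes), beta=beta)


def write_topology(topology, path) -> None:
    rows = []
    for t, s in zip(*np.nonzero(topology.beta)):
        rows.append(
            (topology.genes[s], topology.genes[t], int(topology.beta[t, s]))
        )
    pd.DataFrame(rows, columns=["source", "target", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
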