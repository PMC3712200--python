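"""Pathway similarity from shared gene membership.

Similarity between two pathways is the Jaccard index of their gene
sets — the fraction of common genes among all genes present in either
pathway, so joint absences never contribute.  The matrix is clustered
hierarchically on the 1 - J distance and each pathway's activity at
the top dose is attached to the ordered output, mirroring a clustered
similarity heatmap with an activity margin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

__all__ = ["jaccard_matrix", "cluster_similarity"]


def jaccard_matrix(collection: dict) -> pd.DataFrame:
    """Symmetric Jaccard similarity over a gene-set collection.

    Signs are ignored (membership only); pairs with an empty union are
    defined as 0; the diagonal is 1.
    """
    if not collection:
        raise ValueError("empty collection")
    names = list(collection)
    sets = [set(collection[n]) for n in names]
    n = len(names)
    j = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            union = len(sets[a] | sets[b])
            j[a, b] = j[b, a] = (
                len(sets[a] & sets[b]) / union if union else 0.0
            )
    return pd.DataFrame(j, index=names, columns=names)


def cluster_similarity(
    j: pd.DataFrame,
    activities: pd.DataFrame | None = None,
    linkage_method: str = "average",
) -> dict:
    """Cluster the similarity matrix and merge in pathway activities.

    Clustering uses only the 1 - J distance; the attached annotation
    is each pathway's normalized activity in the last (top-dose)
    sample.  Activity pathway ids must be a subset of the similarity
    matrix's ids.
    """
    if len(j) < 2:
        raise ValueError("need at least 2 pathways")
    if activities is not None and not set(activities.index) <= set(j.index):
        raise ValueError("activity pathway ids not in the similarity matrix")
    dist = 1.0 - j.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    order = [j.index[i] for i in leaves_list(z)]
    labels = fcluster(z, t=2, criterion="maxclust")
    ordered = j.loc[order, order]
    annotation = None
    if activities is not None:
        top_dose = activities.columns[-1]
        annotation = activities[top_dose].reindex(order)
        annotation.name = "activity"
    return {
        "order": order,
        "matrix": ordered,
        "linkage": z,
        "labels": pd.Series(labels, index=j.index, name="cluster"),
        "activity": annotation,
    }
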