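"""Cross-sample (beta-diversity) comparison from a joint OTU clustering.

After clustering the pooled reads of several samples, each sample is
represented by the *set* of OTU labels its reads fall into (presence /
absence, no abundance weighting). Samples are compared by the Jaccard
index of their label sets and grouped by average-linkage hierarchical
clustering of the 1 - J distances.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .clustering import OTUAssignment


def otu_sets_by_sample(assignment: OTUAssignment) -> dict[str, set[str]]:
    """OTU label set per sample, from a joint clustering with sample ids."""
    sids = assignment.sample_ids
    if not sids:
        return {"sample": set(assignment.labels.values())}
    out: dict[str, set[str]] = {}
    for seq_id, otu in assignment.labels.items():
        out.setdefault(sids.get(seq_id, "sample"), set()).add(otu)
    return out


def jaccard_index(a: set[str], b: set[str]) -> float:
    """|a & b| / |a | b|; undefined when both sets are empty."""
    if not a and not b:
        raise ValueError("undefined similarity: both OTU sets empty")
    return len(a & b) / len(a | b)


def similarity_matrix(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Square symmetric Jaccard matrix over samples, diagonal 1.0."""
    if len(sets) < 2:
        raise ValueError("need at least 2 samples")
    names = list(sets)
    m = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            m[i, j] = m[j, i] = jaccard_index(sets[names[i]], sets[names[j]])
    return pd.DataFrame(m, index=names, columns=names)


def cluster_samples(
    matrix: pd.DataFrame, linkage: str = "average"
) -> tuple[str, np.ndarray]:
    """Agglomerate samples on 1 - Jaccard distances.

    Returns ``(newick, Z)``: a Newick serialization whose branch lengths
    are derived from the merge heights, plus the scipy linkage matrix.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    dist = 1.0 - matrix.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    tree = TreeNode.from_linkage_matrix(z, list(matrix.index))
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip(), z
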