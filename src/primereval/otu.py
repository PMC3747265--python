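"""Average-linkage (UPGMA-style) OTU clustering with hard distance cutoffs,
and SR/NFL richness ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import SequenceLibrary
from .phylo import DistanceMatrix, pairwise_seq_distance

__all__ = ["average_linkage_otus", "count_otus", "richness_ratio",
           "DEFAULT_CUTOFFS"]

DEFAULT_CUTOFFS = (0.01, 0.02, 0.03)


def average_linkage_otus(dm: DistanceMatrix, cutoff: float) -> dict[str, int]:
    """id -> cluster label after cutting the average-linkage dendrogram.

    Inter-cluster distance is the arithmetic mean over all cross pairs
    (Lance-Williams size-weighted update); merging stops once the minimum
    inter-cluster distance exceeds the cutoff. Ties break on the
    lexicographically smallest (label, label) pair, labels being each
    cluster's smallest member id, so the result is invariant to input
    order.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    order = sorted(range(len(dm)), key=lambda k: dm.ids[k])
    ids = [dm.ids[k] for k in order]
    D = dm.data[np.ix_(order, order)].astype(float).copy()
    np.fill_diagonal(D, np.inf)
    members: list[list[str]] = [[i] for i in ids]
    labels: list[str] = list(ids)
    sizes = np.ones(len(ids))

    while len(members) > 1:
        dmin = D.min()
        if dmin > cutoff:
            break
        tie = np.argwhere(D <= dmin + 1e-15)
        i, j = min(((tuple(sorted((labels[a], labels[b]))), (a, b))
                    for a, b in tie if a < b))[1]
        # Lance-Williams average-linkage update
        new_row = (sizes[i] * D[i] + sizes[j] * D[j]) / (sizes[i] + sizes[j])
        keep = [k for k in range(len(members)) if k not in (i, j)]
        n2 = len(keep) + 1
        D2 = np.full((n2, n2), np.inf)
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_row[keep]
        members = [members[k] for k in keep] + [members[i] + members[j]]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
        sizes = np.append(sizes[keep], sizes[i] + sizes[j])
        D = D2

    out: dict[str, int] = {}
    for cluster, (label, group) in enumerate(
            sorted(zip(labels, members))):
        for seq_id in group:
            out[seq_id] = cluster
    return out


def count_otus(dm: DistanceMatrix, cutoff: float) -> int:
    return len(set(average_linkage_otus(dm, cutoff).values()))


def richness_ratio(
    sr_library: SequenceLibrary,
    nfl_library: SequenceLibrary,
    cutoffs=DEFAULT_CUTOFFS,
    model: str = "p",
) -> pd.DataFrame:
    """OTU counts for both libraries and SR/NFL ratios per cutoff."""
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("cutoff list must be non-empty")
    shared = sorted(set(sr_library.ids) & set(nfl_library.ids))
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared ids")
    dm_sr = pairwise_seq_distance(sr_library.subset(shared), model=model)
    dm_nfl = pairwise_seq_distance(nfl_library.subset(shared), model=model)
    rows = []
    for cutoff in cutoffs:
        n_sr = count_otus(dm_sr, cutoff)
        n_nfl = count_otus(dm_nfl, cutoff)
        rows.append(dict(cutoff=cutoff, sr_otus=n_sr, nfl_otus=n_nfl,
                         ratio=n_sr / n_nfl))
    return pd.DataFrame(rows, columns=["cutoff", "sr_otus", "nfl_otus",
                                       "ratio"])
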