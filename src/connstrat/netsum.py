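"""Within/between-network summaries of an NBS component.

Nodes are labelled by membership in 8 intrinsic connectivity networks
(7 cortical plus subcortical); each component edge is tallied once into
the unordered network pair it joins. The percentage matrix sums to 100
over the upper triangle including the diagonal; the strength matrix
sums to the component strength.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nbs import NBSComponent
from .synthio import CANONICAL_NETWORKS

__all__ = ["within_between_summary"]


def within_between_summary(component: NBSComponent, partition: np.ndarray,
                           labels_order: tuple | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally component edges by the network pair they connect.

    ``partition`` maps node id -> network label for every node in the
    component. Returns ``(percent, strength)`` as symmetric DataFrames
    over ``labels_order`` (default: the canonical 8-network ordering,
    extended by any extra labels present).
    """
    partition = np.asarray(partition, dtype=object)
    present = set(partition.tolist())
    if labels_order is None:
        labels_order = tuple(
            [nm for nm in CANONICAL_NETWORKS if nm in present]
            + sorted(present - set(CANONICAL_NETWORKS)))
    idx = {nm: i for i, nm in enumerate(labels_order)}
    k = len(labels_order)
    counts = np.zeros((k, k))
    strength = np.zeros((k, k))
    if component.edge_t is None:
        edge_t = np.ones(len(component.edges))
    else:
        edge_t = np.asarray(component.edge_t, dtype=float)
    for (a, b), t in zip(component.edges, edge_t):
        for node in (a, b):
            if node >= partition.size or partition[node] is None:
                raise ValueError(f"node {node} has no network label")
        ia, ib = idx[partition[a]], idx[partition[b]]
        lo, hi = min(ia, ib), max(ia, ib)
        counts[lo, hi] += 1
        strength[lo, hi] += t
    total = counts.sum()
    percent = 100.0 * counts / total if total else counts
    # mirror for symmetric presentation; totals count the triangle once
    percent = percent + np.triu(percent, 1).T
    strength = strength + np.triu(strength, 1).T
    return (pd.DataFrame(percent, index=labels_order, columns=labels_order),
            pd.DataFrame(strength, index=labels_order, columns=labels_order))
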