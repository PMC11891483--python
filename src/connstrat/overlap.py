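"""Overlap statistics between two NBS components.

The Sorensen-Dice coefficient 2k / (|A| + |B|) quantifies node- or
edge-level agreement; significance of edge overlap is assessed against
a hypergeometric null over the universe of possible connections.
"""

from __future__ import annotations

from scipy.stats import hypergeom

__all__ = ["dice", "dice_sets", "edge_overlap_test", "component_overlap"]


def dice(size_a: int, size_b: int, overlap: int) -> float:
    """Sorensen-Dice coefficient 2k / (|A| + |B|); 0 for two empty sets."""
    if min(size_a, size_b, overlap) < 0:
        raise ValueError("sizes and overlap must be non-negative")
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed either set size")
    if size_a + size_b == 0:
        return 0.0
    return 2.0 * overlap / (size_a + size_b)


def dice_sets(a, b) -> float:
    a, b = set(a), set(b)
    return dice(len(a), len(b), len(a & b))


def edge_overlap_test(n_possible: int, n_edges_a: int, n_edges_b: int,
                      n_overlap: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= n_overlap).

    X counts shared edges when n_edges_a edges are drawn from a
    universe of n_possible containing n_edges_b marked edges; the test
    is symmetric in the two sets.
    """
    if max(n_edges_a, n_edges_b) > n_possible:
        raise ValueError("edge counts cannot exceed the universe size")
    if n_overlap > min(n_edges_a, n_edges_b):
        raise ValueError("overlap cannot exceed either edge count")
    if n_overlap < 0:
        raise ValueError("overlap must be non-negative")
    return float(hypergeom.sf(n_overlap - 1, n_possible, n_edges_b, n_edges_a))


def component_overlap(comp_a, comp_b, n_possible_edges: int) -> dict:
    """Node Dice, edge Dice and hypergeometric edge-overlap p for two
    NBS components."""
    nodes_a, nodes_b = set(comp_a.nodes.tolist()), set(comp_b.nodes.tolist())
    edges_a, edges_b = set(map(tuple, comp_a.edges)), set(map(tuple, comp_b.edges))
    shared_edges = len(edges_a & edges_b)
    return {
        "node_dice": dice_sets(nodes_a, nodes_b),
        "edge_dice": dice_sets(edges_a, edges_b),
        "n_shared_nodes": len(nodes_a & nodes_b),
        "n_shared_edges": shared_edges,
        "edge_overlap_p": edge_overlap_test(
            n_possible_edges, len(edges_a), len(edges_b), shared_edges),
    }
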