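"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use dendropy (not the package's own tree
machinery) and naive set/loop arithmetic, so they share no code path with
the implementations they check.
"""

import dendropy
import numpy as np
import pytest

from rhizoecol.core_io import AsvTable, read_tree


@pytest.fixture
def three_tip_tree():
    """The worked 3-tip tree ((A:1,B:1):1,C:2);"""
    return read_tree(newick="((A:1,B:1):1,C:2);")


@pytest.fixture
def small_table():
    counts = np.array([[5, 3, 0],
                       [0, 2, 4],
                       [1, 1, 1]])
    return AsvTable(["s1", "s2", "s3"], ["A", "B", "C"], counts)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def dendropy_branches(newick: str):
    """(branch_length, frozenset_of_tips_below) for every non-root edge."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = frozenset(l.taxon.label.replace(" ", "_")
                         for l in node.leaf_iter())
        out.append((node.edge.length or 0.0, tips))
    return out


def oracle_unweighted_unifrac(newick, present_a, present_b):
    a, b = set(present_a), set(present_b)
    unique = shared_or = 0.0
    for length, tips in dendropy_branches(newick):
        in_a = bool(tips & a)
        in_b = bool(tips & b)
        if in_a or in_b:
            shared_or += length
            if in_a != in_b:
                unique += length
    return unique / shared_or if shared_or > 0 else 0.0


def oracle_weighted_unifrac(newick, abund_a, abund_b, normalized):
    ta = sum(abund_a.values())
    tb = sum(abund_b.values())
    num = denom = 0.0
    for length, tips in dendropy_branches(newick):
        pa = sum(abund_a.get(t, 0.0) for t in tips) / ta
        pb = sum(abund_b.get(t, 0.0) for t in tips) / tb
        num += length * abs(pa - pb)
        denom += length * (pa + pb)
    if normalized:
        return num / denom if denom > 0 else 0.0
    return num


def oracle_cophenetic(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label.replace(" ", "_"): t for t in tree.taxon_namespace}
    return {(x, y): pdm.distance(taxa[x], taxa[y])
            for x in taxa for y in taxa}


def oracle_beta_mntd(newick, abund_a, abund_b):
    """Nested-loop abundance-weighted mean nearest-taxon distance."""
    coph = oracle_cophenetic(newick)
    ta = sum(abund_a.values())
    tb = sum(abund_b.values())

    def directed(src, src_total, dst):
        acc = 0.0
        for i, w in src.items():
            acc += (w / src_total) * min(coph[(i, j)] for j in dst)
        return acc

    return 0.5 * (directed(abund_a, ta, abund_b)
                  + directed(abund_b, tb, abund_a))


def oracle_shortest_paths(edges, nodes):
    """Floyd-Warshall all-pairs shortest paths on an unweighted graph."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in edges:
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    return dist
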