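"""Alpha and beta diversity metrics over a phylogeny of OTUs.

All phylogenetic metrics are computed by a single post-order traversal of a
rooted ``skbio.TreeNode`` whose tips are OTU ids. Branch lengths default to
0 when absent, and the edge above the root participates like any other
edge (its length is 0 in practice). OTUs present in a table but absent
from the tree are a hard error: silently dropping them would corrupt
comparisons between OTU picking runs.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "observed_otus",
    "faith_pd",
    "unweighted_unifrac",
    "weighted_unifrac",
    "beta_diversity_matrix",
]

_METRICS = ("unweighted_unifrac", "weighted_unifrac",
            "weighted_unifrac_normalized")


def observed_otus(counts) -> int:
    """Number of OTUs with count > 0 (the 'observed species' metric)."""
    arr = np.asarray(counts)
    return int((arr > 0).sum())


def _tip_set(tree: TreeNode) -> set[str]:
    return {t.name for t in tree.tips()}


def _check_known(tree, labels):
    unknown = set(labels) - _tip_set(tree)
    if unknown:
        raise ValueError(
            f"OTU ids not present as tree tips: {sorted(unknown)[:5]}"
            f"{'...' if len(unknown) > 5 else ''}")


def _edge_length(node) -> float:
    return node.length if node.length is not None else 0.0


def faith_pd(tree: TreeNode, present_otus) -> float:
    """Faith's Phylogenetic Diversity.

    Sum of the branch lengths of every edge on a path from the root to a
    present tip, each edge counted once. Empty input gives 0.
    """
    present = set(present_otus)
    if not present:
        return 0.0
    _check_known(tree, present)
    has_present: dict[int, bool] = {}
    total = 0.0
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            flag = node.name in present
        else:
            flag = any(has_present[id(ch)] for ch in node.children)
        has_present[id(node)] = flag
        if flag:
            total += _edge_length(node)
    return total


def _pair_traversal(tree, counts_a, counts_b):
    """Yield (edge_length, a_below, b_below) for every edge, post-order."""
    below: dict[int, tuple[float, float]] = {}
    out = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            a = float(counts_a.get(node.name, 0))
            b = float(counts_b.get(node.name, 0))
        else:
            a = b = 0.0
            for ch in node.children:
                ca, cb = below[id(ch)]
                a += ca
                b += cb
        below[id(node)] = (a, b)
        out.append((_edge_length(node), a, b))
    return out


def _as_count_dict(counts) -> dict[str, float]:
    if hasattr(counts, "items"):
        return {k: float(v) for k, v in counts.items()}
    raise TypeError("sample counts must be a mapping or pandas Series")


def unweighted_unifrac(tree: TreeNode, counts_a, counts_b) -> float:
    """Unweighted UniFrac: presence/absence branch-length dissimilarity.

    (branch length unique to one sample's tip set) / (branch length
    observed in either). Two empty samples give 0 by convention.
    """
    ca = _as_count_dict(counts_a)
    cb = _as_count_dict(counts_b)
    _check_known(tree, set(ca) | set(cb))
    unique = 0.0
    observed = 0.0
    for length, a, b in _pair_traversal(tree, ca, cb):
        in_a = a > 0
        in_b = b > 0
        if in_a or in_b:
            observed += length
            if in_a != in_b:
                unique += length
    if observed == 0:
        return 0.0
    return unique / observed


def weighted_unifrac(tree: TreeNode, counts_a, counts_b,
                     normalized: bool = False) -> float:
    """Weighted UniFrac: abundance-weighted branch-length difference.

    Raw form: ``sum_e  l_e * |p_A(e) - p_B(e)|`` where ``p_X(e)`` is the
    proportion of sample X's reads descending through edge e. The
    normalized variant divides by ``sum_e l_e * (p_A(e) + p_B(e))``, the
    maximal attainable value for the pair.
    """
    ca = _as_count_dict(counts_a)
    cb = _as_count_dict(counts_b)
    _check_known(tree, set(ca) | set(cb))
    ta = sum(ca.values())
    tb = sum(cb.values())
    if ta == 0 or tb == 0:
        raise ValueError("weighted UniFrac requires both samples non-empty")
    num = 0.0
    denom = 0.0
    for length, a, b in _pair_traversal(tree, ca, cb):
        pa = a / ta
        pb = b / tb
        num += length * abs(pa - pb)
        denom += length * (pa + pb)
    if not normalized:
        return num
    return num / denom if denom > 0 else 0.0


def beta_diversity_matrix(table, tree: TreeNode,
                          metric: str) -> DistanceMatrix:
    """Pairwise sample distances for one of the UniFrac metrics.

    ``metric`` is one of ``unweighted_unifrac``, ``weighted_unifrac`` (raw)
    or ``weighted_unifrac_normalized``. Symmetric by construction with a
    zero diagonal; every table OTU must be a tree tip.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of "
                         f"{_METRICS}")
    _check_known(tree, table.otu_ids)
    samples = table.sample_ids
    n = len(samples)
    mat = np.zeros((n, n))
    cols = {s: table.sample_counts(s) for s in samples}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cols[samples[i]], cols[samples[j]]
            if metric == "unweighted_unifrac":
                d = unweighted_unifrac(tree, a, b)
            elif metric == "weighted_unifrac":
                d = weighted_unifrac(tree, a, b, normalized=False)
            else:
                d = weighted_unifrac(tree, a, b, normalized=True)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=samples)
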