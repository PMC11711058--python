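"""Independent oracles used by the test suite.

These deliberately share no code with the package's likelihood engine:
likelihoods come from a direct recursive Felsenstein pruning over an
explicitly grafted dendropy tree using scipy matrix exponentials, and the
best placement edge from a dense grid over pendant lengths.
"""

from __future__ import annotations

import dendropy
import numpy as np
from scipy.linalg import expm

from amfplace._seq import encode
from amfplace.reference import ReferenceSet

PENDANT_GRID = np.concatenate(
    [[1e-8], np.geomspace(1e-6, 2.0, 199)]
)  # 200 pendant lengths


def prune_loglik(
    tree: dendropy.Tree,
    seqs: dict[str, np.ndarray],
    model,
    _pcache: dict | None = None,
) -> float:
    """Plain pruning log-likelihood of a tree with leaf code arrays.

    Gamma mixture averaged per column; no scaling (small-fixture use only).
    ``_pcache`` memoizes matrix exponentials across repeated calls.
    """
    L = len(next(iter(seqs.values())))
    pis = model.pi
    cache = _pcache if _pcache is not None else {}

    def pmat(t: float) -> np.ndarray:
        if t not in cache:
            cache[t] = expm(model.Q * t)
        return cache[t]

    persite = []
    for rate in model.rates:

        def partial(node) -> np.ndarray:
            if node.is_leaf():
                codes = seqs[node.taxon.label]
                part = np.ones((L, 4))
                ok = codes >= 0
                part[ok] = 0.0
                part[np.flatnonzero(ok), codes[ok]] = 1.0
                return part
            res = np.ones((L, 4))
            for child in node.child_nodes():
                P = pmat(rate * (child.edge.length or 0.0))
                res = res * (partial(child) @ P.T)
            return res

        persite.append(partial(tree.seed_node) @ pis)
    lik = np.mean(np.stack(persite, axis=0), axis=0)
    return float(np.log(lik).sum())


def grafted_tree(
    ref: ReferenceSet, edge_id: int, pendant: float, query_name: str = "QUERY"
) -> dendropy.Tree:
    """Reference tree with a query leaf attached at an edge midpoint."""
    idx = ref.index

    def build(node_id: int) -> dendropy.Node:
        node = dendropy.Node()
        name = idx.leaf_name.get(node_id)
        if name is not None:
            node.label_name = name
        for ch in idx.children[node_id]:
            child = build(ch)
            length = idx.branch_length[ch]
            if ch - 1 == edge_id:
                mid = dendropy.Node()
                mid.edge.length = length / 2.0
                child.edge.length = length / 2.0
                q = dendropy.Node()
                q.label_name = query_name
                q.edge.length = pendant
                mid.add_child(child)
                mid.add_child(q)
                node.add_child(mid)
            else:
                child.edge.length = length
                node.add_child(child)
        return node

    tree = dendropy.Tree()
    tree.seed_node = build(0)
    ns = tree.taxon_namespace
    for leaf in tree.leaf_node_iter():
        leaf.taxon = ns.new_taxon(leaf.label_name)
    return tree


def grid_place(ref: ReferenceSet, query_codes: np.ndarray, model):
    """Exhaustive placement: dense pendant grid on every edge.

    Returns (best edge id, best pendant, per-edge best log-likelihood).
    """
    seqs = {name: encode(s) for name, s in ref.alignment.items()}
    seqs["QUERY"] = np.asarray(query_codes)
    best_ll = np.full(ref.n_edges, -np.inf)
    best_pend = np.zeros(ref.n_edges)
    pcache: dict = {}
    for e in range(ref.n_edges):
        for pend in PENDANT_GRID:
            tree = grafted_tree(ref, e, pend)
            ll = prune_loglik(tree, seqs, model, _pcache=pcache)
            if ll > best_ll[e]:
                best_ll[e] = ll
                best_pend[e] = pend
    best_edge = int(np.argmax(best_ll))
    return best_edge, best_pend[best_edge], best_ll


def enumerate_query_clades(tree: dendropy.Tree, query_ids: set[str]) -> list[frozenset]:
    """All maximal clades whose leaves are queries only (brute force)."""
    out = []
    for nd in tree.preorder_node_iter():
        leaves = {lf.taxon.label for lf in nd.leaf_iter()}
        if leaves <= query_ids:
            parent = nd.parent_node
            if parent is None:
                out.append(frozenset(leaves))
                continue
            up = {lf.taxon.label for lf in parent.leaf_iter()}
            if not up <= query_ids:
                out.append(frozenset(leaves))
    # maximal only: drop subsets
    maximal = [s for s in out if not any(s < t for t in out)]
    return maximal
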