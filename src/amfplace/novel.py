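"""Candidate novel clades among unknown-AMF ASVs.

Unknown ASVs (placed inside the AMF crown but outside every family crown)
are grafted onto the backbone at their best edges; maximal query-only clades
of the extended tree are the novel-clade candidates, reported with their
sister family, column-bootstrap support and bioclimatic-zone composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .placement import AlignedQuery, Placement, PlacementEngine
from .reference import OUTGROUP, ReferenceSet, UNLABELED


@dataclass
class ExtendedTree:
    """Backbone with query leaves grafted in; reference topology unchanged."""

    tree: dendropy.Tree
    query_ids: set[str]
    ref: ReferenceSet


@dataclass
class NovelCladeReport:
    clade_id: str
    members: list[str]
    sister_family: str
    size: int
    support: float | None = None
    zone_composition: dict[str, float] = field(default_factory=dict)
    structured: bool | None = None


def graft_all(
    ref: ReferenceSet, placements: dict[str, Placement]
) -> ExtendedTree:
    """Graft every placed ASV into the backbone.

    Each edge that received placements is subdivided once at its midpoint;
    the ASVs placed on it hang from that point as a query-only pectinate
    subtree (zero-length internal branches, each member keeping its own
    optimized pendant length), ordered by descending placement
    log-likelihood.  Grouping co-placed queries under one attachment keeps
    them monophyletic in the extended tree, which is what the clade scan
    consumes; the reference topology is otherwise unchanged.
    """
    idx = ref.index
    by_edge: dict[int, list[Placement]] = {}
    for pl in placements.values():
        by_edge.setdefault(pl.best_edge, []).append(pl)
    for group in by_edge.values():
        group.sort(key=lambda p: (-p.log_likelihood, p.asv_id))

    tree = dendropy.Tree()
    ns = tree.taxon_namespace

    def build(node_id: int) -> dendropy.Node:
        node = dendropy.Node()
        name = idx.leaf_name.get(node_id)
        if name is not None:
            node.taxon = ns.new_taxon(name)
        for ch in idx.children[node_id]:
            child = build(ch)
            edge_id = ch - 1
            length = idx.branch_length[ch]
            group = by_edge.get(edge_id)
            if group:
                mid = dendropy.Node()
                mid.edge.length = length / 2.0
                child.edge.length = length / 2.0
                mid.add_child(child)
                mid.add_child(_query_subtree(group, ns))
                node.add_child(mid)
            else:
                child.edge.length = length
                node.add_child(child)
        return node

    def _query_subtree(group: list[Placement], ns) -> dendropy.Node:
        leaves = []
        for pl in group:
            leaf = dendropy.Node()
            leaf.taxon = ns.new_taxon(pl.asv_id)
            leaf.edge.length = pl.pendant_length
            leaves.append(leaf)
        if len(leaves) == 1:
            return leaves[0]
        # pectinate: best-supported member highest
        cur = leaves[-1]
        for leaf in reversed(leaves[:-1]):
            joint = dendropy.Node()
            joint.edge.length = 0.0
            joint.add_child(leaf)
            joint.add_child(cur)
            cur = joint
        return cur

    root = build(0)
    tree.seed_node = root
    return ExtendedTree(
        tree=tree, query_ids=set(placements), ref=ref
    )


def find_novel_clades(
    ext: ExtendedTree,
    min_size: int = 2,
) -> list[NovelCladeReport]:
    """Maximal clades of the extended tree whose leaves are all queries.

    The sister family is read off the nearest labeled sister subtree walking
    rootward: the single family if all its reference leaves agree, else the
    majority family, with ties reported as ``amf_backbone``.  Reports are
    sorted by size descending, then clade id.
    """
    labels = ext.ref.labels
    qids = ext.query_ids

    def is_query_leaf(nd) -> bool:
        return nd.is_leaf() and nd.taxon.label in qids

    all_query: dict[int, bool] = {}
    for nd in ext.tree.postorder_node_iter():
        if nd.is_leaf():
            all_query[id(nd)] = is_query_leaf(nd)
        else:
            all_query[id(nd)] = all(
                all_query[id(c)] for c in nd.child_nodes()
            )

    maximal = []
    for nd in ext.tree.preorder_node_iter():
        if all_query[id(nd)] and (
            nd.parent_node is None or not all_query[id(nd.parent_node)]
        ):
            maximal.append(nd)

    reports = []
    for i, nd in enumerate(maximal):
        members = sorted(lf.taxon.label for lf in nd.leaf_iter())
        if len(members) < min_size:
            continue
        reports.append(
            NovelCladeReport(
                clade_id=f"clade_{i + 1}",
                members=members,
                sister_family=_sister_family(nd, labels, qids),
                size=len(members),
            )
        )
    reports.sort(key=lambda r: (-r.size, r.clade_id))
    return reports


def _sister_family(node, labels: dict[str, str], qids: set[str]) -> str:
    """First labeled sister subtree walking rootward; majority family,
    ties -> ``amf_backbone``."""
    seen = node
    cur = node.parent_node
    while cur is not None:
        ref_leaves = []
        for child in cur.child_nodes():
            if child is seen:
                continue
            ref_leaves.extend(
                lf.taxon.label
                for lf in child.leaf_iter()
                if lf.taxon.label not in qids
            )
        fams = [
            labels[name]
            for name in ref_leaves
            if labels.get(name) not in (None, UNLABELED)
        ]
        fams = [f for f in fams if f != OUTGROUP]
        if fams:
            counts = pd.Series(fams).value_counts()
            top = counts[counts == counts.iloc[0]]
            if len(top) > 1:
                return "amf_backbone"
            return top.index[0]
        if ref_leaves:
            return OUTGROUP  # nearest labeled neighbors are all outgroups
        seen, cur = cur, cur.parent_node
    return "amf_backbone"


def clade_support(
    engine: PlacementEngine,
    report: NovelCladeReport,
    aligned: dict[str, AlignedQuery],
    B: int = 100,
    seed: int = 0,
) -> float:
    """Column-bootstrap support of a candidate clade.

    Per replicate the member ASVs are re-placed on resampled columns and
    re-grafted; the replicate supports the clade when the members again form
    a maximal query-only clade with the same sister family.
    """
    if not report.members:
        raise ValueError("clade has no members")
    rng = np.random.default_rng(seed)
    L = engine.ref.length
    hits = 0
    member_set = set(report.members)
    for _ in range(B):
        cols = rng.integers(L, size=L)
        placements = {}
        for m in report.members:
            pl = engine._place_on(aligned[m].codes, cols=cols)
            pl.asv_id = m
            placements[m] = pl
        ext = graft_all(engine.ref, placements)
        for rep in find_novel_clades(ext, min_size=1):
            if set(rep.members) == member_set and rep.sister_family == report.sister_family:
                hits += 1
                break
    return hits / B


def zone_composition(
    report: NovelCladeReport,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    structured_threshold: float = 0.9,
) -> NovelCladeReport:
    """Read-count composition of a clade across bioclimatic zones.

    The clade is flagged geographically structured when at least
    ``structured_threshold`` of its reads come from a single zone.
    """
    for m in report.members:
        if m not in counts.columns:
            raise KeyError(f"clade member {m!r} absent from the count matrix")
    zones = meta.loc[counts.index, "zone"]
    member_reads = counts[report.members].sum(axis=1)
    per_zone = member_reads.groupby(zones).sum()
    total = per_zone.sum()
    if total > 0:
        comp = {z: c / total for z, c in per_zone.items() if c > 0}
    else:
        comp = {}
    report.zone_composition = {z: float(c) for z, c in comp.items()}
    report.structured = bool(comp and max(comp.values()) >= structured_threshold)
    return report
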