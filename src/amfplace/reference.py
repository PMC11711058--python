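"""Family-annotated reference backbone: loading, validation and clade maps.

A reference set is a rooted binary tree with branch lengths (expected
substitutions/site), an aligned set of reference sequences (one row per
leaf), and a leaf -> family label table.  Labels are either one of the AMF
family names, ``"outgroup"`` or ``"unlabeled"``.

Edges are numbered deterministically: edge ``e`` is the branch above the
node with preorder rank ``e + 1`` (the root, rank 0, has no edge).  A rooted
binary tree with n leaves therefore has 2n - 2 edges.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._seq import encode

OUTGROUP = "outgroup"
UNLABELED = "unlabeled"

#: The 11 major AMF (Glomeromycota) families used throughout.
AMF_FAMILIES = (
    "Acaulosporaceae",
    "Ambisporaceae",
    "Archaeosporaceae",
    "Diversisporaceae",
    "Entrophosporaceae",
    "Gigasporaceae",
    "Glomeraceae",
    "Pacisporaceae",
    "Paraglomeraceae",
    "Pervetustaceae",
    "Sacculosporaceae",
)


class TreeIndex:
    """Array view of a rooted dendropy tree in preorder.

    Node ``i`` is the i-th node in preorder; the root is node 0.  The edge
    above node ``i > 0`` has id ``i - 1``.  Subtree membership tests use the
    preorder interval of each node.
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.preorder_node_iter())
        self.tree = tree
        self.nodes = nodes
        self.n_nodes = len(nodes)
        self._rank = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.branch_length = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.leaf_name: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._rank[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.branch_length[i] = nd.edge.length or 0.0
            if nd.is_leaf():
                name = nd.taxon.label if nd.taxon is not None else nd.label
                self.leaf_name[i] = name
        self.node_of_leaf = {v: k for k, v in self.leaf_name.items()}
        # preorder interval [i, subtree_end[i]) covers the subtree of node i
        self.subtree_end = np.arange(1, self.n_nodes + 1)
        for i in range(self.n_nodes - 1, -1, -1):
            for c in self.children[i]:
                self.subtree_end[i] = max(self.subtree_end[i], self.subtree_end[c])
        self.postorder = [
            self._rank[id(nd)] for nd in tree.postorder_node_iter()
        ]

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def edge_child(self, edge_id: int) -> int:
        if not 0 <= edge_id < self.n_edges:
            raise KeyError(f"edge {edge_id} does not exist")
        return edge_id + 1

    def edge_parent(self, edge_id: int) -> int:
        return int(self.parent[self.edge_child(edge_id)])

    def is_descendant(self, node: int, ancestor: int) -> bool:
        """True if ``node`` lies in the subtree of ``ancestor`` (inclusive)."""
        return ancestor <= node < self.subtree_end[ancestor]

    def mrca(self, node_ids) -> int:
        node_ids = list(node_ids)
        if not node_ids:
            raise ValueError("mrca of empty set")
        anc = min(node_ids)
        hi = max(node_ids)
        while not self.is_descendant(hi, anc):
            anc = int(self.parent[anc])
        return anc

    def leaves_under(self, node: int) -> list[int]:
        return [
            i
            for i in range(node, int(self.subtree_end[node]))
            if i in self.leaf_name
        ]


@dataclass
class ReferenceSet:
    """Backbone tree + aligned reference sequences + family labels."""

    tree: dendropy.Tree
    alignment: dict[str, str]
    labels: dict[str, str]
    index: TreeIndex = field(repr=False, default=None)

    def __post_init__(self):
        if self.index is None:
            self.index = TreeIndex(self.tree)
        self._validate()
        self._codes = None

    def _validate(self) -> None:
        leaves = list(self.index.leaf_name.values())
        if len(set(leaves)) != len(leaves):
            dup = sorted({x for x in leaves if leaves.count(x) > 1})
            raise ValueError(f"duplicate leaf names in tree: {dup}")
        for leaf in leaves:
            if leaf not in self.alignment:
                raise ValueError(f"leaf {leaf!r} missing from alignment")
            if leaf not in self.labels:
                raise ValueError(f"leaf {leaf!r} missing from labels")
        lens = {len(s) for s in self.alignment.values()}
        if len(lens) > 1:
            raise ValueError(f"alignment rows differ in length: {sorted(lens)}")
        if np.any(self.index.branch_length < 0):
            raise ValueError("negative branch length in tree")
        if not any(v == OUTGROUP for v in self.labels.values()):
            raise ValueError("reference set needs at least one outgroup leaf")
        for i in range(self.index.n_nodes):
            k = len(self.index.children[i])
            if k not in (0, 2):
                raise ValueError(
                    f"tree is not binary: node {i} has {k} children"
                )

    @property
    def n_leaves(self) -> int:
        return len(self.index.leaf_name)

    @property
    def n_edges(self) -> int:
        return self.index.n_edges

    @property
    def length(self) -> int:
        return len(next(iter(self.alignment.values())))

    @property
    def families(self) -> list[str]:
        return sorted(
            {v for v in self.labels.values() if v not in (OUTGROUP, UNLABELED)}
        )

    def encoded_alignment(self) -> dict[str, np.ndarray]:
        if self._codes is None:
            self._codes = {k: encode(v) for k, v in self.alignment.items()}
        return self._codes

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class FamilyCladeMap:
    """Crown nodes of the AMF clade and of each family, plus monophyly flags."""

    amf_crown: int
    family_crowns: dict[str, int]
    monophyly_flags: dict[str, bool]
    index: TreeIndex = field(repr=False, default=None)


def _read_text(source) -> str:
    s = str(source)
    try:
        if isinstance(source, Path) or ("\n" not in s and Path(s).exists()):
            return Path(s).read_text()
    except OSError:
        pass
    return s


def _read_fasta(source) -> dict[str, str]:
    from Bio import SeqIO

    text = _read_text(source)
    recs = list(SeqIO.parse(_io.StringIO(text), "fasta"))
    out = {}
    for r in recs:
        if r.id in out:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        out[r.id] = str(r.seq).upper()
    return out


def _read_labels(source) -> dict[str, str]:
    text = _read_text(source)
    df = pd.read_csv(_io.StringIO(text), sep="\t")
    for col in ("leaf_id", "family"):
        if col not in df.columns:
            raise ValueError(f"label table must have a {col!r} column")
    if df["leaf_id"].duplicated().any():
        dup = df.loc[df["leaf_id"].duplicated(), "leaf_id"].tolist()
        raise ValueError(f"duplicate leaf ids in label table: {dup}")
    return dict(zip(df["leaf_id"].astype(str), df["family"].astype(str)))


def _reroot_on_outgroup(tree: dendropy.Tree, outgroups: set[str]) -> dendropy.Tree:
    """Root so that the outgroups and the rest sit on opposite sides of the root."""
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ingroup = leaf_names - outgroups
    root_children = tree.seed_node.child_nodes()
    if len(root_children) == 2:
        for ch in root_children:
            side = {lf.taxon.label for lf in ch.leaf_iter()}
            if side == outgroups or side == ingroup:
                return tree  # already rooted on the outgroup split
    # find an edge whose subtree is exactly the outgroups or exactly the ingroup
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = {lf.taxon.label for lf in nd.leaf_iter()}
        if side == outgroups or side == ingroup:
            length = nd.edge.length or 0.0
            tree.reroot_at_edge(nd.edge, length1=length / 2, length2=length / 2)
            tree.suppress_unifurcations()
            return tree
    raise ValueError(
        "cannot root tree: outgroup leaves do not form a separable group"
    )


def load_reference(tree_source, alignment_source, labels_source) -> ReferenceSet:
    """Load and validate a reference backbone.

    Parameters may be file paths or in-memory strings (newick text, FASTA
    text, TSV text with columns ``leaf_id`` and ``family``).  The tree is
    rooted on the outgroup split; edges are numbered by preorder.
    """
    labels = _read_labels(labels_source)
    alignment = _read_fasta(alignment_source)
    try:
        tree = dendropy.Tree.get(
            data=_read_text(tree_source),
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
        raise ValueError(f"duplicate leaf names in tree: {err}") from err
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for leaf in sorted(leaf_names):
        if leaf not in labels:
            raise ValueError(f"leaf {leaf!r} missing from labels")
    outgroups = {k for k in leaf_names if labels.get(k) == OUTGROUP}
    if outgroups:
        tree = _reroot_on_outgroup(tree, outgroups)
    return ReferenceSet(tree=tree, alignment=alignment, labels=labels)


def delineate_family_clades(ref: ReferenceSet) -> FamilyCladeMap:
    """MRCA crown of each family, the AMF crown, and per-family monophyly."""
    idx = ref.index
    root_children = idx.children[0]
    if len(root_children) != 2:
        raise ValueError("tree is unrooted; root on the outgroup first")
    fam_leaves: dict[str, list[int]] = {}
    for node, name in idx.leaf_name.items():
        lab = ref.labels[name]
        if lab not in (OUTGROUP, UNLABELED):
            fam_leaves.setdefault(lab, []).append(node)
    if not fam_leaves:
        raise ValueError("no family-labeled leaves in reference")
    for fam in ref.families:
        if fam not in fam_leaves:
            raise ValueError(f"family {fam!r} has zero leaves")
    crowns, flags = {}, {}
    for fam, leaves in sorted(fam_leaves.items()):
        crown = idx.mrca(leaves)
        crowns[fam] = crown
        under = set(idx.leaves_under(crown))
        flags[fam] = under == set(leaves)
    amf_leaves = [n for leaves in fam_leaves.values() for n in leaves]
    amf_crown = idx.mrca(amf_leaves)
    return FamilyCladeMap(
        amf_crown=amf_crown,
        family_crowns=crowns,
        monophyly_flags=flags,
        index=idx,
    )


OUTSIDE_AMF = "outside_amf"
AMF_BACKBONE = "amf_backbone"


def edge_membership(clades: FamilyCladeMap, edge_id: int) -> str:
    """Category of an edge: ``family:<f>``, ``amf_backbone`` or ``outside_amf``.

    An edge belongs to family f when both of its endpoints lie within the
    subtree of f's crown (the crown node included) — so a family's stem edge
    is backbone, not family.  It is backbone when both endpoints are within
    the AMF crown subtree but inside no family crown.
    """
    idx = clades.index
    child = idx.edge_child(edge_id)
    parent = idx.edge_parent(edge_id)
    for fam, crown in clades.family_crowns.items():
        if idx.is_descendant(parent, crown):
            return f"family:{fam}"
    if idx.is_descendant(parent, clades.amf_crown):
        return AMF_BACKBONE
    return OUTSIDE_AMF


def family_of_category(category: str) -> str | None:
    """Family name from an edge/assignment category, or None."""
    if category.startswith("family:"):
        return category.split(":", 1)[1]
    return None
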