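"""Synthetic study generator with planted truth.

Emulates everything the real survey consumed: a family-structured LSU
backbone (11 AMF families plus outgroups), query amplicons of three classes
(in-family, planted novel lineages sister to named families, non-AMF),
paired MiSeq-like reads, a sample x ASV count design with bioclimatic-zone
and land-use effects, and a corrupted-label reference database emulating
public-database annotation noise.

Every operation is deterministic given the config seed; each operation
draws from its own derived substream so stages can be re-run independently.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._seq import decode, encode, revcomp
from .reference import (
    AMF_FAMILIES,
    OUTGROUP,
    ReferenceSet,
    UNLABELED,
    delineate_family_clades,
)
from .substmodel import SubstModel

_STREAMS = {"backbone": 0, "queries": 1, "reads": 2, "community": 3, "labels": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class NovelCladeSpec:
    """A lineage planted on the stem of ``sister_family``.

    ``stem_depth_fraction`` locates the attachment point along the stem edge
    measured from its rootward end; ``divergence`` is the branch length from
    that point to the clade's common ancestor; members radiate from the
    ancestor with branches of ``crown_depth``.  ``zone`` optionally restricts
    member reads to one bioclimatic zone (geographic structuring).
    """

    sister_family: str
    n_members: int = 4
    stem_depth_fraction: float = 0.5
    divergence: float = 0.08
    crown_depth: float = 0.02
    zone: str | None = None


@dataclass(frozen=True)
class CommunityDesign:
    """Sampling design and count-generating process.

    Counts are negative binomial around depth x lognormal ASV abundance x
    exp(planted family/zone/land-use log-effect), then zeroed with the
    zero-inflation probability — amplicon community data are zero-heavy.
    """

    zones: tuple[str, ...] = ("boreal", "temperate", "tropical")
    land_uses: tuple[str, ...] = ("remnant", "agricultural", "post_agricultural")
    sites_per_cell: int = 2
    replicates_per_site: int = 2
    mean_depth: float = 5000.0
    nb_dispersion: float = 5.0
    abundance_sigma: float = 1.0
    zero_inflation: float = 0.3
    effects: dict[tuple[str, str, str], float] | None = None

    def effect(self, family: str | None, zone: str, land_use: str) -> float:
        if self.effects is None or family is None:
            return 0.0
        return self.effects.get((family, zone, land_use), 0.0)


def default_effects(
    zones=("boreal", "temperate", "tropical"),
    disturbed=("agricultural", "post_agricultural"),
) -> dict[tuple[str, str, str], float]:
    """Planted land-use effects: Entrophosporaceae up and Glomeraceae down
    in disturbed (agricultural + post-agricultural) sites, in every zone."""
    eff: dict[tuple[str, str, str], float] = {}
    for z in zones:
        for lu in disturbed:
            eff[("Entrophosporaceae", z, lu)] = 1.0
            eff[("Glomeraceae", z, lu)] = -1.0
    return eff


def default_novel_clades() -> tuple[NovelCladeSpec, ...]:
    return (
        NovelCladeSpec("Entrophosporaceae", zone="temperate"),
        NovelCladeSpec("Glomeraceae", zone="temperate"),
        NovelCladeSpec("Archaeosporaceae", zone="tropical"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic study."""

    n_families: int = 11
    leaves_per_family: int = 4
    n_outgroups: int = 3
    seq_length: int = 600
    families: tuple[str, ...] = AMF_FAMILIES
    # true substitution model for sequence evolution
    pi: tuple[float, ...] = (0.26, 0.24, 0.26, 0.24)
    exchangeabilities: tuple[float, ...] = (1.0, 2.5, 1.0, 1.0, 2.5, 1.0)
    gamma_shape: float = 0.5
    n_categories: int = 4
    rate_variation: bool = True
    # backbone depths (expected substitutions/site)
    min_branch_length: float = 0.005
    family_crown_depth: float = 0.03
    family_stem_length: float = 0.10
    spine_internode: float = 0.02
    root_to_amf: float = 0.05
    outgroup_stem: float = 0.25
    outgroup_crown_depth: float = 0.05
    # queries
    in_family_queries_per_family: int = 3
    in_family_divergence: float = 0.01
    n_non_amf_queries: int = 4
    non_amf_divergence: float = 0.02
    novel_clades: tuple[NovelCladeSpec, ...] = field(
        default_factory=default_novel_clades
    )
    # read simulation
    read_length: int = 300
    min_overlap: int = 20
    read_error_rate: float = 0.001
    reads_per_presence: int = 2
    # community
    community: CommunityDesign = field(default_factory=CommunityDesign)
    # reference label corruption
    unlabeled_fraction: float = 0.35
    mislabeled_fraction: float = 0.06
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_families:
            raise ValueError("need at least one family")
        if self.leaves_per_family < 1 or self.n_outgroups < 1:
            raise ValueError("counts must be >= 1")
        for frac in (
            self.unlabeled_fraction,
            self.mislabeled_fraction,
            self.community.zero_inflation,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.unlabeled_fraction + self.mislabeled_fraction > 1.0:
            raise ValueError("unlabeled + mislabeled fractions exceed 1")
        if self.community.mean_depth <= 0 or self.community.nb_dispersion <= 0:
            raise ValueError("depth and dispersion must be positive")
        for nc in self.novel_clades:
            if not 0.0 <= nc.stem_depth_fraction <= 1.0:
                raise ValueError("stem_depth_fraction outside [0, 1]")
            if nc.n_members < 1:
                raise ValueError("novel clade needs >= 1 member")
        names = self.family_names()
        for nc in self.novel_clades:
            if nc.sister_family not in names:
                raise ValueError(
                    f"novel clade sister {nc.sister_family!r} not a simulated family"
                )

    def family_names(self) -> list[str]:
        base = list(self.families[: self.n_families])
        while len(base) < self.n_families:
            base.append(f"Family{len(base) + 1}")
        return base

    def model(self) -> SubstModel:
        return SubstModel(
            pi=np.asarray(self.pi),
            exchangeabilities=np.asarray(self.exchangeabilities),
            gamma_shape=self.gamma_shape,
            n_categories=self.n_categories,
            rate_variation=self.rate_variation,
        )


@dataclass
class NovelCladeTruth:
    sister_family: str
    members: list[str]
    zone: str | None


@dataclass
class TruthSet:
    """Planted truth: true class per query, planted clades, planted effects,
    plus the simulator's internal state (ancestral sequences, site rates)."""

    query_class: dict[str, str] = field(default_factory=dict)
    novel_clades: dict[int, NovelCladeTruth] = field(default_factory=dict)
    effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    expected_depth: dict[str, float] = field(default_factory=dict)
    original_labels: dict[str, str] = field(default_factory=dict)
    node_sequences: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    site_categories: np.ndarray | None = field(default=None, repr=False)
    model: SubstModel | None = field(default=None, repr=False)

    def true_category(self, qid: str) -> str:
        """Expected pipeline category: family:<f>, unknown_amf or non_amf."""
        cls = self.query_class[qid]
        if cls.startswith("novel:"):
            return "unknown_amf"
        return cls


# --------------------------------------------------------------------------
# backbone


def _yule_times(k: int, rng: np.random.Generator):
    """Split times of a pure-birth tree grown to k tips (rate 1/lineage)."""
    times, t, n = [], 0.0, 1
    while n < k:
        t += rng.exponential(1.0 / n)
        times.append(t)
        n += 1
    t_end = t + rng.exponential(1.0 / k)
    return times, t_end


def _yule_subtree(
    k: int, depth: float, rng: np.random.Generator, min_branch: float = 0.0
):
    """Ultrametric pure-birth subtree with ``k`` leaves and root-to-tip
    height ``depth``; returns (root dendropy Node, list of leaf Nodes).

    Branches are clipped from below at ``min_branch``: curated reference
    databases are dereplicated, so backbones do not carry near-zero branches
    (which would make reference sequences bit-identical).
    """
    root = dendropy.Node()
    if k == 1:
        return root, [root]
    times, t_end = _yule_times(k, rng)
    scale = depth / t_end if t_end > 0 else 0.0
    active = [(root, 0.0)]  # (node, start time)
    for t in times:
        i = int(rng.integers(len(active)))
        node, start = active.pop(i)
        node.edge.length = (node.edge.length or 0.0)  # keep stem as set by caller
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        # branch from this split down to children starts at t
        if node is not root:
            node.edge.length = max((t - start) * scale, min_branch)
        else:
            root_split = t  # root splits at time t; caller sets root edge
            node.edge.length = (node.edge.length or 0.0) + root_split * scale
        active.append((left, t))
        active.append((right, t))
    leaves = []
    for node, start in active:
        node.edge.length = max((t_end - start) * scale, min_branch)
        leaves.append(node)
    return root, leaves


def _evolve(
    parent: np.ndarray,
    t: float,
    site_cats: np.ndarray,
    model: SubstModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a code array along a branch of length t with per-site rates."""
    child = parent.copy()
    if t <= 0:
        return child
    for c, rate in enumerate(model.rates):
        sel = np.flatnonzero(site_cats == c)
        if sel.size == 0:
            continue
        P = model.transition_matrix(rate * t)
        cum = np.cumsum(P, axis=1)
        u = rng.random(sel.size)
        child[sel] = (u[:, None] > cum[parent[sel]]).sum(axis=1)
    return child


def _bridge_state(
    upper: np.ndarray,
    lower: np.ndarray,
    t_up: float,
    t_down: float,
    site_cats: np.ndarray,
    model: SubstModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the sequence at an interior point of a realized branch,
    conditioned on both endpoint states (endpoint-conditioned bridge).

    P(x | up, down) is proportional to P(t_up)[up, x] * P(t_down)[x, down]
    per site.  This keeps planted attachment points on the lineage that the
    backbone actually realized, so tree distances match the intent.
    """
    out = np.empty_like(upper)
    for c, rate in enumerate(model.rates):
        sel = np.flatnonzero(site_cats == c)
        if sel.size == 0:
            continue
        P1 = model.transition_matrix(rate * t_up)
        P2 = model.transition_matrix(rate * t_down)
        w = P1[upper[sel], :] * P2[:, lower[sel]].T  # (n_sites, 4)
        w = w / w.sum(axis=1, keepdims=True)
        u = rng.random(sel.size)
        out[sel] = (u[:, None] > np.cumsum(w, axis=1)).sum(axis=1)
    return out


def simulate_backbone(cfg: SimConfig) -> tuple[ReferenceSet, TruthSet]:
    """Simulate the family-annotated backbone.

    Topology: outgroups and the AMF crown split at the root; family crowns
    (pure-birth, ultrametric) hang off a pectinate spine by stem edges that
    are long relative to crown depths, so within-family divergence is well
    below between-family divergence.  Sequences evolve root-to-tip under the
    configured GTR+Gamma model.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "backbone")
    families = cfg.family_names()

    tree = dendropy.Tree()
    root = tree.seed_node
    og_root, og_leaves = _yule_subtree(
        cfg.n_outgroups, cfg.outgroup_crown_depth, rng, cfg.min_branch_length
    )
    og_root.edge.length = (og_root.edge.length or 0.0) + cfg.outgroup_stem
    root.add_child(og_root)

    fam_leaf_nodes: dict[str, list] = {}
    fam_subtrees = []
    for fam in families:
        sub, leaves = _yule_subtree(
            cfg.leaves_per_family, cfg.family_crown_depth, rng, cfg.min_branch_length
        )
        sub.edge.length = (sub.edge.length or 0.0) + cfg.family_stem_length
        fam_subtrees.append(sub)
        fam_leaf_nodes[fam] = leaves

    if len(fam_subtrees) == 1:
        only = fam_subtrees[0]
        only.edge.length += cfg.root_to_amf
        root.add_child(only)
    else:
        spine = dendropy.Node()
        spine.edge.length = cfg.root_to_amf
        root.add_child(spine)
        cur = spine
        for sub in fam_subtrees[:-2]:
            nxt = dendropy.Node()
            nxt.edge.length = cfg.spine_internode
            cur.add_child(sub)
            cur.add_child(nxt)
            cur = nxt
        cur.add_child(fam_subtrees[-2])
        cur.add_child(fam_subtrees[-1])

    labels: dict[str, str] = {}
    ns = tree.taxon_namespace
    for j, leaf in enumerate(og_leaves):
        name = f"Outgroup_{j + 1}"
        leaf.taxon = ns.new_taxon(name)
        labels[name] = OUTGROUP
    for fam in families:
        for j, leaf in enumerate(fam_leaf_nodes[fam]):
            name = f"{fam}_{j + 1}"
            leaf.taxon = ns.new_taxon(name)
            labels[name] = fam

    model = cfg.model()
    site_cats = (
        rng.integers(model.rates.size, size=cfg.seq_length)
        if cfg.rate_variation
        else np.zeros(cfg.seq_length, dtype=int)
    )

    # evolve sequences in preorder over a provisional index
    from .reference import TreeIndex

    idx = TreeIndex(tree)
    node_seqs: dict[int, np.ndarray] = {}
    root_seq = rng.choice(4, size=cfg.seq_length, p=model.pi).astype(np.int8)
    node_seqs[0] = root_seq
    for i in range(1, idx.n_nodes):
        parent_seq = node_seqs[int(idx.parent[i])]
        node_seqs[i] = _evolve(parent_seq, idx.branch_length[i], site_cats, model, rng)

    alignment = {name: decode(node_seqs[n]) for n, name in idx.leaf_name.items()}
    ref = ReferenceSet(tree=tree, alignment=alignment, labels=labels, index=idx)
    planted = (
        cfg.community.effects
        if cfg.community.effects is not None
        else default_effects(cfg.community.zones)
    )
    truth = TruthSet(
        node_sequences=node_seqs,
        site_categories=site_cats,
        model=model,
        effects=dict(planted),
    )
    return ref, truth


# --------------------------------------------------------------------------
# queries


def simulate_queries(
    ref: ReferenceSet, cfg: SimConfig, truth: TruthSet
) -> tuple[dict[str, str], TruthSet]:
    """Simulate query amplicons of three classes and record their truth.

    In-family queries diverge from donor points spread over a family's leaf
    pendant edges; novel-clade members radiate from a planted lineage
    attached to the sister family's stem edge; non-AMF queries diverge from
    outgroup leaves.
    """
    rng = _rng(cfg.seed, "queries")
    idx = ref.index
    model, site_cats = truth.model, truth.site_categories
    clades = delineate_family_clades(ref)
    queries: dict[str, str] = {}

    for fam in cfg.family_names():
        crown = clades.family_crowns[fam]
        leaf_nodes = idx.leaves_under(crown)
        order = rng.permutation(len(leaf_nodes))
        for i in range(cfg.in_family_queries_per_family):
            donor = leaf_nodes[order[i % len(leaf_nodes)]]
            # outer half of the pendant edge: each query is a shallow
            # relative of one particular reference taxon
            frac = rng.uniform(0.5, 1.0)
            blen = idx.branch_length[donor]
            point = _bridge_state(
                truth.node_sequences[int(idx.parent[donor])],
                truth.node_sequences[donor],
                frac * blen,
                (1.0 - frac) * blen,
                site_cats,
                model,
                rng,
            )
            seq = _evolve(point, cfg.in_family_divergence, site_cats, model, rng)
            qid = f"Q_{fam}_{i + 1}"
            queries[qid] = decode(seq)
            truth.query_class[qid] = f"family:{fam}"

    for k, spec in enumerate(cfg.novel_clades):
        crown = clades.family_crowns[spec.sister_family]
        stem_len = idx.branch_length[crown]
        parent = int(idx.parent[crown])
        if parent < 0:
            raise ValueError(
                f"family {spec.sister_family!r} has no stem edge to attach to"
            )
        attach = _bridge_state(
            truth.node_sequences[parent],
            truth.node_sequences[crown],
            spec.stem_depth_fraction * stem_len,
            (1.0 - spec.stem_depth_fraction) * stem_len,
            site_cats,
            model,
            rng,
        )
        ancestor = _evolve(attach, spec.divergence, site_cats, model, rng)
        members = []
        for j in range(spec.n_members):
            seq = _evolve(ancestor, spec.crown_depth, site_cats, model, rng)
            qid = f"NC{k + 1}_{j + 1}"
            queries[qid] = decode(seq)
            truth.query_class[qid] = f"novel:{k + 1}"
            members.append(qid)
        truth.novel_clades[k + 1] = NovelCladeTruth(
            sister_family=spec.sister_family, members=members, zone=spec.zone
        )

    og_leaves = sorted(
        n for n, name in idx.leaf_name.items() if ref.labels[name] == OUTGROUP
    )
    for i in range(cfg.n_non_amf_queries):
        donor = og_leaves[i % len(og_leaves)]
        seq = _evolve(
            truth.node_sequences[donor], cfg.non_amf_divergence, site_cats, model, rng
        )
        qid = f"QOG_{i + 1}"
        queries[qid] = decode(seq)
        truth.query_class[qid] = "non_amf"

    return queries, truth


# --------------------------------------------------------------------------
# reads


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else int(round(-10.0 * np.log10(error_rate)))
    return chr(33 + int(np.clip(q, 2, 40)))


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    codes = encode(seq).copy()
    hits = np.flatnonzero(rng.random(codes.size) < rate)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        codes[hits] = (codes[hits] + shift) % 4
    return decode(codes)


def simulate_reads(
    queries: dict[str, str],
    cfg: SimConfig,
    counts: pd.DataFrame | None = None,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Paired reads: R1 is the first ``read_length`` bases, R2 the reverse
    complement of the last ``read_length`` bases, with iid per-base errors
    and quality strings consistent with the error rate.

    With a count matrix, ``reads_per_presence`` pairs are emitted for every
    nonzero sample x ASV cell (read ids carry the sample); otherwise one
    batch per query under a single pseudo-sample.
    """
    rng = _rng(cfg.seed, "reads")
    rl, mo = cfg.read_length, cfg.min_overlap
    for qid, seq in queries.items():
        if len(seq) < rl:
            raise ValueError(f"amplicon {qid} shorter than the read length")
        if 2 * rl - len(seq) < mo:
            raise ValueError(
                f"amplicon {qid} of length {len(seq)} leaves overlap "
                f"{2 * rl - len(seq)} < min_overlap {mo}"
            )
    qual = _phred_char(cfg.read_error_rate)
    r1, r2 = [], []

    def emit(sample: str, qid: str, copy: int) -> None:
        seq = queries[qid]
        rid = f"{sample}|{qid}|{copy}"
        fwd = _add_errors(seq[:rl], cfg.read_error_rate, rng)
        rev = _add_errors(revcomp(seq[-rl:]), cfg.read_error_rate, rng)
        r1.append((rid, fwd, qual * rl))
        r2.append((rid, rev, qual * rl))

    if counts is None:
        for qid in queries:
            for c in range(cfg.reads_per_presence):
                emit("S0", qid, c + 1)
    else:
        for sample in counts.index:
            row = counts.loc[sample]
            for qid in counts.columns:
                if qid in queries and row[qid] > 0:
                    for c in range(cfg.reads_per_presence):
                        emit(str(sample), qid, c + 1)
    return r1, r2


def write_fastq(records, path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# --------------------------------------------------------------------------
# community


def simulate_community(
    truth: TruthSet, cfg: SimConfig, queries: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x ASV counts plus sample metadata (zone, land use, site, rep).

    Counts are NB(mean = depth * abundance * exp(effect)) with lognormal
    per-ASV abundances (drawn once, shared across samples) and iid
    zero-inflation.  Zone-restricted novel clades receive zero mean outside
    their zone.
    """
    des = cfg.community
    if not des.zones or not des.land_uses or des.sites_per_cell < 1:
        raise ValueError("empty community design")
    rng = _rng(cfg.seed, "community")
    asvs = list(queries)
    abundance = rng.lognormal(mean=0.0, sigma=des.abundance_sigma, size=len(asvs))
    abundance = abundance / abundance.sum()
    effects = truth.effects

    fam_of = {}
    zone_of = {}
    for qid in asvs:
        cls = truth.query_class.get(qid, "non_amf")
        if cls.startswith("family:"):
            fam_of[qid] = cls.split(":", 1)[1]
        elif cls.startswith("novel:"):
            k = int(cls.split(":", 1)[1])
            zone_of[qid] = truth.novel_clades[k].zone

    rows, meta = [], []
    theta = des.nb_dispersion
    for zone in des.zones:
        for lu in des.land_uses:
            for s in range(1, des.sites_per_cell + 1):
                site = f"{zone}.{lu}.{s}"
                for r in range(1, des.replicates_per_site + 1):
                    sample = f"{site}.r{r}"
                    mean = des.mean_depth * abundance.copy()
                    for j, qid in enumerate(asvs):
                        eff = effects.get((fam_of.get(qid), zone, lu), 0.0)
                        if eff:
                            mean[j] *= np.exp(eff)
                        restricted = zone_of.get(qid)
                        if restricted is not None and restricted != zone:
                            mean[j] = 0.0
                    counts = np.zeros(len(asvs), dtype=np.int64)
                    pos = mean > 0
                    if pos.any():
                        p = theta / (theta + mean[pos])
                        counts[pos] = rng.negative_binomial(theta, p)
                    if des.zero_inflation > 0:
                        counts[rng.random(len(asvs)) < des.zero_inflation] = 0
                    rows.append(counts)
                    meta.append((sample, zone, lu, site, r))
                    truth.expected_depth[sample] = des.mean_depth
    counts_df = pd.DataFrame(
        np.vstack(rows), index=[m[0] for m in meta], columns=asvs
    )
    counts_df.index.name = "sample_id"
    meta_df = pd.DataFrame(
        meta, columns=["sample_id", "zone", "land_use", "site", "replicate"]
    ).set_index("sample_id")
    return counts_df, meta_df


# --------------------------------------------------------------------------
# label corruption


def corrupt_labels(
    ref: ReferenceSet,
    unlabeled_fraction: float,
    mislabeled_fraction: float,
    seed: int,
) -> tuple[dict[str, str], dict[str, str]]:
    """Corrupt AMF reference labels: independently per leaf, replace with
    ``unlabeled`` with probability u, or with a different uniformly chosen
    family with probability m.  Returns (corrupted labels, original labels).
    """
    if unlabeled_fraction + mislabeled_fraction > 1.0:
        raise ValueError("u + m must be <= 1")
    rng = _rng(seed, "labels")
    families = ref.families
    original = dict(ref.labels)
    corrupted = dict(ref.labels)
    for leaf in sorted(ref.labels):
        lab = ref.labels[leaf]
        if lab in (OUTGROUP, UNLABELED):
            continue
        x = rng.uniform()
        if x < unlabeled_fraction:
            corrupted[leaf] = UNLABELED
        elif x < unlabeled_fraction + mislabeled_fraction:
            others = [f for f in families if f != lab]
            if others:
                corrupted[leaf] = others[int(rng.integers(len(others)))]
    return corrupted, original


# --------------------------------------------------------------------------
# file output


def write_outputs(
    outdir,
    ref: ReferenceSet,
    queries: dict[str, str],
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    truth: TruthSet,
    corrupted_labels: dict[str, str] | None = None,
) -> None:
    """Write the simulated study as plain-text files (newick, FASTA, TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "backbone.nwk").write_text(ref.newick() + "\n")
    with open(outdir / "reference.fasta", "w") as fh:
        for name, seq in ref.alignment.items():
            fh.write(f">{name}\n{seq}\n")
    pd.DataFrame(
        {"leaf_id": list(ref.labels), "family": list(ref.labels.values())}
    ).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    if corrupted_labels is not None:
        pd.DataFrame(
            {
                "leaf_id": list(corrupted_labels),
                "family": list(corrupted_labels.values()),
            }
        ).to_csv(outdir / "labels_corrupted.tsv", sep="\t", index=False)
    with open(outdir / "queries.fasta", "w") as fh:
        for qid, seq in queries.items():
            fh.write(f">{qid}\n{seq}\n")
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    meta.to_csv(outdir / "metadata.tsv", sep="\t")
    pd.DataFrame(
        {
            "query_id": list(truth.query_class),
            "true_class": list(truth.query_class.values()),
        }
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
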