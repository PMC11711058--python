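"""ASV classification: tree-placement categories, top-hit identity
assignment against a (possibly mislabeled) reference database, and the
concordance/misassignment comparison between the two methods.

Categories are ``non_amf``, ``unknown_amf`` (inside the AMF crown but
outside every family crown, or hitting an unlabeled reference) and
``family:<name>``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import kmer_set, ungap
from .placement import Placement, make_aligner
from .reference import (
    AMF_BACKBONE,
    FamilyCladeMap,
    OUTGROUP,
    OUTSIDE_AMF,
    UNLABELED,
    edge_membership,
    family_of_category,
)

NON_AMF = "non_amf"
UNKNOWN_AMF = "unknown_amf"


@dataclass
class Assignment:
    asv_id: str
    method: str  # "tree" | "tophit"
    category: str  # non_amf | unknown_amf | family:<f>
    evidence: dict

    @property
    def family(self) -> str | None:
        return family_of_category(self.category)

    @property
    def is_amf(self) -> bool:
        return self.category != NON_AMF


def classify_tree(
    placement: Placement,
    clades: FamilyCladeMap,
    min_support: float = 0.0,
) -> Assignment:
    """Category from the best edge's membership; optionally demote family
    calls whose bootstrap category support is below ``min_support``."""
    cat = edge_membership(clades, placement.best_edge)
    if cat == OUTSIDE_AMF:
        category = NON_AMF
    elif cat == AMF_BACKBONE:
        category = UNKNOWN_AMF
    else:
        category = cat
        if (
            min_support > 0
            and placement.category_support is not None
            and placement.category_support < min_support
        ):
            category = UNKNOWN_AMF
    return Assignment(
        asv_id=placement.asv_id,
        method="tree",
        category=category,
        evidence={
            "best_edge": placement.best_edge,
            "pendant_length": placement.pendant_length,
            "log_likelihood": placement.log_likelihood,
            "category_support": placement.category_support,
        },
    )


def _alignment_identity(aln) -> float:
    """Percent identity over aligned columns, excluding query end overhang.

    Columns between the first and last query-aligned column count (internal
    gaps in either sequence included); matches are exact base agreements.
    """
    target, query = aln.target, aln.query
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return 0.0
    matches = 0
    columns = 0
    for bi, ((ts, te), (qs, qe)) in enumerate(zip(tblocks, qblocks)):
        for off in range(te - ts):
            columns += 1
            if target[ts + off] == query[qs + off]:
                matches += 1
        if bi + 1 < len(tblocks):
            columns += (tblocks[bi + 1][0] - te) + (qblocks[bi + 1][0] - qe)
    return 100.0 * matches / columns if columns else 0.0


def tophit_assign(
    asv_id: str,
    sequence: str,
    database: dict[str, str],
    labels: dict[str, str],
    identity_threshold: float = 98.0,
    n_candidates: int | None = 12,
) -> Assignment:
    """Nearest-reference classification with a percent-identity floor.

    The best hit maximizes the semi-global alignment score (ties broken by
    higher identity, then lexicographically smallest reference id).  Hits
    below the identity threshold (strictly lower) are non-AMF; otherwise the
    hit's label decides: a family name assigns the family, ``unlabeled``
    yields unknown-AMF, ``outgroup`` yields non-AMF.

    ``n_candidates`` restricts exact scoring to the references sharing the
    most 8-mers with the query (seed-and-extend shape); ``None`` scores the
    whole database.
    """
    if not database:
        raise ValueError("top-hit database is empty")
    sequence = ungap(sequence).upper()
    names = sorted(database)
    if n_candidates is not None and n_candidates < len(names):
        qk = kmer_set(sequence, 8)
        shared = [(-len(qk & kmer_set(database[n], 8)), n) for n in names]
        shared.sort()
        names = [n for _, n in shared[:n_candidates]]
    aligner = make_aligner()
    best = None  # (-score, -identity, name)
    for name in names:
        aln = aligner.align(ungap(database[name]).upper(), sequence)[0]
        ident = _alignment_identity(aln)
        key = (-aln.score, -ident, name)
        if best is None or key < best:
            best = key
    score, identity, hit = -best[0], -best[1], best[2]
    label = labels[hit]
    if identity < identity_threshold:
        category = NON_AMF
    elif label == UNLABELED:
        category = UNKNOWN_AMF
    elif label == OUTGROUP:
        category = NON_AMF
    else:
        category = f"family:{label}"
    return Assignment(
        asv_id=asv_id,
        method="tophit",
        category=category,
        evidence={"best_hit": hit, "percent_identity": identity, "score": score},
    )


@dataclass
class ConcordanceReport:
    """Agreement between tree placement and top-hit assignment.

    ``shared`` ASVs are AMF under both methods.  Misassignment is reported
    under both denominators: all shared ASVs, and only those where both
    methods assign a family.
    """

    n_asvs: int
    n_shared: int
    fraction_tophit_unknown: float
    fraction_tree_unknown: float
    n_both_family: int
    n_misassigned: int
    fraction_misassigned_shared: float
    fraction_misassigned_both_family: float
    confusion: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ConcordanceReport(shared={self.n_shared}, "
            f"tophit_unknown={self.fraction_tophit_unknown:.3f}, "
            f"tree_unknown={self.fraction_tree_unknown:.3f}, "
            f"misassigned(shared)={self.fraction_misassigned_shared:.3f})"
        )


def concordance(
    tree_assignments: dict[str, Assignment],
    tophit_assignments: dict[str, Assignment],
) -> ConcordanceReport:
    """Compare the two assignment methods on their common ASV set."""
    common = sorted(set(tree_assignments) & set(tophit_assignments))
    if not common:
        raise ValueError("no ASVs shared between the two assignment sets")
    tree_amf = [a for a in common if tree_assignments[a].is_amf]
    tophit_amf = [a for a in common if tophit_assignments[a].is_amf]
    shared = [a for a in common if tree_assignments[a].is_amf and tophit_assignments[a].is_amf]

    def frac_unknown(assigns, amf_ids):
        if not amf_ids:
            return float("nan")
        unk = sum(1 for a in amf_ids if assigns[a].category == UNKNOWN_AMF)
        return unk / len(amf_ids)

    both_family = [
        a
        for a in shared
        if tree_assignments[a].family is not None
        and tophit_assignments[a].family is not None
    ]
    mis = [
        a
        for a in both_family
        if tree_assignments[a].family != tophit_assignments[a].family
    ]
    fams = sorted(
        {tree_assignments[a].family for a in shared if tree_assignments[a].family}
        | {tophit_assignments[a].family for a in shared if tophit_assignments[a].family}
    )
    rows = fams + [UNKNOWN_AMF]
    confusion = pd.DataFrame(0, index=rows, columns=rows, dtype=int)
    for a in shared:
        r = tree_assignments[a].family or UNKNOWN_AMF
        c = tophit_assignments[a].family or UNKNOWN_AMF
        confusion.loc[r, c] += 1
    return ConcordanceReport(
        n_asvs=len(common),
        n_shared=len(shared),
        fraction_tophit_unknown=frac_unknown(tophit_assignments, tophit_amf),
        fraction_tree_unknown=frac_unknown(tree_assignments, tree_amf),
        n_both_family=len(both_family),
        n_misassigned=len(mis),
        fraction_misassigned_shared=len(mis) / len(shared) if shared else float("nan"),
        fraction_misassigned_both_family=(
            len(mis) / len(both_family) if both_family else float("nan")
        ),
        confusion=confusion,
    )
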