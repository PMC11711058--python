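"""Maximum-likelihood placement of query amplicons on the fixed backbone.

Each aligned query is attached, by a pendant branch, at the midpoint of every
edge in turn; the pendant length is optimized per edge and the edge with the
highest log-likelihood of the query-augmented tree wins (ties break to the
smallest edge id).  Likelihoods are Felsenstein-pruning likelihoods under
GTR(+Gamma) with per-node numeric rescaling, so 600-column alignments do not
underflow.

The engine precomputes, for every edge, the conditional likelihood of the
whole reference alignment as seen from the edge's midpoint ("attachment
partials").  Scoring a pendant length is then a single 4-state convolution
per column, and column-bootstrap replicates are plain column re-indexing.
This is the standard evolutionary-placement shortcut: the reference topology
never changes, so reference partials are computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from ._seq import MISSING, encode, kmer_set, ungap
from .reference import FamilyCladeMap, ReferenceSet, edge_membership
from .substmodel import SubstModel

PENDANT_MIN = 1e-8
PENDANT_MAX = 2.0
PENDANT_TOL = 1e-4

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class AlignedQuery:
    """A query threaded into the reference columns (missing = -1)."""

    asv_id: str
    codes: np.ndarray
    nearest_reference: str
    score: float
    low_confidence: bool = False


@dataclass
class Placement:
    """Best attachment of one query."""

    asv_id: str
    best_edge: int
    pendant_length: float
    log_likelihood: float
    edge_log_likelihoods: np.ndarray | None = field(default=None, repr=False)
    edge_support: float | None = None
    category_support: float | None = None


def make_aligner() -> Align.PairwiseAligner:
    """Semi-global scorer: match +1, mismatch -1, gap -2, free query end gaps."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -2.0
    a.end_deletion_score = 0.0  # end gaps free on the query
    return a


def align_query(ref: ReferenceSet, asv_id: str, sequence: str) -> AlignedQuery:
    """Thread a query into the reference alignment columns.

    The nearest reference by shared 8-mers (ties to the lexicographically
    smallest leaf name) anchors a semi-global pairwise alignment; query bases
    are then assigned to the columns of that reference's aligned row.  Query
    insertions relative to the reference are discarded and uncovered columns
    are missing.
    """
    sequence = ungap(sequence).upper()
    if not sequence:
        raise ValueError(f"query {asv_id!r} is empty")
    qk = kmer_set(sequence, 8)
    best_name, best_shared = None, -1
    for name in sorted(ref.alignment):
        shared = len(qk & kmer_set(ref.alignment[name], 8))
        if shared > best_shared:
            best_name, best_shared = name, shared
    ref_aln = ref.alignment[best_name]
    ref_seq = ungap(ref_aln)
    colmap = [i for i, ch in enumerate(ref_aln) if ch not in "-."]
    aligner = make_aligner()
    aln = aligner.align(ref_seq, sequence)[0]
    qcodes = encode(sequence)
    row = np.full(ref.length, MISSING, dtype=np.int8)
    tblocks, qblocks = aln.aligned
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for toff in range(te - ts):
            row[colmap[ts + toff]] = qcodes[qs + toff]
    return AlignedQuery(
        asv_id=asv_id,
        codes=row,
        nearest_reference=best_name,
        score=float(aln.score),
        low_confidence=aln.score < 0,
    )


class PlacementEngine:
    """Per-reference placement engine with cached attachment partials.

    Parameters
    ----------
    ref : the reference backbone.
    model : substitution model; default is empirical base frequencies from
        the reference alignment, equal exchangeabilities and Gamma(4, alpha=1)
        rate variation.
    """

    def __init__(self, ref: ReferenceSet, model: SubstModel | None = None):
        if model is None:
            model = SubstModel.from_alignment(
                ref.alignment.values(), gamma_shape=1.0, n_categories=4
            )
        self.ref = ref
        self.model = model
        self._build()

    # -- reference partials -------------------------------------------------

    def _build(self) -> None:
        ref, model = self.ref, self.model
        idx = ref.index
        L, K, N = ref.length, model.rates.size, idx.n_nodes
        codes = ref.encoded_alignment()

        # transition matrices for each node's parent edge, per rate category
        P = np.zeros((N, K, 4, 4))
        for i in range(1, N):
            P[i] = model.category_matrices(idx.branch_length[i])

        down = np.ones((N, K, L, 4))
        dscale = np.zeros((N, K, L))
        for i in idx.postorder:
            if not idx.children[i]:
                c = codes[idx.leaf_name[i]]
                part = np.ones((L, 4))
                ok = c >= 0
                part[ok] = 0.0
                part[np.flatnonzero(ok), c[ok]] = 1.0
                down[i] = part[None, :, :]
                continue
            for ch in idx.children[i]:
                msg = np.einsum("kxy,kly->klx", P[ch], down[ch])
                down[i] = down[i] * msg
                dscale[i] += dscale[ch]
            m = down[i].max(axis=2)
            m[m == 0] = 1.0
            down[i] /= m[:, :, None]
            dscale[i] += np.log(m)

        # outside partials: conditional likelihood of everything outside the
        # subtree of node i, given the state at node i
        out = np.ones((N, K, L, 4))
        oscale = np.zeros((N, K, L))
        for i in range(N):
            for ch in idx.children[i]:
                R = out[i].copy()
                rs = oscale[i].copy()
                for sib in idx.children[i]:
                    if sib == ch:
                        continue
                    R = R * np.einsum("kxy,kly->klx", P[sib], down[sib])
                    rs = rs + dscale[sib]
                o = np.einsum("kyx,klx->kly", P[ch], R)
                m = o.max(axis=2)
                m[m == 0] = 1.0
                out[ch] = o / m[:, :, None]
                oscale[ch] = rs + np.log(m)

        # attachment partials per edge: what the rest of the tree looks like
        # from the midpoint of each edge
        E = idx.n_edges
        A = np.zeros((E, K, L, 4))
        S = np.zeros((E, K, L))
        for e in range(E):
            v = e + 1
            u = int(idx.parent[v])
            half = model.category_matrices(idx.branch_length[v] / 2.0)
            lower = np.einsum("kxy,kly->klx", half, down[v])
            R = out[u].copy()
            rs = oscale[u].copy()
            for sib in idx.children[u]:
                if sib == v:
                    continue
                R = R * np.einsum("kxy,kly->klx", P[sib], down[sib])
                rs = rs + dscale[sib]
            upper = np.einsum("kyx,klx->kly", half, R)
            a = lower * upper
            m = a.max(axis=2)
            m[m == 0] = 1.0
            A[e] = a / m[:, :, None]
            S[e] = dscale[v] + rs + np.log(m)
        A *= model.pi  # fold the root frequencies into the partials
        self._A, self._S = A, S
        self._Asum = A.sum(axis=3)  # site likelihood of a fully missing query
        self._n_cat = K

    # -- likelihood ----------------------------------------------------------

    def _loglik(
        self,
        qcodes: np.ndarray,
        pendants: np.ndarray,
        A: np.ndarray,
        S: np.ndarray,
        Asum: np.ndarray | None = None,
    ) -> np.ndarray:
        """Log-likelihood of the augmented tree for each edge at the given
        per-edge pendant length.  ``A``/``S`` may be column-resampled views;
        ``A`` carries the stationary frequencies already folded in."""
        model = self.model
        K = self._n_cat
        E, _, L, _ = A.shape
        if Asum is None:
            Asum = A.sum(axis=3)
        t = np.multiply.outer(pendants, model.rates).reshape(-1)  # (E*K,)
        P = model.transition_matrix(t).reshape(E, K, 4, 4)
        # site[e,k,l] = sum_z A[e,k,l,z] * P[e,k,z,code_l]; missing -> Asum
        out = A @ P  # (E, K, L, 4)
        codes = np.where(qcodes >= 0, qcodes, 0)
        site = out[:, :, np.arange(L), codes]
        missing = qcodes < 0
        if missing.any():
            site[:, :, missing] = Asum[:, :, missing]
        site = np.maximum(site, 1e-300)
        M = np.log(site) + S
        mx = M.max(axis=1)
        lse = mx + np.log(np.exp(M - mx[:, None, :]).sum(axis=1))
        return lse.sum(axis=1) - L * np.log(K)

    def edge_loglik(
        self, aligned: AlignedQuery | np.ndarray, edge_id: int, pendant: float
    ) -> float:
        """Log-likelihood of the query attached at ``edge_id``'s midpoint by a
        pendant branch of the given length."""
        if pendant < 0:
            raise ValueError("pendant length must be non-negative")
        qcodes = aligned.codes if isinstance(aligned, AlignedQuery) else aligned
        e = self.ref.index.edge_child(edge_id) - 1  # validates the id
        val = self._loglik(
            np.asarray(qcodes),
            np.array([pendant]),
            self._A[e : e + 1],
            self._S[e : e + 1],
            self._Asum[e : e + 1],
        )[0]
        if not np.isfinite(val):
            raise FloatingPointError("non-finite placement likelihood")
        return float(val)

    def place(
        self,
        aligned: AlignedQuery,
        keep_edge_table: bool = False,
    ) -> Placement:
        """Optimize the pendant length on every edge and return the best
        placement (ties to the smallest edge id)."""
        return self._place_on(aligned, keep_edge_table=keep_edge_table)

    def _place_on(
        self, aligned, A=None, S=None, keep_edge_table=False, Asum=None, cols=None
    ) -> Placement:
        if A is None:
            A, S, Asum = self._A, self._S, self._Asum
        qcodes = aligned.codes if isinstance(aligned, AlignedQuery) else aligned
        active = qcodes if cols is None else qcodes[cols]
        if np.all(active < 0):
            raise ValueError(
                f"query {getattr(aligned, 'asv_id', '?')!r} is unplaceable: "
                "no aligned columns"
            )
        pend, ll = self._golden_search(qcodes, A, S, Asum, cols=cols)
        best = int(np.flatnonzero(ll == ll.max())[0])
        return Placement(
            asv_id=getattr(aligned, "asv_id", "?"),
            best_edge=best,
            pendant_length=float(pend[best]),
            log_likelihood=float(ll[best]),
            edge_log_likelihoods=ll.copy() if keep_edge_table else None,
        )

    def _prepare(self, qcodes, A, S, Asum, cols=None):
        """Group alignment columns by query base so each likelihood
        evaluation streams the attachment partials once; missing columns
        contribute a pendant-independent constant.  ``cols`` optionally
        selects (with repeats) a column resample, e.g. a bootstrap draw.
        """
        K = self._n_cat
        lnK = np.log(K)
        if cols is None:
            cols = np.arange(qcodes.size)
        qc = qcodes[cols]
        blocks = []
        for c in range(4):
            sel = cols[qc == c]
            if sel.size:
                blocks.append(
                    (c, np.ascontiguousarray(A[:, :, sel, :]), S[:, :, sel])
                )
        miss = cols[qc < 0]
        const = np.zeros(A.shape[0])
        if miss.size:
            M = np.log(np.maximum(Asum[:, :, miss], 1e-300)) + S[:, :, miss]
            mx = M.max(axis=1)
            const = (
                mx + np.log(np.exp(M - mx[:, None, :]).sum(axis=1))
            ).sum(axis=1) - miss.size * lnK
        return blocks, const

    def _loglik_prepared(self, blocks, const, pendants):
        model = self.model
        K = self._n_cat
        lnK = np.log(K)
        E = const.shape[0]
        t = np.multiply.outer(pendants, model.rates).reshape(-1)
        P = model.transition_matrix(t).reshape(E, K, 4, 4)
        tot = const.copy()
        for c, Ab, Sb in blocks:
            site = np.einsum("eklz,ekz->ekl", Ab, P[:, :, :, c])
            M = np.log(np.maximum(site, 1e-300)) + Sb
            mx = M.max(axis=1)
            tot += (
                mx + np.log(np.exp(M - mx[:, None, :]).sum(axis=1))
            ).sum(axis=1) - Ab.shape[2] * lnK
        return tot

    def _golden_search(self, qcodes, A, S, Asum=None, cols=None):
        """Golden-section maximization of the pendant on all edges at once."""
        E = A.shape[0]
        if Asum is None:
            Asum = A.sum(axis=3)
        blocks, const = self._prepare(qcodes, A, S, Asum, cols=cols)
        lo = np.full(E, PENDANT_MIN)
        hi = np.full(E, PENDANT_MAX)
        x1 = hi - _INVPHI * (hi - lo)
        x2 = lo + _INVPHI * (hi - lo)
        f1 = self._loglik_prepared(blocks, const, x1)
        f2 = self._loglik_prepared(blocks, const, x2)
        while np.max(hi - lo) > PENDANT_TOL:
            left = f1 >= f2
            lo = np.where(left, lo, x1)
            hi = np.where(left, x2, hi)
            nx1 = hi - _INVPHI * (hi - lo)
            nx2 = lo + _INVPHI * (hi - lo)
            x_eval = np.where(left, nx1, nx2)
            f_eval = self._loglik_prepared(blocks, const, x_eval)
            f2_new = np.where(left, f1, f_eval)
            f1_new = np.where(left, f_eval, f2)
            x1, x2, f1, f2 = nx1, nx2, f1_new, f2_new
        x = 0.5 * (lo + hi)
        f = self._loglik_prepared(blocks, const, x)
        return x, f

    # -- bootstrap -----------------------------------------------------------

    def bootstrap_support(
        self,
        aligned: AlignedQuery,
        clades: FamilyCladeMap,
        B: int = 100,
        seed: int = 0,
        placement: Placement | None = None,
    ) -> tuple[float, float]:
        """Column-bootstrap support for a placement.

        Resamples alignment columns with replacement B times, re-places the
        query per replicate, and reports the fraction of replicates choosing
        the original best edge (edge support) and the fraction yielding the
        same edge-membership category (category support).
        """
        if B < 1:
            raise ValueError("need at least one bootstrap replicate")
        if placement is None:
            placement = self.place(aligned)
        cat0 = edge_membership(clades, placement.best_edge)
        rng = np.random.default_rng(seed)
        L = self.ref.length
        same_edge = same_cat = 0
        for _ in range(B):
            idx = rng.integers(L, size=L)
            pl = self._place_on(aligned.codes, cols=idx)
            if pl.best_edge == placement.best_edge:
                same_edge += 1
            if edge_membership(clades, pl.best_edge) == cat0:
                same_cat += 1
        return same_edge / B, same_cat / B


def place_queries(
    engine: PlacementEngine, queries: dict[str, str]
) -> tuple[dict[str, AlignedQuery], dict[str, Placement]]:
    """Align and place a batch of queries (order-independent results)."""
    aligned = {
        qid: align_query(engine.ref, qid, seq) for qid, seq in queries.items()
    }
    placements = {qid: engine.place(aq) for qid, aq in aligned.items()}
    return aligned, placements
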