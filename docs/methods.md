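# Methods

## The analysis model

### Placement likelihood

Queries are placed on a fixed, rooted, binary backbone tree whose leaves are
reference LSU sequences labeled with one of the 11 AMF families,
`outgroup`, or `unlabeled`. Edges are numbered by preorder rank of their
child node, so a backbone with *n* leaves has 2*n*−2 edges and results are
reproducible across runs and platforms.

The substitution model is GTR with stationary frequencies π,
exchangeabilities *s*, and discrete-gamma rate variation (Yang's
equal-probability categories with category-mean rates, K = 4). The rate
matrix is normalized to one expected substitution per site, so all branch
lengths and pendant lengths are in substitutions/site. Transition matrices
come from the eigendecomposition of the π-symmetrized rate matrix.

A query is attached at the **midpoint** of each edge in turn by a pendant
branch whose length is the only free parameter (an EPA-style heuristic; a
full joint re-optimization of the tree is deliberately out of scope). The
engine precomputes, per edge, the conditional likelihood of the entire
reference alignment as seen from the edge midpoint ("attachment partials",
with per-column log-scalers to avoid underflow at 600 columns). Scoring one
pendant length is then a single 4-state convolution per column, the pendant
is optimized by golden-section search on [1e-8, 2.0] to a width of 1e-4
simultaneously on every edge, and the best edge is the argmax with ties
broken to the smallest edge id. Column bootstrap (support values) is plain
column re-indexing of the precomputed partials, which is exactly equivalent
to recomputing on the resampled alignment.

The default analysis model is deliberately *not* the simulator's true model:
empirical base frequencies from the reference alignment, equal
exchangeabilities, Γ(4) with shape 1.0. Placement rank is robust to this
mismatch, and the package does not attempt full ML estimation of GTR
parameters.

Gaps and IUPAC ambiguity codes contribute all-ones partials (fully missing),
the standard pruning convention.

### Query alignment

Each query is anchored to its nearest reference by shared 8-mers (ties to
the lexicographically smallest leaf name) and aligned semi-globally (match
+1, mismatch −1, gap −2, end gaps free on the query). Query bases are
threaded into the anchor's alignment columns; query insertions relative to
the reference are discarded and uncovered columns are missing. Real-data
users must primer-trim reads beforehand — the simulator emits primer-free
amplicons, a documented limitation.

### Classification

Tree method: the best edge's membership decides the category. A family's
crown is the MRCA of its labeled leaves; an edge belongs to the family iff
both endpoints lie within the crown's subtree, so the **stem edge of a
family is backbone, not family** — a query on a stem becomes `unknown_amf`.
This is a choice: the source analysis does not state how stem placements
were counted, and the conservative reading (stem → unknown) matches the
discovery of lineages *sister to* named families. A bootstrap
category-support threshold exists but defaults to off.

Top-hit method: best database hit by semi-global alignment score (the raw
score is a monotone surrogate for a bit score under a fixed scoring scheme),
ties by higher identity then lexicographic id. Identity is computed over
aligned columns excluding the query's end overhang, mimicking
local-alignment identity. Identity strictly below 98% → non-AMF; an
`unlabeled` hit → unknown-AMF; an `outgroup` hit → non-AMF. Exact scoring is
preceded by a shared-8-mer candidate preselection (top 12 references by
default, exhaustive available via `n_candidates=None`) — the same
seed-then-score shape as the search tool this emulates; on the database
sizes used here the candidate set contains the score maximum (cross-checked
against exhaustive mode in the tests).

Concordance: "shared" ASVs are AMF under both methods. Because the source
analysis does not pin the misassignment denominator, the report carries
both: misassigned/shared and misassigned/both-family-assigned.

### Novel clades

Unknown-AMF ASVs are grafted at their best edges. When several ASVs share an
edge they hang from a single node at the edge midpoint as a query-only
pectinate subtree (zero-length internal branches, members keep their own
pendant lengths, ordered by descending placement log-likelihood). Grouping
co-placed queries under one attachment node is what makes them monophyletic
in the extended tree; attaching them at distinct points along the edge would
interleave them with the downstream subtree and no multi-member query-only
clade could ever exist — the grouped grafting is the coherent reading of
"queries that cluster together, separated from known families".

Candidate clades are the maximal subtrees whose leaves are all queries
(minimum size 2 by default; singletons via `min_size=1`). The sister family
is read from the nearest labeled sister subtree walking rootward — a single
family if unanimous, else the majority, ties reported as `amf_backbone`.
Clade support re-places the members per column-bootstrap replicate and asks
whether the same member set re-forms a query-only clade with the same
sister. A clade is "geographically structured" when ≥90% of its member reads
come from a single bioclimatic zone (the source judged structure by
inspection; the threshold is a choice).

### Ecology statistics

Richness, Shannon (natural log) and bias-corrected Chao1
(S + F1(F1−1)/(2(F2+1)), the +1 avoiding division by zero) per sample ×
family, with `unknown_amf` as a pseudo-family and non-AMF reads excluded.

Proportion-of-reads models are binomial GLMs (logit link, IRLS to 1e-8) on
(reads in family, other AMF reads). Amplicon counts are far overdispersed
relative to the binomial, so the covariance is scaled by the Pearson χ²/df
(quasi-binomial); site-cluster–robust covariance is optional. The mixed
models of the original analysis (replicate nested in zone:site random
effects, Tweedie responses, zero-inflated intercepts) are replaced by this
fixed-effects + dispersion/robust-SE scheme: the acceptance surface is sign
and calibration of contrasts, not variance-component estimates. Separation
triggers a warning and a small-ridge refit, flagged on the result.

Diversity models are negative-binomial regressions (log link, ML dispersion,
method-of-moments fallback flagged) with log total reads as a covariate.
Contrasts are linear combinations w'β with normal Wald inference; the
remnant-vs-disturbed contrast averages the two disturbed land-use
coefficients.

Differential abundance is a stand-in with the same decision structure as the
tool it replaces: median-of-ratios size factors (geometric means over ASVs
nonzero in every sample; total-count fallback with a warning), per-ASV
negative-binomial Wald tests with the log size factor as offset, no
dispersion shrinkage, Benjamini–Hochberg step-up, significance at adjusted
p < 0.1.

## The synthetic-data generator

The generator emulates everything the real survey consumed; its defaults are
the study conditions for all tests.

**Backbone** (`simulate_backbone`): outgroups and the AMF crown split at the
root; 11 family crowns (pure-birth, ultrametric, crown depth 0.03) hang off
a pectinate spine (internodes 0.02) by stem edges of length 0.10; outgroups
attach by a 0.25 stem. Crown branches are clipped from below at 0.005
substitutions/site: curated reference databases are dereplicated, and the
raw pure-birth process otherwise realizes near-zero branches that make
reference sequences bit-identical and placement edges unidentifiable. Stems long relative to crowns guarantee
within-family < between-family divergence, the premise of MRCA-based
classification. Sequences (600 bp, the scale of merged LROR–FLR2 amplicons)
evolve root-to-tip under GTR+Γ (π = (.26,.24,.26,.24), transition bias 2.5,
shape 0.5, 4 categories, per-site category fixed once so query evolution
sees the same site rates).

**Queries** (`simulate_queries`): (a) in-family — donors sampled on the
outer half of distinct leaf pendant edges (each query a shallow relative of
one reference taxon; spreads top hits across references), divergence 0.01 so
that top-hit identity stays above the 98% floor; (b) novel — a lineage
attached halfway up a family's stem edge, diverging 0.08 before radiating 4
members at depth 0.02; planted sisters are Entrophosporaceae, Glomeraceae
and Archaeosporaceae with temperate/temperate/tropical zone restriction,
mirroring the discovery setting; (c) non-AMF — outgroup relatives at
divergence 0.02. Interior attachment points are sampled by an
**endpoint-conditioned bridge** (state at an interior point of a branch
conditioned on both realized endpoint states) — sampling them as free
lineages off the parent node would silently move the planted attachment to
the wrong edge.

**Reads** (`simulate_reads`): R1 = first 300 bp, R2 = reverse complement of
the last 300 bp, iid per-base errors (default 0.001, within the
post-filtering MiSeq range) and constant quality strings at the matching
Phred score. Config validation rejects amplicons whose paired reads cannot
overlap by ≥20 bp.

**Community** (`simulate_community`): samples = zones × land uses × sites ×
replicates (default 3×3×2×2); counts are negative binomial (size 5) around
depth (5,000; a round desk-scale number — the source reports only a total
depth) × lognormal per-ASV abundance (σ = 1, drawn once) ×
exp(family-zone-land-use log-effect), then zeroed with probability 0.3
(amplicon data are zero-heavy; the level is a round default, not
calibrated). Default planted effects: Entrophosporaceae +1 and Glomeraceae
−1 (log scale) in agricultural and post-agricultural ("disturbed") samples.

**Label corruption** (`corrupt_labels`): independently per AMF reference,
the label is blanked with probability u = 0.35 or swapped to a different
uniform family with probability m = 0.06 — the observed rates of unusable
and wrong family labels in the public-database comparison, used here as
defaults only.

Determinism: one global seed; each operation draws from its own derived
substream (`SeedSequence(seed, spawn_key=(op,))`), so stages can be rerun
independently and the whole pipeline is bit-reproducible.

**What the generator does not emulate** — chimeras, PCR and primer bias,
indels (substitutions only), DADA2-style error structure, spatial
autocorrelation between sites, and real LSU secondary-structure constraints.
Passing tests therefore demonstrate the pipeline's internal correctness and
its statistical calibration under a faithful-but-idealized data model, not
performance on raw field data.

## Numerical and degenerate-input choices

- Per-node rescaling of partials with per-column log-scalers; 600-column
  alignments underflow without it.
- Pendant search on [1e-8, 2.0] to 1e-4; the likelihood is empirically
  unimodal in the pendant (asserted on grids in the tests).
- Ties everywhere break deterministically (smallest edge id, lexicographic
  names); all-missing query rows are a hard "unplaceable" error.
- Even with the minimum-branch clip, two references on a short cherry can
  realize identical sequences; a query equal to such a sequence ties between
  the duplicates' pendant edges and resolves by edge id. Checks of identity
  placement therefore accept any exact-match reference's pendant edge.
- BH adjustment is the step-up formula with a reverse cumulative minimum,
  capped at 1; p-values outside [0, 1] are rejected.

## Problem sizes used by the test and acceptance runs

Oracle-equivalence fixtures: 50 random 6–8-leaf backbones at 80 columns
against a 200-point pendant-grid pruning oracle. Recovery/calibration: 20
independent default studies (47-leaf backbone, 600 columns, 49 queries
each). Statistical calibration and power: 100 simulated 60-sample designs
per check. Bootstrap examples run at B = 25–100 (the analysis default is
B = 100; the original used 1,000 — support values at these B differ only in
Monte-Carlo resolution).
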