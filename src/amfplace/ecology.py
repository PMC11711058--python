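"""Family-level diversity and land-use statistics.

Per-sample, per-family alpha diversity (observed richness, Shannon in nats,
bias-corrected Chao1), proportion-of-reads binomial models with zone and
land-use contrasts, the high-zero family filter, and a per-ASV differential
abundance test (median-of-ratios normalization, negative-binomial Wald test,
Benjamini-Hochberg correction at adjusted p < 0.1).

Model notes: the binomial proportion model is fit by IRLS with the Pearson
X2/df dispersion as a quasi-likelihood scale, because amplicon read counts
are strongly overdispersed relative to the binomial; site-cluster-robust
covariance is optional.  Diversity counts use a negative-binomial regression
with ML dispersion and log total reads as a covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy import stats

BH_ALPHA = 0.1


# --------------------------------------------------------------------------
# alpha diversity


@dataclass
class DiversityRecord:
    sample_id: str
    family: str  # family name, "all" or "unknown_amf"
    richness: int
    shannon: float
    chao1: float
    reads_in_family: int
    total_reads: int


def diversity_metrics(
    counts, sample_id: str = "", family: str = "all", total_reads: int | None = None
) -> DiversityRecord:
    """Alpha diversity of one sample restricted to one family's ASVs.

    richness = number of nonzero ASVs; Shannon = -sum p_i ln p_i (nats);
    Chao1 (bias-corrected) = S_obs + F1(F1-1) / (2(F2+1)).  An empty sample
    yields zeros throughout.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative count in diversity input")
    nz = c[c > 0]
    richness = int(nz.size)
    if richness == 0:
        shannon = chao1 = 0.0
    else:
        p = nz / nz.sum()
        shannon = float(-(p * np.log(p)).sum())
        f1 = int(np.sum(nz == 1))
        f2 = int(np.sum(nz == 2))
        chao1 = richness + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    reads = int(nz.sum())
    return DiversityRecord(
        sample_id=sample_id,
        family=family,
        richness=richness,
        shannon=shannon,
        chao1=float(chao1),
        reads_in_family=reads,
        total_reads=int(total_reads if total_reads is not None else reads),
    )


def diversity_table(
    counts: pd.DataFrame, category_of_asv: dict[str, str]
) -> pd.DataFrame:
    """Per-sample, per-family diversity records as a tidy DataFrame.

    ``category_of_asv`` maps ASV id -> ``family:<f>``, ``unknown_amf`` or
    ``non_amf``; non-AMF ASVs are excluded, unknown-AMF form their own
    pseudo-family, and ``all`` pools every AMF ASV.
    """
    groups: dict[str, list[str]] = {}
    amf_cols: list[str] = []
    for asv in counts.columns:
        cat = category_of_asv.get(asv, "non_amf")
        if cat == "non_amf":
            continue
        key = cat.split(":", 1)[1] if cat.startswith("family:") else "unknown_amf"
        groups.setdefault(key, []).append(asv)
        amf_cols.append(asv)
    rows = []
    for sample in counts.index:
        total = int(counts.loc[sample, amf_cols].sum()) if amf_cols else 0
        for fam in sorted(groups) + ["all"]:
            cols = amf_cols if fam == "all" else groups[fam]
            rec = diversity_metrics(
                counts.loc[sample, cols], str(sample), fam, total_reads=total
            )
            rows.append(rec.__dict__)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# proportion of reads


def proportion_reads(
    counts: pd.DataFrame, category_of_asv: dict[str, str], family: str
) -> pd.DataFrame:
    """Per-sample (reads_in, reads_out) for one family.

    ``reads_in`` are the reads of ASVs assigned to the family (``unknown_amf``
    acts as a pseudo-family); ``reads_out`` are the remaining AMF reads.
    Non-AMF reads are excluded entirely.
    """
    in_cols, amf_cols = [], []
    for asv in counts.columns:
        cat = category_of_asv.get(asv, "non_amf")
        if cat == "non_amf":
            continue
        amf_cols.append(asv)
        key = cat.split(":", 1)[1] if cat.startswith("family:") else "unknown_amf"
        if key == family:
            in_cols.append(asv)
    reads_in = counts[in_cols].sum(axis=1) if in_cols else pd.Series(0, index=counts.index)
    total = counts[amf_cols].sum(axis=1) if amf_cols else pd.Series(0, index=counts.index)
    return pd.DataFrame(
        {"reads_in": reads_in.astype(int), "reads_out": (total - reads_in).astype(int)}
    )


def filter_high_zero_families(
    reads_in_by_family: pd.DataFrame, zero_threshold: float = 0.7
) -> tuple[list[str], list[str]]:
    """Iteratively drop the family with the highest fraction of zero cells
    while that fraction exceeds ``zero_threshold`` (ties: lexicographically
    first).  Input: samples x families matrix of reads_in.  Returns
    (retained families, removal order)."""
    remaining = sorted(reads_in_by_family.columns)
    removed: list[str] = []
    while remaining:
        zero_frac = {
            f: float((reads_in_by_family[f] == 0).mean()) for f in remaining
        }
        worst = max(zero_frac.values())
        if worst <= zero_threshold:
            break
        victim = min(f for f, v in zero_frac.items() if v == worst)
        removed.append(victim)
        remaining.remove(victim)
    return remaining, removed


# --------------------------------------------------------------------------
# regression models


@dataclass
class ModelFit:
    params: pd.Series
    cov: pd.DataFrame
    dispersion: float | None
    model_type: str
    separation_flag: bool = False
    dispersion_fallback: bool = False
    results: object = field(default=None, repr=False)


def fit_proportion_model(
    data: pd.DataFrame,
    formula: str,
    cluster: str | None = None,
) -> ModelFit:
    """Binomial (logit) regression of (reads_in, reads_out) on a factorial
    design, with quasi-likelihood scale = Pearson X2/df.

    ``data`` needs ``reads_in``/``reads_out`` plus the design columns named
    in the patsy ``formula`` (right-hand side only, e.g.
    ``"C(family) * C(zone) * C(land_use)"``).  ``cluster`` names a column for
    cluster-robust (site) covariance.
    """
    endog = data[["reads_in", "reads_out"]].to_numpy(dtype=float)
    if (endog.sum(axis=1) <= 0).any():
        raise ValueError("sample with zero AMF reads; drop it before fitting")
    X = dmatrix(formula, data, return_type="dataframe")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient; need >=2 levels per factor")
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if cluster is not None:
                res = model.fit(
                    cov_type="cluster",
                    cov_kwds={"groups": data[cluster].astype("category").cat.codes},
                )
            else:
                res = model.fit()
        mu = res.fittedvalues
        if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10) or not np.all(
            np.isfinite(res.params)
        ):
            raise ValueError("separation")
    except Exception:
        separation = True
        warnings.warn("separation detected; refitting with a small ridge penalty")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start = model.fit_regularized(alpha=1e-4, L1_wt=0.0).params
            res = model.fit(start_params=start, maxiter=5)
    pearson = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else 1.0
    cov = np.asarray(res.cov_params())
    if cluster is None:
        # quasi-binomial: inflate the MLE covariance by the Pearson X2/df
        # dispersion (the cluster sandwich is already overdispersion-robust)
        cov = cov * pearson
    return ModelFit(
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        dispersion=pearson,
        model_type="quasibinomial",
        separation_flag=separation,
        results=res,
    )


def fit_diversity_model(
    data: pd.DataFrame,
    response: str,
    formula: str,
    depth_covariate: bool = True,
) -> ModelFit:
    """Negative-binomial (log link) regression of a count diversity metric.

    ``log(total_reads)`` enters as a covariate to absorb depth differences.
    Dispersion is estimated by maximum likelihood; on ML failure a
    method-of-moments estimate with a fixed-dispersion GLM is used (flagged).
    """
    y = data[response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("negative response")
    if np.all(y == 0):
        raise ValueError("all-zero response")
    rhs = formula
    if depth_covariate:
        rhs = f"{formula} + np.log(total_reads)"
    X = dmatrix(rhs, data, return_type="dataframe")
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.params)):
                raise ValueError("non-finite NB fit")
            params = pd.Series(res.params[:-1], index=X.columns)
            alpha = float(res.params[-1])
            cov = pd.DataFrame(
                np.asarray(res.cov_params())[: len(X.columns), : len(X.columns)],
                index=X.columns,
                columns=X.columns,
            )
        except Exception:
            fallback = True
            pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            mu = pois.fittedvalues
            alpha = max(
                float(((y - mu) ** 2 - mu).sum() / (mu**2).sum()), 1e-8
            )
            res = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha)
            ).fit()
            params = pd.Series(res.params, index=X.columns)
            cov = pd.DataFrame(
                res.cov_params(), index=X.columns, columns=X.columns
            )
    return ModelFit(
        params=params,
        cov=cov,
        dispersion=alpha,
        model_type="negative_binomial",
        dispersion_fallback=fallback,
        results=res,
    )


@dataclass
class ContrastResult:
    term: str
    estimate: float
    se: float
    z: float
    p: float
    adjusted_p: float | None = None


def contrast(fit: ModelFit, weights, term: str = "contrast") -> ContrastResult:
    """Linear contrast w'beta with normal (Wald) inference."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(fit.params),):
        raise ValueError(
            f"weights length {w.size} != {len(fit.params)} coefficients"
        )
    if np.all(w == 0):
        raise ValueError("degenerate contrast: all-zero weights")
    est = float(w @ fit.params.to_numpy())
    var = float(w @ fit.cov.to_numpy() @ w)
    if not np.isfinite(var) or var <= 0:
        raise ValueError("singular covariance for contrast")
    se = float(np.sqrt(var))
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ContrastResult(term=term, estimate=est, se=se, z=z, p=p)


def contrast_weights(fit: ModelFit, coef_weights: dict[str, float]) -> np.ndarray:
    """Build a weight vector from coefficient-name -> weight pairs."""
    w = np.zeros(len(fit.params))
    names = list(fit.params.index)
    for name, weight in coef_weights.items():
        if name not in names:
            raise KeyError(f"coefficient {name!r} not in the fit ({names})")
        w[names.index(name)] = weight
    return w


# --------------------------------------------------------------------------
# differential abundance (median-of-ratios + NB Wald + BH)


@dataclass
class DiffAbundanceResult:
    asv_id: str
    log2_fold_change: float
    se: float
    p: float
    adjusted_p: float = np.nan
    significant: bool = False


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    Geometric means are taken over ASVs nonzero in every sample; if no such
    ASV exists the factors fall back to total-count scaling (flagged through
    a warning).
    """
    mat = counts.to_numpy(dtype=float)
    universal = (mat > 0).all(axis=0)
    if universal.any():
        logmat = np.log(mat[:, universal])
        geo = logmat.mean(axis=0)
        sf = np.exp(np.median(logmat - geo, axis=1))
    else:
        warnings.warn("no ASV nonzero in all samples; using total-count scaling")
        totals = mat.sum(axis=1)
        sf = totals / np.exp(np.log(totals[totals > 0]).mean())
        sf[sf == 0] = 1.0
    return pd.Series(sf, index=counts.index)


def diff_abundance(
    counts: pd.DataFrame,
    groups: pd.Series,
    alpha: float = BH_ALPHA,
) -> list[DiffAbundanceResult]:
    """Per-ASV two-group differential abundance.

    Negative-binomial regression of counts on the group indicator with the
    log size factor as offset; Wald p-values, BH adjustment, significance at
    adjusted p < ``alpha``.
    """
    groups = groups.loc[counts.index]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    if (groups == levels[0]).sum() < 2 or (groups == levels[1]).sum() < 2:
        raise ValueError("need >=2 samples per group")
    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    g = (groups == levels[1]).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(g), g])
    out = []
    ln2 = np.log(2.0)
    for asv in counts.columns:
        y = counts[asv].to_numpy(dtype=float)
        if (y > 0).sum() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.NegativeBinomial(y, X, offset=offset).fit(
                    disp=0, maxiter=100
                )
                beta, se = res.params[1], res.bse[1]
                if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
                    raise ValueError
            except Exception:
                try:
                    res = sm.GLM(
                        y,
                        X,
                        family=sm.families.NegativeBinomial(alpha=0.5),
                        offset=offset,
                    ).fit()
                    beta, se = res.params[1], res.bse[1]
                except Exception:
                    continue
        if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
            continue
        z = beta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(
            DiffAbundanceResult(
                asv_id=asv, log2_fold_change=float(beta / ln2), se=float(se / ln2), p=p
            )
        )
    if out:
        adj = bh_adjust(np.array([r.p for r in out]))
        for r, a in zip(out, adj):
            r.adjusted_p = float(a)
            r.significant = bool(a < alpha)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out
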