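"""Diversity metrics, proportion/diversity models, contrasts, differential
abundance and the BH step-up — against closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from amfplace.ecology import (
    bh_adjust,
    contrast,
    contrast_weights,
    diff_abundance,
    diversity_metrics,
    diversity_table,
    filter_high_zero_families,
    fit_diversity_model,
    fit_proportion_model,
    proportion_reads,
    size_factors,
)

# -- alpha diversity ---------------------------------------------------------


def test_diversity_uniform_counts():
    rec = diversity_metrics([10, 10, 10, 10])
    assert rec.richness == 4
    assert rec.shannon == pytest.approx(np.log(4))
    assert rec.chao1 == pytest.approx(4.0)


def test_diversity_chao1_formula():
    # S_obs=5, F1=2 singletons, F2=1 doubleton -> 5 + 2*1/(2*2) = 5.5
    rec = diversity_metrics([5, 5, 1, 1, 2])
    assert rec.richness == 5
    assert rec.chao1 == pytest.approx(5.5)


def test_diversity_single_and_empty():
    assert diversity_metrics([7]).shannon == 0.0
    empty = diversity_metrics([0, 0, 0])
    assert (empty.richness, empty.shannon, empty.chao1) == (0, 0.0, 0.0)
    with pytest.raises(ValueError):
        diversity_metrics([-1, 2])


def test_diversity_matches_skbio_oracle():
    from skbio.diversity.alpha import chao1, shannon

    rng = np.random.default_rng(7)
    for _ in range(20):
        counts = rng.integers(0, 20, size=12)
        if counts.sum() == 0:
            continue
        rec = diversity_metrics(counts)
        nz = counts[counts > 0]
        assert rec.shannon == pytest.approx(shannon(nz, base=np.e))
        assert rec.chao1 == pytest.approx(chao1(counts, bias_corrected=True))


@given(
    st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=30)
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_diversity_invariants(counts):
    rec = diversity_metrics(counts)
    assert rec.chao1 >= rec.richness - 1e-9
    assert rec.shannon >= 0.0
    assert rec.shannon <= np.log(max(rec.richness, 1)) + 1e-9
    nz = [c for c in counts if c > 0]
    if nz and len(set(nz)) == 1:
        # uniform proportions attain the Shannon maximum ln S
        assert rec.shannon == pytest.approx(np.log(len(nz)))
    if nz and min(nz) > 1:
        assert rec.chao1 == pytest.approx(rec.richness)  # no singletons


# -- proportions -------------------------------------------------------------


@pytest.fixture()
def toy_counts():
    counts = pd.DataFrame(
        {
            "a1": [10, 0],
            "a2": [5, 5],
            "a3": [0, 20],
            "x": [3, 3],  # non-AMF
        },
        index=["s1", "s2"],
    )
    cats = {
        "a1": "family:F1",
        "a2": "family:F2",
        "a3": "unknown_amf",
        "x": "non_amf",
    }
    return counts, cats


def test_proportion_reads_partition(toy_counts):
    counts, cats = toy_counts
    total_amf = counts[["a1", "a2", "a3"]].sum(axis=1)
    numerators = pd.Series(0, index=counts.index)
    for fam in ("F1", "F2", "unknown_amf"):
        pr = proportion_reads(counts, cats, fam)
        assert ((pr["reads_in"] + pr["reads_out"]) == total_amf).all()
        numerators = numerators + pr["reads_in"]
    # numerators over families + unknown partition the AMF reads
    assert (numerators == total_amf).all()


def test_proportion_reads_extremes(toy_counts):
    counts, cats = toy_counts
    only = proportion_reads(counts.loc[["s1"], ["a1", "x"]], cats, "F1")
    assert only.loc["s1", "reads_in"] == 10 and only.loc["s1", "reads_out"] == 0
    none = proportion_reads(counts, cats, "F_missing")
    assert (none["reads_in"] == 0).all()


def test_filter_high_zero_families():
    df = pd.DataFrame(
        {
            "A": [0] * 71 + [1] * 29,  # 71% zeros
            "B": [0] * 10 + [1] * 90,
            "C": [0] * 80 + [1] * 20,  # 80% zeros
            "D": [0] * 80 + [1] * 20,  # tie with C
        }
    )
    retained, removed = filter_high_zero_families(df, zero_threshold=0.7)
    assert removed == ["C", "D", "A"]  # ties lexicographic, then next worst
    assert retained == ["B"]
    retained, removed = filter_high_zero_families(df[["B"]], 0.7)
    assert removed == [] and retained == ["B"]


# -- proportion model --------------------------------------------------------


def _two_group_df(p0, p1, n=40, trials=20000, seed=0):
    rng = np.random.default_rng(seed)
    g = np.repeat([0, 1], n // 2)
    p = np.where(g == 0, p0, p1)
    ri = rng.binomial(trials, p)
    return pd.DataFrame(
        {"reads_in": ri, "reads_out": trials - ri, "g": g,
         "site": np.arange(n) // 4}
    )


def test_proportion_model_recovers_logit_difference():
    df = _two_group_df(0.2, 0.8)
    fit = fit_proportion_model(df, "C(g)")
    # log-odds difference ln(0.8/0.2) - ln(0.2/0.8) = 2 ln 4
    est = fit.params["C(g)[T.1]"]
    assert est == pytest.approx(2 * np.log(4), abs=0.05)


def test_proportion_model_null_contrast_near_zero():
    df = _two_group_df(0.4, 0.4, seed=3)
    fit = fit_proportion_model(df, "C(g)")
    cr = contrast(fit, contrast_weights(fit, {"C(g)[T.1]": 1.0}))
    assert abs(cr.z) < 3.5


def test_proportion_model_cluster_robust_runs():
    df = _two_group_df(0.3, 0.5, seed=4)
    fit = fit_proportion_model(df, "C(g)", cluster="site")
    assert fit.cov.shape == (2, 2)
    assert np.all(np.isfinite(fit.cov.to_numpy()))


def test_proportion_model_rank_deficiency_rejected():
    df = _two_group_df(0.3, 0.3)
    df["g2"] = df["g"]
    with pytest.raises(ValueError, match="rank"):
        fit_proportion_model(df, "C(g) + C(g2)")


# -- diversity model ---------------------------------------------------------


def test_nb_model_poisson_limit_matches_poisson_fit():
    import statsmodels.api as sm
    from patsy import dmatrix

    rng = np.random.default_rng(0)
    n = 800
    g = rng.integers(0, 2, n)
    depth = rng.uniform(2000, 20000, n)
    mu = np.exp(1.2 + 0.6 * g) * (depth / 5000.0)
    df = pd.DataFrame({"rich": rng.poisson(mu), "g": g, "total_reads": depth})
    fit = fit_diversity_model(df, "rich", "C(g)")
    assert fit.dispersion < 0.05  # NB alpha -> 0 in the Poisson limit
    X = dmatrix("C(g) + np.log(total_reads)", df, return_type="dataframe")
    pois = sm.GLM(df["rich"], X, family=sm.families.Poisson()).fit()
    assert np.abs(fit.params.to_numpy() - pois.params.to_numpy()).max() < 1e-3


def test_nb_model_depth_scaling_coefficient():
    """Doubling depth with no rate effect doubles the mean: the log-depth
    coefficient is ~1."""
    rng = np.random.default_rng(1)
    n = 600
    depth = np.repeat([4000.0, 8000.0], n // 2)
    mu = 20.0 * depth / 4000.0
    df = pd.DataFrame(
        {"rich": rng.poisson(mu), "g": rng.integers(0, 2, n), "total_reads": depth}
    )
    fit = fit_diversity_model(df, "rich", "C(g)")
    assert fit.params["np.log(total_reads)"] == pytest.approx(1.0, abs=0.1)


def test_nb_model_rejects_degenerate_responses():
    df = pd.DataFrame({"rich": [0, 0, 0], "g": [0, 1, 0], "total_reads": [1, 1, 1]})
    with pytest.raises(ValueError):
        fit_diversity_model(df, "rich", "C(g)")


# -- contrasts ---------------------------------------------------------------


def test_contrast_identity_weights_reproduce_coefficient():
    df = _two_group_df(0.2, 0.6, seed=5)
    fit = fit_proportion_model(df, "C(g)")
    w = contrast_weights(fit, {"C(g)[T.1]": 1.0})
    cr = contrast(fit, w)
    assert cr.estimate == pytest.approx(fit.params["C(g)[T.1]"])
    assert cr.se == pytest.approx(np.sqrt(fit.cov.loc["C(g)[T.1]", "C(g)[T.1]"]))


def test_contrast_zero_weights_rejected():
    df = _two_group_df(0.2, 0.6, seed=5)
    fit = fit_proportion_model(df, "C(g)")
    with pytest.raises(ValueError, match="degenerate"):
        contrast(fit, np.zeros(len(fit.params)))


def test_remnant_vs_disturbed_contrast_matches_two_level_refit():
    """Averaging the two disturbed land-use coefficients equals refitting
    with the pooled two-level coding on balanced data."""
    rng = np.random.default_rng(6)
    lu = np.repeat(["remnant", "agricultural", "post_agricultural"], 30)
    p = {"remnant": 0.3, "agricultural": 0.5, "post_agricultural": 0.5}
    trials = 50000
    ri = rng.binomial(trials, [p[x] for x in lu])
    df = pd.DataFrame({"reads_in": ri, "reads_out": trials - ri, "land_use": lu})
    fit3 = fit_proportion_model(df, "C(land_use, Treatment('remnant'))")
    names = [c for c in fit3.params.index if "T." in c]
    w = contrast_weights(fit3, {names[0]: 0.5, names[1]: 0.5})
    cr3 = contrast(fit3, w)
    df["disturbed"] = (df["land_use"] != "remnant").astype(int)
    fit2 = fit_proportion_model(df, "C(disturbed)")
    cr2 = contrast(fit2, contrast_weights(fit2, {"C(disturbed)[T.1]": 1.0}))
    assert cr3.estimate == pytest.approx(cr2.estimate, abs=1e-6)


# -- differential abundance --------------------------------------------------


def test_size_factors_equal_counts_are_one():
    counts = pd.DataFrame(
        np.tile([10, 20, 30, 40], (6, 1)),
        index=[f"s{i}" for i in range(6)],
        columns=list("abcd"),
    )
    sf = size_factors(counts)
    assert np.allclose(sf, 1.0)


def test_size_factors_track_library_scale():
    rng = np.random.default_rng(2)
    base = rng.integers(50, 150, size=30)
    scale = np.array([0.5, 1.0, 2.0, 1.0])
    counts = pd.DataFrame(
        np.round(np.outer(scale, base)).astype(int),
        index=list("wxyz"),
        columns=[f"a{i}" for i in range(30)],
    )
    sf = size_factors(counts)
    assert np.allclose(sf / sf.iloc[1], scale, rtol=0.02)


def test_diff_abundance_null_false_positives_controlled():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(
        rng.poisson(100, size=(20, 200)),
        index=[f"s{i}" for i in range(20)],
        columns=[f"a{j}" for j in range(200)],
    )
    groups = pd.Series(["A"] * 10 + ["B"] * 10, index=counts.index)
    res = diff_abundance(counts, groups)
    fp = sum(r.significant for r in res)
    assert fp / len(res) <= 0.1
    # p-values roughly uniform: mean within 4 SE of 0.5
    pvals = np.array([r.p for r in res])
    assert abs(pvals.mean() - 0.5) < 4 * (1 / np.sqrt(12 * len(pvals)))


def test_diff_abundance_recovers_planted_fold_change():
    rng = np.random.default_rng(8)
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        counts = pd.DataFrame(
            rng.poisson(250, size=(20, 60)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"a{j}" for j in range(60)],
        )
        counts.iloc[10:, 0] = rng.poisson(1000, size=10)  # 4-fold up in B
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=counts.index)
        res = {r.asv_id: r for r in diff_abundance(counts, groups)}
        r = res["a0"]
        if abs(r.log2_fold_change - 2.0) <= 0.5 and r.significant:
            hits += 1
    assert hits >= 9


def test_diff_abundance_requires_two_groups(toy_counts):
    counts, _ = toy_counts
    with pytest.raises(ValueError):
        diff_abundance(counts, pd.Series(["A", "A"], index=counts.index))


# -- BH ----------------------------------------------------------------------


def test_bh_stepup_frozen_example():
    adj = bh_adjust([0.01, 0.02, 0.04, 0.5])
    assert np.allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.5])


def test_bh_edge_cases():
    assert bh_adjust([0.3]).tolist() == [0.3]
    assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([np.nan])


@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        min_size=1,
        max_size=60,
    )
)
@settings(max_examples=80, deadline=None, derandomize=True)
def test_bh_matches_statsmodels_and_is_monotone(pvals):
    from statsmodels.stats.multitest import multipletests

    mine = bh_adjust(pvals)
    theirs = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(mine, theirs, atol=1e-12)
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(mine[order]) >= -1e-12)
    assert np.all((mine >= np.asarray(pvals) - 1e-12) & (mine <= 1.0))


# -- diversity_table wiring ---------------------------------------------------


def test_diversity_table_excludes_non_amf(toy_counts):
    counts, cats = toy_counts
    tab = diversity_table(counts, cats)
    fams = set(tab["family"])
    assert fams == {"F1", "F2", "unknown_amf", "all"}
    all_s1 = tab[(tab.sample_id == "s1") & (tab.family == "all")].iloc[0]
    assert all_s1.total_reads == 15  # excludes the non-AMF column
    assert all_s1.richness == 2
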