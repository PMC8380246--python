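"""Normalization, NB-GLM differential expression, and the screening funnel."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adtraj import bh_adjust, nb_wald_de, normalize_log2, pearson_screen, residualize, size_factors
from adtraj.screening import select_candidates

# --- size factors -----------------------------------------------------------


def test_size_factors_doubled_sample_closed_form():
    counts = pd.DataFrame({"s1": [10, 100, 50], "s2": [20, 200, 100]})
    s = size_factors(counts)
    assert s["s1"] == pytest.approx(1 / np.sqrt(2))
    assert s["s2"] == pytest.approx(np.sqrt(2))


def test_size_factors_identical_and_single_sample():
    counts = pd.DataFrame({"a": [5, 8, 3], "b": [5, 8, 3], "c": [5, 8, 3]})
    assert np.allclose(size_factors(counts).values, 1.0)
    assert size_factors(pd.DataFrame({"only": [4, 7]})).values == pytest.approx([1.0])


def test_size_factor_ratio_equivariance(rng):
    counts = pd.DataFrame(rng.poisson(50, size=(200, 4)), columns=list("abcd")) + 1
    s = size_factors(counts)
    scaled = counts.copy()
    scaled["b"] = scaled["b"] * 3
    s2 = size_factors(scaled)
    assert (s2["b"] / s2["a"]) == pytest.approx(3 * s["b"] / s["a"], rel=1e-9)


def test_size_factors_need_one_allpositive_gene():
    counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError, match="positive"):
        size_factors(counts)


# --- log2 transform and residualization -------------------------------------


def test_normalize_log2_values_and_scale_invariance():
    counts = pd.DataFrame({"a": [7], "b": [0]})
    out = normalize_log2(counts, np.array([1.0, 2.0]), pseudocount=1.0)
    assert out.iloc[0, 0] == pytest.approx(3.0)
    assert out.iloc[0, 1] == pytest.approx(0.0)
    doubled = normalize_log2(2 * counts, np.array([2.0, 4.0]), pseudocount=1.0)
    pd.testing.assert_frame_equal(out, doubled)
    with pytest.raises(ValueError):
        normalize_log2(counts, np.array([1.0, 1.0]), pseudocount=0.0)


def test_residualize_removes_known_covariate_effect(rng):
    age = rng.uniform(18, 61, 50)
    cov = pd.DataFrame({"age": age, "sex": rng.integers(0, 2, 50), "rin": rng.uniform(6, 10, 50)})
    expr = pd.DataFrame(np.outer([0.3, -0.2], age) + 5.0, index=["g1", "g2"])
    adjusted = residualize(expr, cov)
    for g in ("g1", "g2"):
        slope = np.polyfit(age, adjusted.loc[g].values, 1)[0]
        assert abs(slope) < 1e-8
    # grand mean is preserved
    assert adjusted.values.mean(axis=1) == pytest.approx(expr.values.mean(axis=1))


def test_residualize_orthogonal_covariates_is_identity(rng):
    cov = pd.DataFrame({"x": np.array([1.0, -1.0, 1.0, -1.0])})
    expr = pd.DataFrame([[2.0, 2.0, 5.0, 5.0]])  # orthogonal to x, centered on mean
    out = residualize(expr, cov)
    assert np.allclose(out.values, expr.values)


def test_residualize_rank_deficient_names_columns(rng):
    cov = pd.DataFrame({"age": np.arange(10.0), "age2": 2 * np.arange(10.0)})
    expr = pd.DataFrame(rng.normal(size=(3, 10)))
    with pytest.raises(ValueError, match="age"):
        residualize(expr, cov)


# --- BH adjustment -----------------------------------------------------------


def test_bh_adjust_hand_examples():
    assert bh_adjust([0.04]) == pytest.approx([0.04])
    out = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
@settings(max_examples=60, deadline=None)
def test_bh_adjust_dominates_input_and_is_rank_monotone(pvals):
    adj = bh_adjust(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # monotone in input ranks


# --- Pearson screen -----------------------------------------------------------


def test_pearson_screen_matches_scipy(rng):
    expr = pd.DataFrame(rng.normal(size=(25, 12)))
    y = rng.normal(size=12)
    out = pearson_screen(expr, y)
    for g in range(25):
        r, p = stats.pearsonr(expr.iloc[g].values, y)
        assert out["r"].iloc[g] == pytest.approx(r, abs=1e-12)
        assert out["p"].iloc[g] == pytest.approx(p, rel=1e-9)


def test_pearson_screen_perfect_and_degenerate():
    x = np.arange(10.0)
    expr = pd.DataFrame([x, np.zeros(10)])
    out = pearson_screen(expr, x)
    assert out["r"].iloc[0] == pytest.approx(1.0)
    assert out["p"].iloc[0] < 1e-12
    assert out["zero_variance"].iloc[1]
    assert np.isnan(out["r"].iloc[1]) and out["p"].iloc[1] == 1.0


def test_pearson_screen_null_pvalues_uniform(rng):
    expr = pd.DataFrame(rng.normal(size=(4000, 30)))
    y = rng.normal(size=30)
    out = pearson_screen(expr, y)
    assert stats.kstest(out["p"].values, "uniform").pvalue > 0.01


# --- NB GLM Wald DE -----------------------------------------------------------


def _simulate_nb(rng, n_genes, n_per_group, mu, alpha, lfc2=0.0):
    group = np.repeat([0.0, 1.0], n_per_group)
    mu_mat = np.full((n_genes, 2 * n_per_group), float(mu))
    mu_mat[:, group == 1] *= 2.0**lfc2
    counts = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu_mat))
    return pd.DataFrame(counts), group


def test_nb_wald_de_matches_statsmodels_at_fixed_dispersion(rng):
    counts, group = _simulate_nb(rng, 15, 30, mu=80, alpha=0.2, lfc2=0.7)
    sf = np.ones(counts.shape[1])
    ours = nb_wald_de(counts, group, sf)
    X = sm.add_constant(group)
    for g in range(15):
        fam = sm.families.NegativeBinomial(alpha=ours["dispersion"].iloc[g])
        fit = sm.GLM(counts.iloc[g].values, X, family=fam).fit()
        assert ours["lfc"].iloc[g] * np.log(2) == pytest.approx(fit.params[1], abs=1e-4)
        assert ours["se"].iloc[g] * np.log(2) == pytest.approx(fit.bse[1], abs=1e-4)


def test_nb_wald_de_poisson_limit_matches_poisson_glm(rng):
    group = np.repeat([0.0, 1.0], 40)
    mu = np.where(group == 1, 300.0, 200.0)
    counts = pd.DataFrame(rng.poisson(np.tile(mu, (10, 1))))
    ours = nb_wald_de(counts, group, np.ones(80))
    X = sm.add_constant(group)
    for g in range(10):
        fit = sm.GLM(counts.iloc[g].values, X, family=sm.families.Poisson()).fit()
        assert ours["lfc"].iloc[g] * np.log(2) == pytest.approx(fit.params[1], abs=1e-3)
        assert ours["dispersion"].iloc[g] < 0.02


def test_nb_wald_de_lfc_recovery(rng):
    counts, group = _simulate_nb(rng, 200, 50, mu=100, alpha=0.1, lfc2=1.0)
    out = nb_wald_de(counts, group, np.ones(100))
    assert out["lfc"].mean() == pytest.approx(1.0, abs=0.1)


def test_nb_wald_de_dispersion_recovery(rng):
    counts, group = _simulate_nb(rng, 150, 200, mu=150, alpha=0.25)
    out = nb_wald_de(counts, group, np.ones(400))
    assert np.median(out["dispersion"]) == pytest.approx(0.25, abs=0.05)


def test_nb_wald_de_all_zero_gene_flagged(rng):
    counts, group = _simulate_nb(rng, 5, 10, mu=50, alpha=0.1)
    counts.iloc[2] = 0
    out = nb_wald_de(counts, group, np.ones(20))
    assert out["all_zero"].iloc[2]
    assert out["p"].iloc[2] == 1.0 and out["lfc"].iloc[2] == 0.0


def test_nb_wald_de_input_validation(rng):
    counts, group = _simulate_nb(rng, 3, 5, mu=50, alpha=0.1)
    with pytest.raises(ValueError, match="binary"):
        nb_wald_de(counts, np.array([0, 1, 2] + [0] * 7), np.ones(10))
    with pytest.raises(ValueError, match="at least 2"):
        nb_wald_de(counts.iloc[:, :3], np.array([0.0, 1.0, 1.0]), np.ones(3))


# --- funnel -------------------------------------------------------------------


def _funnel_tables(n, padj, p_t8, p_t0):
    idx = pd.Index([f"g{i}" for i in range(n)], name="gene")
    de = pd.DataFrame({"padj": padj}, index=idx)
    c8 = pd.DataFrame({"r": 0.0, "p": p_t8}, index=idx)
    c0 = pd.DataFrame({"r": 0.0, "p": p_t0}, index=idx)
    return de, c8, c0


def test_select_candidates_stagewise_logic():
    de, c8, c0 = _funnel_tables(
        4,
        padj=[0.1, 0.1, 0.5, 0.1],
        p_t8=[0.01, 0.2, 0.01, 0.01],
        p_t0=[0.5, 0.5, 0.5, 0.05],
    )
    res = select_candidates(de, c8, c0)
    assert res.selected == ["g0"]
    counts = res.stage_counts
    assert counts["criterion1_de"] == 3
    assert counts["criterion2_corr_t8"] == 2
    assert counts["criterion3_no_baseline_corr"] == 1
    vals = [
        counts["universe"],
        counts["criterion1_de"],
        counts["not_missing"],
        counts["criterion2_corr_t8"],
        counts["criterion3_no_baseline_corr"],
    ]
    assert vals == sorted(vals, reverse=True)  # funnel is monotone


def test_select_candidates_empty_de_pass():
    de, c8, c0 = _funnel_tables(3, padj=[0.9, 0.9, 0.9], p_t8=[0.01] * 3, p_t0=[0.9] * 3)
    res = select_candidates(de, c8, c0)
    assert res.selected == []
    assert res.stage_counts["criterion1_de"] == 0


def test_select_candidates_threshold_validation():
    de, c8, c0 = _funnel_tables(2, padj=[0.1, 0.1], p_t8=[0.01, 0.01], p_t0=[0.9, 0.9])
    with pytest.raises(ValueError):
        select_candidates(de, c8, c0, de_fdr=1.5)


def test_screen_cohort_marker_genes_pass_early_criteria(small_screen):
    """Markers are baseline-DE and correlate with the week-8 MADRS ratio."""
    cohort, labels, result = small_screen
    markers = list(cohort.truth.gene)
    funnel = result.funnel
    assert funnel.loc[markers, "criterion2_corr_t8"].sum() >= 2  # of 3 markers
    null_genes = funnel.index.difference(markers)
    # null genes pass the baseline-DE criterion at well below the marker rate
    assert funnel.loc[null_genes, "criterion1_de"].mean() < 0.2
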