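"""Trend fits, projections, feature regression, gene rankings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phyloprogress.progress import (
    feature_regression,
    fit_trend,
    project,
    rank_genes,
)

YEARS = np.arange(1993, 2009)


# -- trends ------------------------------------------------------------------


def test_exact_line_perfect_linear_fit():
    series = pd.Series(2.0 * (YEARS - 1993) + 1.0, index=YEARS)
    lin = fit_trend(series, order=1)
    assert lin.r_squared == pytest.approx(1.0)
    quad = fit_trend(series, order=2)
    assert quad.p_improvement == pytest.approx(1.0)  # nothing left to explain


def test_exact_parabola_needs_quadratic():
    x = YEARS - 1993
    series = pd.Series(0.01 * x**2 + 0.1 * x, index=YEARS)
    lin = fit_trend(series, order=1)
    quad = fit_trend(series, order=2)
    assert quad.r_squared == pytest.approx(1.0)
    assert quad.r_squared > lin.r_squared
    assert quad.p_improvement < 1e-10


def test_quadratic_never_decreases_r2():
    rng = np.random.default_rng(0)
    for _ in range(10):
        series = pd.Series(rng.random(len(YEARS)), index=YEARS)
        assert fit_trend(series, 2).r_squared >= fit_trend(series, 1).r_squared - 1e-12


def test_exponential_fit_recovers_growth_rate():
    series = pd.Series(50.0 * np.exp(0.3 * (YEARS - 1993)), index=YEARS)
    fit = fit_trend(series, order="exp")
    assert fit.coefficients[1] == pytest.approx(0.3)
    assert fit.r_squared == pytest.approx(1.0)


def test_trend_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fit_trend(pd.Series([1.0, 2.0], index=[2000, 2001]), order=2)
    with pytest.raises(ValueError):
        fit_trend(pd.Series([1.0, 2.0, 3.0], index=[2000, 2000, 2000]), order=1)


def test_quadratic_coefficient_recovery():
    """On 16-point noisy series the OLS coefficients land within 3 SEs of
    the generating values in at least 95% of seeds."""
    truth = np.array([0.02, 0.005, 0.0008])
    hits = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        x = YEARS - 1993.0
        y = truth[0] + truth[1] * x + truth[2] * x**2 + rng.normal(0, 0.005, len(x))
        fit = fit_trend(pd.Series(y, index=YEARS), order=2)
        hits += bool(np.all(np.abs(fit.coefficients - truth) <= 3 * fit.bse))
    assert hits >= 0.95 * n_seeds


# -- projection --------------------------------------------------------------


def _linear_fit(slope=0.05, start=1993):
    years = np.arange(start, start + 6)
    series = pd.Series(slope * (years - start), index=years)
    return fit_trend(series, order=1)


def test_projection_arithmetic():
    fit = _linear_fit(0.05)
    assert project(fit, 1.0, last_year=1998) == 2013  # 0.05 * 20 = 1.0


def test_projection_target_already_met_returns_last_year():
    fit = _linear_fit(0.05)
    assert project(fit, 0.1, last_year=2000) == 2000


def test_projection_decreasing_trend_not_reached():
    years = np.arange(2000, 2006)
    fit = fit_trend(pd.Series(1.0 - 0.05 * (years - 2000), index=years), order=1)
    assert project(fit, 0.9, last_year=2005) is None


def test_projection_horizon():
    fit = _linear_fit(0.0001)
    assert project(fit, 1.0, last_year=1998, horizon=2050) is None


def test_projection_matches_year_scan():
    x = YEARS - 1993.0
    series = pd.Series(0.001 * x**2 + 0.01 * x, index=YEARS)
    fit = fit_trend(series, order=2)
    target = 0.6
    got = project(fit, target, last_year=2008)
    scan = next(
        y
        for y in range(2008, 2101)
        if min(float(fit.predict([y])[0]), 1.0) >= target
    )
    assert got == scan


@given(t1=st.floats(0.1, 0.9), t2=st.floats(0.1, 0.9))
@settings(max_examples=30, deadline=None)
def test_projection_monotone_in_target(t1, t2):
    fit = _linear_fit(0.02)
    lo, hi = sorted((t1, t2))
    y_lo, y_hi = project(fit, lo, 1998), project(fit, hi, 1998)
    assert y_lo is not None and y_hi is not None and y_lo <= y_hi


# -- feature regression ------------------------------------------------------


def _feature_table(rng, n=100, betas=(0.8, 0.2, 0.1, 0.1), sigma=0.05):
    X = rng.normal(size=(n, 4))
    Xz = (X - X.mean(0)) / X.std(0, ddof=1)
    y = Xz @ np.array(betas) + rng.normal(0, sigma, n)
    return pd.DataFrame(
        {
            "proportion_sampled": X[:, 0],
            "clade_size": X[:, 1],
            "characters_per_species": X[:, 2],
            "density": X[:, 3],
            "resolution_50": y,
        }
    )


def test_response_equal_to_predictor():
    rng = np.random.default_rng(1)
    table = _feature_table(rng, betas=(1.0, 0.0, 0.0, 0.0), sigma=0.0)
    res = feature_regression(table)
    assert res.params["proportion_sampled"] == pytest.approx(1.0, abs=1e-6)
    for other in ("clade_size", "characters_per_species", "density"):
        assert res.params[other] == pytest.approx(0.0, abs=1e-6)
    assert res.r_squared == pytest.approx(1.0)


def test_beta_recovery_ordering():
    """Generating betas (0.8, 0.2, 0.1, 0.1) on orthogonal standardized
    predictors are recovered within 3 SEs in >= 95% of 200 seeds.  The
    closed-form expectation for a standardized coefficient is
    beta * sd(x)/sd(y) = beta / sd(y) here, since the response is also
    z-scored.  The dominant predictor is the proportion of species
    sampled, echoing the coefficient ordering 0.8 > 0.2 > 0.1 ~ 0.1."""
    gen = np.array([0.8, 0.2, 0.1, 0.1])
    hits = 0
    n_seeds = 200
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        table = _feature_table(rng, betas=tuple(gen))
        truth = gen / table["resolution_50"].std(ddof=1)
        res = feature_regression(table)
        betas = res.params.to_numpy()
        hits += bool(np.all(np.abs(betas - truth) <= 3 * res.bse.to_numpy()))
        order = res.params.sort_values(ascending=False).index
        assert order[0] == "proportion_sampled"
        assert order[1] == "clade_size"
    assert hits >= 0.95 * n_seeds


def test_permuted_response_p_uniform():
    """Under the null (permuted response) the overall p-value is Uniform(0,1)."""
    pvals = []
    for seed in range(150):
        rng = np.random.default_rng(seed + 1000)
        table = _feature_table(rng, n=40)
        table["resolution_50"] = rng.permutation(table["resolution_50"].to_numpy())
        pvals.append(feature_regression(table).f_pvalue)
    _, p = stats.kstest(pvals, "uniform")
    assert p > 0.01


def test_collinear_predictors_named():
    rng = np.random.default_rng(2)
    table = _feature_table(rng, n=30)
    table["density"] = table["clade_size"] * 2.0
    with pytest.raises(ValueError, match="clade_size.*density|density.*clade_size"):
        feature_regression(table)


def test_too_few_clades_rejected():
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError, match="at least 6"):
        feature_regression(_feature_table(rng, n=5))


# -- gene ranking ------------------------------------------------------------


def _gene_table(n_clades=10, n_genes=25, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_clades):
        for g in range(n_genes):
            rows.append(
                {
                    "clade": f"clade{c:03d}",
                    "gene": f"L{g:02d}",
                    "n_taxa": int(rng.integers(4, 40)),
                    "resolution": float(rng.random()),
                }
            )
    return pd.DataFrame(rows)


def test_top5_is_sorted_head():
    table = _gene_table(n_clades=1)
    ranking = rank_genes(table, min_genes=20)
    df = table.sort_values(["n_taxa", "gene"], ascending=[False, True])
    assert ranking.top5_taxa["clade000"] == list(df["gene"].head(5))


def test_top5_frequency_arithmetic():
    rows = []
    for c in range(10):
        for g in range(6):
            # gene L0 leads in 8 of 10 clades
            n = 100 - g if (c < 8 or g > 0) else 1
            rows.append(
                {"clade": f"c{c}", "gene": f"L{g}", "n_taxa": n, "resolution": 0.5}
            )
    ranking = rank_genes(pd.DataFrame(rows), min_genes=6)
    assert ranking.freq_top5_taxa["L0"] == pytest.approx(0.8)


def test_underfilled_clades_excluded():
    table = _gene_table(n_clades=3, n_genes=10)
    extra = _gene_table(n_clades=1, n_genes=25, seed=5)
    extra["clade"] = "big"
    ranking = rank_genes(pd.concat([table, extra]), min_genes=20)
    assert ranking.clades == ["big"]


def test_no_qualifying_clade_warns_and_returns_empty():
    table = _gene_table(n_clades=2, n_genes=3)
    with pytest.warns(UserWarning, match="no clade qualifies"):
        ranking = rank_genes(table, min_genes=20)
    assert ranking.clades == []


def test_oversampled_locus_tops_ranking():
    """A locus with twice the sampling probability of the rest ends with
    the highest mean top-5-by-taxa frequency across synthetic worlds."""
    from phyloprogress.clustering import cluster_records, dedup_longest
    from phyloprogress.synthetic import WorldConfig, generate_world

    freq_sum: dict[str, float] = {}
    n_worlds = 5
    for seed in range(n_worlds):
        cfg = WorldConfig(
            n_clades=4,
            described_range=(10, 14),
            n_loci=3,
            locus_sampling=(0.9, 0.45, 0.45),
            misspell_rate=0,
            hybrid_rate=0,
            unsuitable_rate=0,
            seed=seed + 20,
        )
        world = generate_world(cfg)
        rows = []
        for clade in world.taxonomy.clades(rank="clade"):
            recs = [r for r in world.records if r.clade == clade]
            for cl in cluster_records(recs):
                dd = dedup_longest(cl)
                if len(dd.members) < 2:
                    continue
                locus = {world.locus_truth[r.accession] for r in dd.members}
                rows.append(
                    {
                        "clade": clade,
                        "gene": sorted(locus)[0],
                        "n_taxa": len(dd.members),
                        "resolution": 0.1 + 0.01 * len(dd.members),
                    }
                )
        ranking = rank_genes(pd.DataFrame(rows), min_genes=2)
        for g, f in ranking.freq_top5_taxa.items():
            freq_sum[g] = freq_sum.get(g, 0.0) + f
    assert max(freq_sum, key=freq_sum.get) == "L00"
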