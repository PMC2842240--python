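"""Trend fitting, projection, dataset-feature regression, gene rankings.

The statistics layer follows the statsmodels idiom: fitting functions
return small results objects carrying estimates, standard errors and a
``summary()``.  Everything is ordinary least squares: polynomial trends in
(year - first year), an exponential trend as log-linear OLS, and the
multiple regression of clade resolution on four dataset features with all
variables z-standardized so the partial coefficients are comparable
standardized betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

PREDICTORS = ("proportion_sampled", "clade_size", "characters_per_species", "density")


@dataclass
class TrendFit:
    """Polynomial (or log-linear exponential) trend in time.

    ``coefficients`` are ascending powers of (year - first_year); for the
    exponential order they are (intercept, slope) of the log-linear fit.
    ``p_improvement`` is the nested-F p-value of order 2 over order 1 and
    only set for quadratic fits.
    """

    order: int | str
    first_year: int
    coefficients: np.ndarray
    bse: np.ndarray
    r_squared: float
    rss: float
    n: int
    p_improvement: float | None = None
    _res: object = field(default=None, repr=False)

    def predict(self, years) -> np.ndarray:
        x = np.asarray(years, dtype=float) - self.first_year
        if self.order == "exp":
            return np.exp(self.coefficients[0] + self.coefficients[1] * x)
        return sum(c * x**k for k, c in enumerate(self.coefficients))

    def derivative(self, year: float) -> float:
        x = year - self.first_year
        if self.order == "exp":
            return float(self.coefficients[1] * self.predict([year])[0])
        return float(
            sum(k * c * x ** (k - 1) for k, c in enumerate(self.coefficients) if k >= 1)
        )

    def summary(self):
        return self._res.summary() if self._res is not None else repr(self)


def _poly_ols(x: np.ndarray, y: np.ndarray, order: int):
    X = np.column_stack([x**k for k in range(order + 1)])
    res = sm.OLS(y, X).fit()
    return res


def fit_trend(series, order: int | str = 2) -> TrendFit:
    """OLS trend of a year -> value series.

    ``order`` 1 (linear), 2 (quadratic; also reports the nested-F p-value
    for the gain over linear), or "exp" (log-linear on positive values).
    """
    if isinstance(series, dict):
        series = pd.Series(series)
    series = series.sort_index()
    years = np.asarray(series.index, dtype=float)
    y = np.asarray(series.values, dtype=float)
    norder = 1 if order == "exp" else int(order)
    if order not in (1, 2, "exp"):
        raise ValueError("order must be 1, 2 or 'exp'")
    if len(years) < norder + 2:
        raise ValueError("too few points for this order")
    if np.ptp(years) == 0:
        raise ValueError("degenerate series: constant year")
    x = years - years.min()
    first_year = int(years.min())

    if order == "exp":
        if (y <= 0).any():
            raise ValueError("exponential trend requires positive values")
        res = _poly_ols(x, np.log(y), 1)
        return TrendFit(
            order="exp",
            first_year=first_year,
            coefficients=np.asarray(res.params),
            bse=np.asarray(res.bse),
            r_squared=float(res.rsquared),
            rss=float(res.ssr),
            n=len(y),
            _res=res,
        )

    res = _poly_ols(x, y, int(order))
    p_improvement = None
    if order == 2:
        res1 = _poly_ols(x, y, 1)
        rss1, rss2 = float(res1.ssr), float(res.ssr)
        df2 = len(y) - 3
        if rss2 <= 1e-30:
            p_improvement = 1.0 if rss1 <= 1e-30 else 0.0
        else:
            f = (rss1 - rss2) / (rss2 / df2)
            p_improvement = float(stats.f.sf(f, 1, df2))
    return TrendFit(
        order=int(order),
        first_year=first_year,
        coefficients=np.asarray(res.params),
        bse=np.asarray(res.bse),
        r_squared=float(res.rsquared),
        rss=float(res.ssr),
        n=len(y),
        p_improvement=p_improvement,
        _res=res,
    )


def project(
    fit: TrendFit, target: float, last_year: int, horizon: int = 2100
) -> int | None:
    """First calendar year (>= last_year) at which the fitted trend,
    capped at 1.0, reaches ``target``; None when the trend is not
    increasing at ``last_year`` or the horizon passes first."""
    if fit.derivative(last_year) <= 0 and fit.predict([last_year])[0] < target:
        return None
    for year in range(last_year, horizon + 1):
        if min(float(fit.predict([year])[0]), 1.0) >= target:
            return year
    return None


@dataclass
class RegressionResult:
    """Standardized multiple regression of resolution on dataset features."""

    params: pd.Series  # standardized betas, one per predictor
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    f_pvalue: float
    n: int
    _res: object = field(default=None, repr=False)

    def summary(self):
        return self._res.summary()


def feature_regression(
    table: pd.DataFrame,
    response: str = "resolution_50",
    predictors: tuple[str, ...] = PREDICTORS,
) -> RegressionResult:
    """OLS of z-standardized resolution on four z-standardized features.

    The reported coefficients are standardized betas, so their magnitudes
    are comparable across predictors measured in different units.
    """
    if len(table) < 6:
        raise ValueError("need at least 6 clades")
    for col in (response, *predictors):
        if table[col].std(ddof=1) == 0:
            raise ValueError(f"constant column {col!r}")
    Z = (table[list(predictors)] - table[list(predictors)].mean()) / table[
        list(predictors)
    ].std(ddof=1)
    zy = (table[response] - table[response].mean()) / table[response].std(ddof=1)
    corr = Z.corr().abs()
    if np.linalg.cond(Z.to_numpy()) > 1e8:
        np.fill_diagonal(corr.values, 0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            f"collinear predictors: {predictors[i]!r} and {predictors[j]!r}"
        )
    X = sm.add_constant(Z.to_numpy())
    res = sm.OLS(zy.to_numpy(), X).fit()
    idx = list(predictors)
    return RegressionResult(
        params=pd.Series(res.params[1:], index=idx),
        bse=pd.Series(res.bse[1:], index=idx),
        pvalues=pd.Series(res.pvalues[1:], index=idx),
        r_squared=float(res.rsquared),
        f_pvalue=float(res.f_pvalue),
        n=len(table),
        _res=res,
    )


@dataclass
class GeneRanking:
    """Top-5 gene lists per clade and cross-clade top-5 frequencies."""

    clades: list[str]
    top5_taxa: dict[str, list[str]]  # clade -> genes, by taxa sampled
    top5_resolution: dict[str, list[str]]  # clade -> genes, by resolution
    freq_top5_taxa: dict[str, float]  # gene -> fraction of clades
    freq_top5_resolution: dict[str, float]
    sampling_vs_resolution: dict  # slope, r_squared, p_value of the check


def _top5(df: pd.DataFrame, col: str) -> list[str]:
    ranked = df.sort_values([col, "gene"], ascending=[False, True])
    return list(ranked["gene"].head(5))


def rank_genes(table: pd.DataFrame, min_genes: int = 20) -> GeneRanking:
    """Gene sampling/resolution rankings over heavily studied clades.

    ``table`` has one row per (clade, gene) with columns ``n_taxa`` and
    ``resolution``.  Clades with fewer than ``min_genes`` genes are
    excluded.  Also reports the regression of per-gene resolution on taxa
    sampled across all qualifying rows — the check that ranking by
    resolution is not just ranking by sampling.
    """
    counts = table.groupby("clade")["gene"].count()
    qualifying = sorted(counts[counts >= min_genes].index)
    if not qualifying:
        warnings.warn("no clade qualifies for gene ranking", stacklevel=2)
        return GeneRanking(
            clades=[],
            top5_taxa={},
            top5_resolution={},
            freq_top5_taxa={},
            freq_top5_resolution={},
            sampling_vs_resolution={},
        )
    sub = table[table["clade"].isin(qualifying)]
    top_taxa = {}
    top_res = {}
    for clade, df in sub.groupby("clade"):
        top_taxa[clade] = _top5(df, "n_taxa")
        top_res[clade] = _top5(df, "resolution")
    genes = sorted(sub["gene"].unique())
    nq = len(qualifying)
    freq_taxa = {
        g: sum(g in top_taxa[c] for c in qualifying) / nq for g in genes
    }
    freq_res = {
        g: sum(g in top_res[c] for c in qualifying) / nq for g in genes
    }
    X = sm.add_constant(sub["n_taxa"].to_numpy(dtype=float))
    res = sm.OLS(sub["resolution"].to_numpy(dtype=float), X).fit()
    check = {
        "slope": float(res.params[1]),
        "r_squared": float(res.rsquared),
        "p_value": float(res.pvalues[1]),
    }
    return GeneRanking(
        clades=qualifying,
        top5_taxa=top_taxa,
        top5_resolution=top_res,
        freq_top5_taxa=freq_taxa,
        freq_top5_resolution=freq_res,
        sampling_vs_resolution=check,
    )
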