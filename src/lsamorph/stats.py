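"""Covariate-adjusted cohort statistics.

Reproduces the analysis style of cross-sectional vessel-morphometry
studies: ANCOVA-style group comparisons and partial Spearman rank
correlations, both adjusted for age, sex and intracranial volume;
chi-square tests for categorical pairs; Bonferroni correction within
each comparison family; and an intraclass correlation coefficient for
intra-observer measurement consistency.

Missing data are handled by listwise deletion per comparison, with the
n actually used reported in every result.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import ARTERIES, RISK_FACTORS
from .types import StatResult

DEFAULT_COVARIATES = ("age", "sex", "icv")

GROUP_OUTCOMES = ("median_dm", "median_vti", "median_vl", "lsa_count")
DIAMETER_OUTCOMES = ("lsa_count", "mean_dm", "median_dm", "mean_vti",
                     "median_vti", "mean_vl", "median_vl")


def _complete_rows(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"required column(s) missing from table: {missing}")
    return table[columns].dropna()


def adjusted_group_compare(
    table: pd.DataFrame,
    outcome: str,
    group: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> StatResult:
    """ANCOVA comparison of a continuous outcome between two groups.

    The outcome is modeled on the binary group indicator plus the
    covariates (OLS); the group term's partial F statistic and p value
    are reported, together with the covariate-adjusted group-mean
    difference.
    """
    cols = [outcome, group, *covariates]
    data = _complete_rows(table, cols)
    g = data[group].to_numpy(dtype=float)
    if set(np.unique(g)) - {0.0, 1.0}:
        raise ValueError(f"group column {group!r} must be binary 0/1")
    if (g == 1).sum() < 2 or (g == 0).sum() < 2:
        raise ValueError(f"need >= 2 subjects per level of {group!r}")
    y = data[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"outcome {outcome!r} is constant after deletion")

    x_cov = data[list(covariates)].to_numpy(dtype=float) if covariates else \
        np.empty((len(data), 0))
    x_full = sm.add_constant(np.column_stack([g, x_cov]), has_constant="add")
    x_red = sm.add_constant(x_cov, has_constant="add")
    fit_full = sm.OLS(y, x_full).fit()
    fit_red = sm.OLS(y, x_red).fit()
    df_resid = fit_full.df_resid
    rss_full, rss_red = fit_full.ssr, fit_red.ssr
    if rss_full <= 0:
        f_stat, p = 0.0 if rss_red <= rss_full + 1e-12 else np.inf, np.nan
        p = 1.0 if f_stat == 0.0 else 0.0
    else:
        f_stat = (rss_red - rss_full) / (rss_full / df_resid)
        p = float(sps.f.sf(f_stat, 1, df_resid))
    return StatResult(
        comparison=f"{group} -> {outcome}",
        effect=float(fit_full.params[1]),      # adjusted mean difference
        statistic=float(f_stat),
        p_raw=float(np.clip(p, 0.0, 1.0)),
        n=len(data),
    )


def rank_correlation(
    table: pd.DataFrame,
    x: str,
    y: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> StatResult:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates.

    All variables are rank-transformed (midranks for ties), the
    covariate ranks are regressed out of both variable ranks, and the
    Pearson correlation of the residuals is reported with a t-based p
    value on n - 2 - k degrees of freedom.  With no covariates this is
    exactly the classical Spearman coefficient.
    """
    cols = [x, y, *covariates]
    data = _complete_rows(table, cols)
    if len(data) < 4:
        raise ValueError(f"need >= 4 complete rows, have {len(data)}")
    rx = sps.rankdata(data[x])
    ry = sps.rankdata(data[y])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant variable after listwise deletion")
    if covariates:
        rc = np.column_stack([sps.rankdata(data[c]) for c in covariates])
        design = sm.add_constant(rc, has_constant="add")
        rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = len(data) - 2 - len(covariates)
    if dof <= 0:
        raise ValueError("not enough rows for the requested covariates")
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) == 1.0:
        t, p = np.inf, 0.0
    else:
        t = r_clip * np.sqrt(dof / (1.0 - r_clip ** 2))
        p = float(2 * sps.t.sf(abs(t), dof))
    return StatResult(
        comparison=f"{x} ~ {y}",
        effect=r_clip,
        statistic=float(t),
        p_raw=p,
        n=len(data),
    )


def chi_square(table: pd.DataFrame, a: str, b: str,
               correction: bool = False) -> StatResult:
    """Pearson chi-square on the 2x2 table of two binaries (no Yates
    continuity correction by default)."""
    data = _complete_rows(table, [a, b])
    ct = pd.crosstab(data[a], data[b])
    if ct.shape != (2, 2) or (ct.sum(axis=0) == 0).any() or \
            (ct.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 margin for {a!r} x {b!r}")
    stat, p, _, _ = sps.chi2_contingency(ct.to_numpy(), correction=correction)
    n = int(ct.to_numpy().sum())
    phi = float(np.sign(np.linalg.det(ct.to_numpy())) * np.sqrt(stat / n))
    return StatResult(
        comparison=f"{a} x {b}",
        effect=phi,
        statistic=float(stat),
        p_raw=float(p),
        n=n,
    )


def bonferroni(pvals: list[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p replaced by min(1, p * m)."""
    pvals = list(pvals)
    if any(not 0 <= p <= 1 for p in pvals):
        raise ValueError("p values must lie in [0, 1]")
    m = len(pvals) if m is None else m
    return [min(1.0, p * m) for p in pvals]


def icc_consistency(measure1, measure2) -> float:
    """Single-rater, absolute-agreement intraclass correlation from a
    two-way (subjects x raters) layout — the ICC(A,1) of McGraw & Wong,
    appropriate for intra-observer repeat measurements."""
    m1 = np.asarray(measure1, dtype=float)
    m2 = np.asarray(measure2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ValueError("measurements must be 1D arrays of equal length")
    n = len(m1)
    if n < 3:
        raise ValueError("need >= 3 paired measurements")
    data = np.column_stack([m1, m2])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(icc)


def run_full_analysis(
    table: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> list[StatResult]:
    """The full comparison grid.

    Family ``risk_factors``: every binary risk factor against median DM,
    median VTI, median VL and vessel count via ANCOVA.  Family
    ``diameters``: every artery diameter against count and mean/median
    DM, VTI, VL via partial Spearman.  Bonferroni correction is applied
    within each family and the family label travels with each result.
    """
    from dataclasses import replace

    results: list[StatResult] = []
    risk_block = [
        replace(adjusted_group_compare(table, outcome, factor, covariates),
                family="risk_factors")
        for factor in RISK_FACTORS for outcome in GROUP_OUTCOMES
    ]
    diam_block = [
        replace(rank_correlation(table, f"{artery}_diameter_mm", outcome,
                                 covariates),
                family="diameters")
        for artery in ARTERIES for outcome in DIAMETER_OUTCOMES
    ]
    for block in (risk_block, diam_block):
        adj = bonferroni([r.p_raw for r in block])
        results.extend(replace(r, p_adjusted=p) for r, p in zip(block, adj))
    return results


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    """Tabulate results for CSV export."""
    return pd.DataFrame([
        {"comparison": r.comparison, "effect": r.effect,
         "statistic": r.statistic, "p_raw": r.p_raw,
         "p_adjusted": r.p_adjusted, "n": r.n, "family": r.family}
        for r in results
    ])
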