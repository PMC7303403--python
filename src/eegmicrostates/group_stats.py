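"""Covariate-adjusted group comparison of microstate features.

Features (durations, occurrences, coverages and transition percentages) are
log-transformed, compared across diagnostic groups with an ANCOVA adjusting
for age, sex, education and five medication flags, and corrected with
Benjamini-Hochberg FDR over a fixed battery of 24 comparisons per frequency
band (12 map features + 12 transitions).  Post hoc pairwise GLM contrasts run
only where the omnibus test survives FDR.  Partial correlations relate
microstate features to cognitive scores under the same covariates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
from statsmodels.formula.api import ols

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COVARIATES", "log_features", "ancova", "fdr_bh",
    "posthoc_pair", "partial_correlation", "run_battery",
]

DEFAULT_COVARIATES = ("age", "sex", "education_years", "med_antipsychotic",
                      "med_antidepressant", "med_hypnotic", "med_antidementia",
                      "med_painkiller")


def log_features(table: pd.DataFrame, feature_cols) -> pd.DataFrame:
    """Natural-log transform of the feature columns.

    Exact zeros (possible for transition percentages in short recordings) are
    offset by half the smallest positive observed value of that feature and
    flagged in the log; negative values are an error.
    """
    out = table.copy()
    for col in feature_cols:
        values = out[col].to_numpy(dtype=float)
        if np.nanmin(values) < 0:
            raise ValueError(f"feature {col!r} has negative values; cannot log")
        zeros = values == 0
        if zeros.any():
            positive = values[values > 0]
            if positive.size == 0:
                raise ValueError(f"feature {col!r} is identically zero")
            offset = positive.min() / 2.0
            values = np.where(zeros, offset, values)
            logger.warning("feature %s: %d zero(s) offset by %.3g before log",
                           col, int(zeros.sum()), offset)
        out[col] = np.log(values)
    return out


def _design_frame(feature, group, covariates) -> pd.DataFrame:
    df = pd.DataFrame({"feature": np.asarray(feature, dtype=float),
                       "group": np.asarray(group)})
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    df = pd.concat([df.reset_index(drop=True), cov], axis=1)
    df = df.dropna()  # complete-case analysis
    # zero-variance covariates carry no information and break the fit
    keep = [c for c in cov.columns if df[c].nunique() > 1]
    dropped = [c for c in cov.columns if c not in keep]
    if dropped:
        logger.info("dropping zero-variance covariates: %s", dropped)
    return df[["feature", "group", *keep]], keep


def ancova(feature, group, covariates=None) -> tuple[float, tuple[int, int], float]:
    """One-way ANCOVA: F-test of the group factor, Type II sums of squares.

    Returns ``(F, (df_num, df_den), p)`` for the model
    ``feature ~ group + covariates`` on complete cases.
    """
    if covariates is None:
        covariates = pd.DataFrame(index=range(len(feature)))
    df, cov_cols = _design_frame(feature, group, covariates)
    n_groups = df["group"].nunique()
    n_params = n_groups + len(cov_cols)
    if len(df) <= n_params:
        raise ValueError("not enough complete cases for the model")
    terms = " + ".join(["C(group)", *cov_cols]) if cov_cols else "C(group)"
    model = ols(f"feature ~ {terms}", data=df).fit()
    if model.df_resid <= 0 or np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design; check columns {cov_cols}")
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(group)"]
    df_num = int(row["df"])
    df_den = int(table.loc["Residual", "df"])
    return float(row["F"]), (df_num, df_den), float(row["PR(>F)"])


def fdr_bh(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for a battery of ``m`` tests.

    ``m`` may exceed ``len(pvalues)`` when only part of a declared battery is
    supplied; adjusted values are monotone in raw-p order and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError("battery size m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def posthoc_pair(feature, group, pair, covariates=None
                 ) -> tuple[float, int, float]:
    """GLM contrast between two groups with the same covariates.

    Returns ``(t, df, p)`` for the group coefficient of the model restricted
    to the two groups of ``pair``.
    """
    group = np.asarray(group)
    mask = np.isin(group, list(pair))
    if covariates is None:
        covariates = pd.DataFrame(index=range(len(feature)))
    cov = pd.DataFrame(covariates).reset_index(drop=True).loc[mask]
    df, cov_cols = _design_frame(np.asarray(feature, dtype=float)[mask],
                                 group[mask], cov)
    for g in pair:
        if (df["group"] == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 complete cases")
    terms = " + ".join(["C(group)", *cov_cols]) if cov_cols else "C(group)"
    model = ols(f"feature ~ {terms}", data=df).fit()
    coef_name = next(name for name in model.params.index
                     if name.startswith("C(group)"))
    return (float(model.tvalues[coef_name]), int(model.df_resid),
            float(model.pvalues[coef_name]))


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Correlation of x and y after regressing out the covariates.

    Residualizes both variables on an intercept plus the covariates, then
    Pearson-correlates the residuals; the p-value uses the t-distribution
    with ``n - 2 - n_covariates`` degrees of freedom.  Complete cases only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "shape") and
                              np.size(covariates) == 0):
        z = np.empty((len(x), 0))
    else:
        z = np.atleast_2d(np.asarray(pd.DataFrame(covariates), dtype=float))
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(z), axis=1)
    x, y, z = x[mask], y[mask], z[mask]
    n, k = len(x), z.shape[1]
    if n <= k + 2:
        raise ValueError("too few complete cases for partial correlation")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho_c * np.sqrt(dof / (1 - rho_c ** 2))
    p = float(2 * sstats.t.sf(abs(t), dof))
    return rho, p


def run_battery(table: pd.DataFrame, feature_cols, group_col: str = "group",
                covariate_cols=DEFAULT_COVARIATES, battery_size: int = 24,
                alpha: float = 0.05) -> pd.DataFrame:
    """ANCOVA + BH-FDR over one band's feature battery, post hocs gated.

    The battery is corrected as one family of ``battery_size`` comparisons
    (asserted against the number of features supplied); pairwise post hoc
    contrasts are computed only for features with ``p_fdr < alpha``.
    """
    feature_cols = list(feature_cols)
    if len(feature_cols) != battery_size:
        raise ValueError(f"battery has {len(feature_cols)} features but "
                         f"battery_size={battery_size}")
    logged = log_features(table, feature_cols)
    cov = logged[list(covariate_cols)] if covariate_cols else None
    rows = []
    for col in feature_cols:
        f, (dfn, dfd), p = ancova(logged[col], logged[group_col], cov)
        rows.append({"feature": col, "F": f, "df_num": dfn, "df_den": dfd,
                     "p": p})
    result = pd.DataFrame(rows)
    result["p_fdr"] = fdr_bh(result["p"].to_numpy(), m=battery_size)
    groups = sorted(logged[group_col].unique())
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    for a, b in pairs:
        result[f"t_{a}_vs_{b}"] = np.nan
        result[f"p_{a}_vs_{b}"] = np.nan
    for i, col in enumerate(feature_cols):
        if result.loc[i, "p_fdr"] >= alpha:
            continue
        for a, b in pairs:
            t, _, p = posthoc_pair(logged[col], logged[group_col], (a, b), cov)
            result.loc[i, f"t_{a}_vs_{b}"] = t
            result.loc[i, f"p_{a}_vs_{b}"] = p
    return result
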