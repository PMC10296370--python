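"""Per-species logistic association of disease class with lipid abundance.

For every lipid species a maximum-likelihood logistic regression of the
binary class (sCAD+ vs sCAD-) on the log concentration is fitted, both
unadjusted and adjusted for BMI, hypertension, current smoking, diabetes,
and hypercholesterolemia. Effects are reported as odds ratios per unit
log-concentration with 95% Wald intervals, and discoveries are controlled
at a Benjamini-Hochberg false discovery rate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import ConfigurationError, DataError

__all__ = [
    "ADJUSTMENT_COVARIATES",
    "fit_lipid_associations",
    "bh_adjust",
    "export_forest_data",
]

#: clinical covariates of the adjusted model
ADJUSTMENT_COVARIATES = [
    "bmi", "hypertension", "current_smoking", "diabetes", "hypercholesterolemia",
]

_Z95 = 1.959963984540054  # Phi^-1(0.975)


def _fit_one(y: np.ndarray, design: np.ndarray) -> tuple[float, float, float] | None:
    """(beta, se, p) for the first non-intercept column, or None when the
    fit is degenerate (perfect separation / non-convergence)."""
    X = sm.add_constant(design, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    beta = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or se > 1e3:
        return None
    return beta, se, float(res.pvalues[1])


def fit_lipid_associations(
    X: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit the per-species logistic models.

    ``labels`` maps sample_id to sCAD_minus / sCAD_plus (other labels are
    dropped). When ``covariates`` is given, an adjusted variant is fitted
    per species and both variants appear in the output. Species with a
    degenerate fit are flagged (``flag = 'degenerate'``, missing p) and
    excluded from the FDR adjustment.
    """
    lab = labels.reindex(X.index)
    keep = lab.isin(["sCAD_minus", "sCAD_plus"]).to_numpy()
    if keep.sum() == 0:
        raise DataError("no analytical samples among the matrix rows")
    y = (lab[keep] == "sCAD_plus").to_numpy(float)
    if y.min() == y.max():
        raise DataError("both classes must be present")
    Xk = X.loc[keep]
    const = Xk.columns[Xk.nunique() <= 1]
    if len(const):
        raise DataError(f"constant species present: {list(const)[:5]}")

    cov = None
    if covariates is not None:
        cov = covariates.reindex(Xk.index).astype(float).to_numpy()
        if np.isnan(cov).any():
            raise DataError("missing covariate values among analytical samples")

    records = []
    for sp in Xk.columns:
        x = Xk[sp].to_numpy(float)
        variants = [("univariate", x[:, None])]
        if cov is not None:
            variants.append(("adjusted", np.column_stack([x, cov])))
        for name, design in variants:
            fit = _fit_one(y, design)
            if fit is None:
                records.append(
                    {
                        "species": sp, "model": name, "odds_ratio": np.nan,
                        "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                        "flag": "degenerate",
                    }
                )
            else:
                beta, se, p = fit
                records.append(
                    {
                        "species": sp, "model": name,
                        "odds_ratio": float(np.exp(beta)),
                        "ci_low": float(np.exp(beta - _Z95 * se)),
                        "ci_high": float(np.exp(beta + _Z95 * se)),
                        "p": p, "flag": "",
                    }
                )
    table = pd.DataFrame.from_records(records)
    table["p_adj"] = np.nan
    for name in table["model"].unique():
        mask = (table["model"] == name) & table["p"].notna()
        table.loc[mask, "p_adj"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    return table


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN entries pass through
    and do not count toward the number of tests."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def export_forest_data(table: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Forest-plot table: species whose adjusted-model BH-adjusted p is below
    ``fdr``, sorted ascending by it, with both model variants' OR/CI kept
    wide and significance stars from the adjusted p-values."""
    adj = table[table["model"] == "adjusted"]
    if adj.empty:
        raise DataError("no adjusted-model records; fit with covariates first")
    hits = adj[adj["p_adj"] < fdr].sort_values("p_adj", kind="stable")
    uni = table[table["model"] == "univariate"].set_index("species")

    def stars(p: float) -> str:
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return ""

    rows = []
    for _, rec in hits.iterrows():
        sp = rec["species"]
        row = {
            "species": sp,
            "adjusted_or": rec["odds_ratio"],
            "adjusted_ci_low": rec["ci_low"],
            "adjusted_ci_high": rec["ci_high"],
            "adjusted_p_adj": rec["p_adj"],
            "significance": stars(rec["p_adj"]),
        }
        if sp in uni.index:
            u = uni.loc[sp]
            row.update(
                univariate_or=u["odds_ratio"],
                univariate_ci_low=u["ci_low"],
                univariate_ci_high=u["ci_high"],
                univariate_p_adj=u["p_adj"],
            )
        rows.append(row)
    return pd.DataFrame(rows)
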