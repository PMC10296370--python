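"""Per-sample classifiability from repeated stratified cross-validation,
the modifying-covariate scan, and sub-cohort stratification.

The individual classifiability score (ICS) of a sample is the fraction of
cross-validation repeats in which the sample is predicted correctly: per
repeat a stratified f-fold partition is drawn, a ridge-logistic model is
fitted on the training folds, and each sample is predicted exactly once as
a held-out case. Samples that sit in a region of feature space where the
lipidome-class relationship is strong classify consistently (ICS near 1);
samples where it is weak hover near chance. Regressing ICS on candidate
clinical covariates (adjusted for age and sex) then points at the variable
that modifies the lipidome-disease association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold

from .errors import AnalysisError, ConfigurationError, DataError
from .risk import _as_binary, _fit_penalized, _youden_threshold

__all__ = [
    "ICSResult",
    "ModifierScan",
    "compute_ics",
    "find_modifying_variable",
    "stratify_cohort",
]


@dataclass
class ICSResult:
    scores: pd.Series  # per-sample classifiability in [0, 1]
    n_repeats: int
    n_folds: int
    model_spec: dict


@dataclass
class ModifierScan:
    table: pd.DataFrame  # candidate, slope, p
    winner: str


def compute_ics(
    X_disc: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    penalty: float = 1.0,
    features: list[str] | None = None,
    r: int = 50,
    f: int = 5,
    seed: int = 0,
    threshold: str = "youden",
) -> ICSResult:
    """Individual classifiability scores from ``r``-repeated stratified
    ``f``-fold cross-validation of a ridge-logistic model.

    Rows are put into a canonical order (sorted by sample id) before fold
    assignment, so the scores do not depend on input row order. Inside each
    repeat the binary cutoff is either the Youden-optimal threshold of the
    training folds (default) or a fixed probability 0.5 (``threshold="half"``).
    """
    if threshold not in ("youden", "half"):
        raise ConfigurationError("threshold must be 'youden' or 'half'")
    if features is not None:
        missing = [c for c in features if c not in X_disc.columns]
        if missing:
            raise DataError(f"requested features absent: {missing[:5]}")
        X_disc = X_disc[features]
    X_disc = X_disc.sort_index(kind="stable")
    y = _as_binary(labels, X_disc.index)
    if y.min() == y.max():
        raise DataError("both classes required")
    n = len(y)
    if min(int(y.sum()), int(n - y.sum())) < f:
        raise DataError(f"each class needs at least {f} members for {f}-fold CV")

    Xmat = X_disc.to_numpy(float)
    correct = np.zeros(n)
    for rep in range(r):
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=f, shuffle=True, random_state=seed + 131 * rep + attempt)
            folds = list(skf.split(Xmat, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
                break
        else:
            raise AnalysisError("could not draw folds with both classes in training")
        for train, test in folds:
            mu = Xmat[train].mean(axis=0)
            sd = Xmat[train].std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xtr = (Xmat[train] - mu) / sd
            b0, b = _fit_penalized(Xtr, y[train], penalty)
            p_tr = 1.0 / (1.0 + np.exp(-(b0 + Xtr @ b)))
            cut = _youden_threshold(p_tr, y[train]) if threshold == "youden" else 0.5
            p_te = 1.0 / (1.0 + np.exp(-(b0 + ((Xmat[test] - mu) / sd) @ b)))
            correct[test] += ((p_te >= cut).astype(float) == y[test]).astype(float)

    scores = pd.Series(correct / r, index=X_disc.index, name="ics")
    return ICSResult(
        scores=scores,
        n_repeats=r,
        n_folds=f,
        model_spec={"penalty": penalty, "n_features": X_disc.shape[1], "threshold": threshold},
    )


def find_modifying_variable(
    ics: ICSResult | pd.Series,
    clinical: pd.DataFrame,
    candidates: tuple[str, ...] = ("bmi", "hypertension", "hypercholesterolemia"),
) -> ModifierScan:
    """One linear model per candidate: ``ics ~ candidate + age + sex``.

    The winner is the candidate with the smallest p-value on its own
    coefficient. Constant candidates are skipped with a warning.
    """
    scores = ics.scores if isinstance(ics, ICSResult) else ics
    meta = clinical.set_index("sample_id").reindex(scores.index)
    if meta["age"].isna().any() or meta["sex"].isna().any():
        raise DataError("age/sex missing for some scored samples")
    age = meta["age"].to_numpy(float)
    female = (meta["sex"] == "F").to_numpy(float)

    rows = []
    for cand in candidates:
        if cand not in meta.columns:
            raise DataError(f"candidate {cand!r} absent from clinical table")
        x = meta[cand].astype(float).to_numpy()
        if np.nanstd(x) == 0:
            warnings.warn(f"candidate {cand!r} is constant; skipped", stacklevel=2)
            continue
        design = sm.add_constant(np.column_stack([x, age, female]))
        res = sm.OLS(scores.to_numpy(float), design).fit()
        rows.append({"candidate": cand, "slope": float(res.params[1]), "p": float(res.pvalues[1])})
    if not rows:
        raise AnalysisError("no usable candidate covariates")
    table = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    return ModifierScan(table=table, winner=table.iloc[0]["candidate"])


def stratify_cohort(
    clinical: pd.DataFrame,
    ids: list | None = None,
    variable: str = "bmi",
    cutoff: float = 25.0,
) -> tuple[list, list]:
    """Split samples into (below-cutoff, at-or-above-cutoff) id lists on a
    numeric clinical variable; samples with missing values are dropped with
    a warning. The boundary value goes to the high group."""
    meta = clinical.set_index("sample_id")
    if ids is not None:
        meta = meta.loc[[i for i in ids if i in meta.index]]
    vals = pd.to_numeric(meta[variable], errors="coerce")
    if vals.isna().any():
        dropped = list(vals[vals.isna()].index)
        warnings.warn(
            f"{len(dropped)} samples missing {variable!r} excluded from stratification",
            stacklevel=2,
        )
    low = list(vals[vals < cutoff].index)
    high = list(vals[vals >= cutoff].index)
    return low, high
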