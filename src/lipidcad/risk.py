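"""Risk models: the Framingham general cardiovascular risk function, an
L2-penalized logistic lipid risk score (LRS) with bootstrap hyperparameter
and feature selection, and the combined lipids + FRS model.

The Framingham 10-year general-CVD risk is the sex-specific Cox-model
approximation ``risk = 1 - S0(10) ^ exp(sum(beta_j x_j) - mean)`` with the
published coefficients on log age, log total and HDL cholesterol (mg/dL),
log systolic blood pressure (separately for treated and untreated),
current smoking, and diabetes.

The LRS is a ridge-penalized logistic regression maximizing
``l(beta) - penalty * ||beta_-0||^2 / 2`` (intercept unpenalized) over the
selected top lipid species, standardized on the training data. Feature
informativity is the mean absolute standardized ridge coefficient across
bootstrap resamples; the (penalty, n_features) pair is chosen to maximize
mean out-of-bag AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .errors import AnalysisError, ConfigurationError, DataError

__all__ = [
    "FRS_COEFFICIENTS",
    "RiskModel",
    "FeatureSelection",
    "framingham_risk",
    "select_lrs_features",
    "fit_ridge_logistic",
    "fit_frs_model",
    "fit_combined",
    "predict_risk",
]

MMOL_TO_MGDL = 38.67  # cholesterol unit conversion

#: D'Agostino 2008 general-CVD function, sex-specific (version 2008-general).
FRS_COEFFICIENTS = {
    "version": "general-cvd-2008",
    "M": {
        "log_age": 3.06117,
        "log_tc": 1.12370,
        "log_hdl": -0.93263,
        "log_sbp_untreated": 1.93303,
        "log_sbp_treated": 1.99881,
        "smoker": 0.65451,
        "diabetes": 0.57367,
        "mean_terms": 23.9802,
        "baseline_survival": 0.88936,
    },
    "F": {
        "log_age": 2.32888,
        "log_tc": 1.20904,
        "log_hdl": -0.70833,
        "log_sbp_untreated": 2.76157,
        "log_sbp_treated": 2.82263,
        "smoker": 0.52873,
        "diabetes": 0.69154,
        "mean_terms": 26.1931,
        "baseline_survival": 0.95012,
    },
}

_FRS_REQUIRED = ["age", "sex", "sbp", "tc", "hdl", "current_smoking", "diabetes"]


def framingham_risk(clinical: pd.DataFrame | pd.Series) -> pd.Series | float:
    """Sex-specific 10-year general cardiovascular risk in (0, 1).

    Total and HDL cholesterol are expected in mmol/L and converted
    internally. Blood-pressure treatment is read from a ``bp_treated``
    column when present, else from the ``hypertension`` flag. Ages outside
    the 30-74 y range of the underlying equation are clamped with a warning.
    """
    single = isinstance(clinical, pd.Series)
    frame = clinical.to_frame().T if single else clinical
    for col in _FRS_REQUIRED:
        if col not in frame.columns or frame[col].isna().any():
            raise DataError(f"framingham_risk requires complete covariate {col!r}")
    treated_col = "bp_treated" if "bp_treated" in frame.columns else "hypertension"

    age = frame["age"].to_numpy(float)
    if ((age < 30) | (age > 74)).any():
        warnings.warn("ages outside 30-74 clamped to the equation's range", stacklevel=2)
        age = np.clip(age, 30.0, 74.0)
    tc = frame["tc"].to_numpy(float) * MMOL_TO_MGDL
    hdl = frame["hdl"].to_numpy(float) * MMOL_TO_MGDL
    sbp = frame["sbp"].to_numpy(float)
    treated = frame[treated_col].astype(bool).to_numpy()
    smoker = frame["current_smoking"].astype(bool).to_numpy(float)
    diab = frame["diabetes"].astype(bool).to_numpy(float)

    risk = np.empty(len(frame))
    for sex in ("M", "F"):
        c = FRS_COEFFICIENTS[sex]
        sel = (frame["sex"] == sex).to_numpy()
        if not sel.any():
            continue
        lp = (
            c["log_age"] * np.log(age[sel])
            + c["log_tc"] * np.log(tc[sel])
            + c["log_hdl"] * np.log(hdl[sel])
            + np.where(treated[sel], c["log_sbp_treated"], c["log_sbp_untreated"])
            * np.log(sbp[sel])
            + c["smoker"] * smoker[sel]
            + c["diabetes"] * diab[sel]
        )
        risk[sel] = 1.0 - c["baseline_survival"] ** np.exp(lp - c["mean_terms"])
    if not ((frame["sex"] == "M") | (frame["sex"] == "F")).all():
        raise DataError("sex must be 'M' or 'F'")
    out = pd.Series(risk, index=frame.index, name="frs")
    return float(out.iloc[0]) if single else out


@dataclass
class RiskModel:
    """A fitted logistic risk score with its standardization and threshold."""

    kind: str  # FRS | LRS | FRS_plus_LRS
    feature_names: list[str]
    intercept: float
    coefficients: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    l2_penalty: float
    threshold: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.feature_names):
            raise ConfigurationError("one coefficient per feature required")
        if self.l2_penalty < 0:
            raise ConfigurationError("l2_penalty must be >= 0")
        if self.l2_penalty == 0 and self.kind != "FRS":
            raise ConfigurationError("zero penalty is only allowed for the FRS model")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "intercept": self.intercept,
            "coefficients": np.asarray(self.coefficients).tolist(),
            "feature_means": np.asarray(self.feature_means).tolist(),
            "feature_sds": np.asarray(self.feature_sds).tolist(),
            "l2_penalty": self.l2_penalty,
            "threshold": self.threshold,
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(
            kind=d["kind"],
            feature_names=d["feature_names"],
            intercept=d["intercept"],
            coefficients=np.asarray(d["coefficients"], dtype=float),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            l2_penalty=d["l2_penalty"],
            threshold=d["threshold"],
            training_meta=d["training_meta"],
        )


@dataclass
class FeatureSelection:
    """Result of the bootstrap hyperparameter / feature search."""

    ranking: list[str]  # species, most informative first
    chosen_n: int
    chosen_penalty: float
    auc_grid: pd.DataFrame  # columns penalty, n_features, mean_auc
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.chosen_n > len(self.ranking):
            raise ConfigurationError("chosen_n exceeds the ranked feature list")


def _as_binary(labels: pd.Series | np.ndarray, index=None) -> np.ndarray:
    if isinstance(labels, pd.Series) and index is not None:
        labels = labels.reindex(index)
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        return (arr == "sCAD_plus").astype(float)
    return arr.astype(float)


def _youden_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Score cutoff maximizing sensitivity + specificity - 1 on (scores, y)."""
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    n_pos, n_neg = yy.sum(), (1 - yy).sum()
    tps = np.cumsum(yy)
    fps = np.cumsum(1 - yy)
    # evaluate at the end of each tie block
    block_end = np.flatnonzero(np.diff(s, append=-np.inf) != 0)
    j = tps[block_end] / n_pos - fps[block_end] / n_neg
    best = block_end[int(np.argmax(j))]
    return float(s[best])


def _fit_penalized(
    Xs: np.ndarray, y: np.ndarray, penalty: float, tol: float = 1e-6
) -> tuple[float, np.ndarray]:
    """Fit the penalized logistic on standardized features; returns
    (intercept, coefficients)."""
    if penalty < 0:
        raise ConfigurationError("penalty must be >= 0")
    if penalty == 0:
        clf = LogisticRegression(penalty=None, solver="lbfgs", tol=tol, max_iter=2000)
    else:
        clf = LogisticRegression(
            penalty="l2", C=1.0 / penalty, solver="lbfgs", tol=tol, max_iter=2000
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xs, y)
    n_iter = int(np.max(clf.n_iter_))
    if n_iter >= 2000:
        raise AnalysisError(
            f"ridge-logistic failed to converge within 2000 iterations "
            f"(penalty={penalty}); last iteration count {n_iter}"
        )
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def _threshold_scores(
    Xs: np.ndarray, y: np.ndarray, penalty: float, intercept: float, coef: np.ndarray
) -> np.ndarray:
    """Training scores used to place the Youden threshold.

    With many features the in-sample probabilities are optimistic and a
    cutoff placed among them misses held-out cases, so for wide problems
    the threshold is placed on out-of-fold predictions (deterministic
    5-fold split of the training data). Low-dimensional fits use the
    in-sample scores directly.
    """
    from sklearn.model_selection import StratifiedKFold

    n, p = Xs.shape
    if p < 10 or n < 50 or min(y.sum(), n - y.sum()) < 10:
        return 1.0 / (1.0 + np.exp(-(intercept + Xs @ coef)))
    oof = np.empty(n)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
    for train, test in skf.split(Xs, y):
        b0, b = _fit_penalized(Xs[train], y[train], penalty)
        oof[test] = 1.0 / (1.0 + np.exp(-(b0 + Xs[test] @ b)))
    return oof


def fit_ridge_logistic(
    X: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    penalty: float,
    kind: str = "LRS",
    training_meta: dict | None = None,
) -> RiskModel:
    """Fit an L2-penalized logistic risk model.

    Features are standardized to mean 0 / SD 1 on the training data and the
    transform is stored in the model. The binary-call threshold is the
    Youden-optimal cutoff of the training risk scores (out-of-fold scores
    for wide problems; see :func:`_threshold_scores`).
    """
    y = _as_binary(labels, X.index)
    if y.min() == y.max():
        raise DataError("both classes required for model fitting")
    means = X.to_numpy(float).mean(axis=0)
    sds = X.to_numpy(float).std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Xs = (X.to_numpy(float) - means) / sds
    intercept, coef = _fit_penalized(Xs, y, penalty)
    scores = _threshold_scores(Xs, y, penalty, intercept, coef)
    model = RiskModel(
        kind=kind,
        feature_names=list(X.columns),
        intercept=intercept,
        coefficients=coef,
        feature_means=means,
        feature_sds=sds,
        l2_penalty=penalty,
        threshold=_youden_threshold(scores, y),
        training_meta=training_meta or {},
    )
    return model


def fit_frs_model(frs_values: pd.Series, labels: pd.Series | np.ndarray) -> RiskModel:
    """One-covariate unpenalized logistic regression of class on FRS."""
    X = frs_values.to_frame("frs")
    return fit_ridge_logistic(X, labels, penalty=0.0, kind="FRS")


def fit_combined(
    X_top: pd.DataFrame,
    frs_values: pd.Series,
    labels: pd.Series | np.ndarray,
    penalty: float,
) -> RiskModel:
    """Ridge over the selected lipid species plus FRS as one extra predictor."""
    X = X_top.copy()
    X["frs"] = frs_values.reindex(X.index)
    if X["frs"].isna().any():
        raise DataError("FRS missing for some samples in the combined fit")
    return fit_ridge_logistic(X, labels, penalty, kind="FRS_plus_LRS")


def _oob_auc(scores: np.ndarray, y: np.ndarray) -> float:
    from .evaluation import _auc_mann_whitney

    return _auc_mann_whitney(scores, y)


def select_lrs_features(
    X_disc: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    grid: list[tuple[float, int]] | None = None,
    n_boot: int = 100,
    seed: int = 0,
    ranking_penalty: float | None = None,
    discovery_ids: set | None = None,
) -> FeatureSelection:
    """Bootstrap selection of the ridge penalty and the number of top species.

    Per bootstrap resample: an all-species ridge fit on the in-bag samples
    contributes |standardized coefficient| to the informativity ranking, and
    every (penalty, n_features) grid point is scored by the out-of-bag AUC of
    a ridge fit on the in-bag top-n species. The grid point with the highest
    mean out-of-bag AUC wins.

    ``discovery_ids``, when given, guards against information leakage: any
    sample outside it raises.
    """
    if discovery_ids is not None:
        outside = [i for i in X_disc.index if i not in discovery_ids]
        if outside:
            raise DataError(
                f"feature selection must only see discovery samples; got {outside[:5]}"
            )
    y = _as_binary(labels, X_disc.index)
    if y.min() == y.max():
        raise DataError("both classes required for feature selection")
    p = X_disc.shape[1]
    if grid is None:
        penalties = [0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]
        sizes = [s for s in (50, 100, 200) if s <= p] or [p]
        grid = [(pen, s) for pen in penalties for s in sizes]
    for pen, s in grid:
        if pen <= 0 or s < 1 or s > p:
            raise ConfigurationError(f"invalid grid point (penalty={pen}, n={s})")
    if ranking_penalty is None:
        # median grid penalty: the all-species ranking fit should be
        # regularized at the same order of magnitude as the models it ranks for
        ranking_penalty = float(np.median(sorted({g[0] for g in grid})))

    rng = np.random.default_rng(seed)
    n = len(X_disc)
    means = X_disc.to_numpy(float).mean(axis=0)
    sds = X_disc.to_numpy(float).std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Xs = (X_disc.to_numpy(float) - means) / sds

    importance = np.zeros(p)
    grid_aucs = {g: [] for g in grid}
    for _ in range(n_boot):
        in_bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if oob.size == 0 or len(np.unique(y[in_bag])) < 2 or len(np.unique(y[oob])) < 2:
            if oob.size == 0:
                raise AnalysisError("empty out-of-bag set; cohort too small to bootstrap")
            continue  # single-class resample: skip, cannot be scored
        _, coef = _fit_penalized(Xs[in_bag], y[in_bag], ranking_penalty)
        importance += np.abs(coef)
        order = np.argsort(-np.abs(coef), kind="stable")
        for pen, size in grid:
            top = order[:size]
            b0, b = _fit_penalized(Xs[in_bag][:, top], y[in_bag], pen)
            scores = Xs[oob][:, top] @ b + b0
            grid_aucs[(pen, size)].append(_oob_auc(scores, y[oob]))

    scored = {g: np.mean(v) for g, v in grid_aucs.items() if v}
    if not scored:
        raise AnalysisError("no bootstrap resample contained both classes out-of-bag")
    best = max(scored, key=lambda g: (scored[g], -g[0], g[1]))
    ranking_idx = np.argsort(-importance, kind="stable")
    auc_grid = pd.DataFrame(
        [(pen, size, scored.get((pen, size), np.nan)) for pen, size in grid],
        columns=["penalty", "n_features", "mean_auc"],
    )
    return FeatureSelection(
        ranking=[X_disc.columns[i] for i in ranking_idx],
        chosen_n=best[1],
        chosen_penalty=best[0],
        auc_grid=auc_grid,
        n_boot=n_boot,
        seed=seed,
    )


def predict_risk(
    model: RiskModel, X: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Per-sample risk probability and binary call (risk >= threshold)."""
    missing = [f for f in model.feature_names if f not in X.columns]
    if missing:
        raise DataError(f"missing model features: {missing[:10]}")
    Z = X[model.feature_names].to_numpy(float)
    Zs = (Z - model.feature_means) / model.feature_sds
    eta = model.intercept + Zs @ model.coefficients
    risk = pd.Series(1.0 / (1.0 + np.exp(-eta)), index=X.index, name="risk")
    call = pd.Series(risk.to_numpy() >= model.threshold, index=X.index, name="call")
    return risk, call
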