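"""Batch-effect diagnosis and removal with RUV-III and pseudo-replicates.

RUV-III estimates hidden (unwanted) factors from replicate samples and
negative-control features. True replicates are rare in a cohort study, so
clinically homogeneous groups of participants — built by Ward agglomerative
clustering on age, sex, BMI, and the binary risk factors — are treated as
pseudo-replicates, with each QC sample type (pooled QC, technical QC, blank,
NIST 1950 reference plasma) forming one further replicate group.

With column-centered data Y (n x p), replicate membership matrix M
(n x m), control-feature set c, and k factors, the estimator is:

1. ``Y0 = (I - M (M'M)^-1 M') Y``  — residual after removing group means;
2. ``U`` = top-k left singular vectors of ``Y0``;
3. ``alpha = U' Y``  (k x p) — feature coefficients of the hidden factors;
4. ``W = Y_c alpha_c' (alpha_c alpha_c')^-1``  (n x k) — sample scores,
   estimated from the control features only;
5. ``Y_adjusted = Y - W alpha + column means``.

A fitted model (alpha, controls, k, feature means) can be transferred to a
new cohort: the new matrix is centered on its own column means, W is
re-estimated from its control features with the stored alpha, and the
product is subtracted before the new cohort's means are restored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ConfigurationError, DataError

__all__ = [
    "ReplicateStructure",
    "RuvModel",
    "pca_diagnostics",
    "make_pseudo_replicates",
    "select_control_features",
    "ruv3_fit",
    "ruv3_transfer",
]

_CLUSTER_CONTINUOUS = ["age", "bmi"]
_CLUSTER_BINARY = [
    "hypertension", "current_smoking", "diabetes", "hypercholesterolemia",
]


@dataclass
class ReplicateStructure:
    """Sample-to-replicate-group assignment.

    ``membership`` is the n x m indicator matrix M (each row sums to one);
    ``sample_ids`` gives the row order; ``group_names`` the column order.
    """

    membership: np.ndarray
    sample_ids: list[str]
    group_names: list[str]

    def __post_init__(self) -> None:
        M = np.asarray(self.membership)
        if not np.array_equal(M.sum(axis=1), np.ones(M.shape[0])):
            raise DataError("every sample must belong to exactly one replicate group")
        if (M.sum(axis=0) == 0).any():
            empty = [g for g, s in zip(self.group_names, M.sum(axis=0)) if s == 0]
            raise DataError(f"empty replicate groups: {empty}")


@dataclass
class RuvModel:
    """Frozen RUV-III fit: everything needed to adjust a new cohort."""

    alpha: np.ndarray  # k x p
    k: int
    controls: np.ndarray  # column indices into the species list
    species: list[str]
    feature_means: np.ndarray  # p, column means of the fitting cohort


def _r_squared(score: np.ndarray, design: np.ndarray) -> float:
    """R^2 of OLS of a PC score on a (dummy-coded) design with intercept."""
    X = np.column_stack([np.ones(len(score)), design])
    beta, *_ = np.linalg.lstsq(X, score, rcond=None)
    resid = score - X @ beta
    sst = float(((score - score.mean()) ** 2).sum())
    if sst == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / sst


def _encode(values: pd.Series) -> np.ndarray | None:
    """Dummy-code a covariate for regression; None if constant."""
    vals = values
    if vals.dtype == object or str(vals.dtype) == "category" or vals.dtype == bool:
        dummies = pd.get_dummies(vals, drop_first=True)
        if dummies.shape[1] == 0:
            return None
        return dummies.to_numpy(float)
    arr = vals.to_numpy(float)
    if np.nanstd(arr) == 0:
        return None
    return arr[:, None]


def pca_diagnostics(
    X: pd.DataFrame,
    clinical: pd.DataFrame,
    n_pcs: int = 30,
    variables: tuple[str, ...] = ("batch", "age", "sex"),
) -> pd.DataFrame:
    """Principal components of the column-centered lipid matrix with, per PC,
    the variance explained and the R^2 from regressing the PC score on each
    diagnostic variable (batch dummy-coded; constant variables report 0)."""
    if len(X) < n_pcs + 1:
        raise DataError(f"need at least {n_pcs + 1} samples for {n_pcs} PCs")
    Y = X.to_numpy(float)
    Y = Y - Y.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Y, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    scores = U[:, :n_pcs] * s[:n_pcs]
    var_explained = (s**2 / (s**2).sum())[:n_pcs]

    meta = clinical.set_index("sample_id").reindex(X.index)
    out = pd.DataFrame(
        {"pc": [f"PC{i + 1}" for i in range(n_pcs)], "var_explained": var_explained}
    ).set_index("pc")
    for var in variables:
        if var not in meta.columns:
            raise DataError(f"variable {var!r} absent from clinical table")
        col = meta[var]
        mask = col.notna().to_numpy()
        design = _encode(col[mask]) if mask.any() else None
        r2 = np.zeros(n_pcs)
        if design is None:
            warnings.warn(f"variable {var!r} is constant; R^2 reported as 0", stacklevel=2)
        else:
            for i in range(n_pcs):
                r2[i] = _r_squared(scores[mask, i], design)
        out[f"r2_{var}"] = r2
    return out


def make_pseudo_replicates(
    clinical: pd.DataFrame, n_clusters: int = 80
) -> ReplicateStructure:
    """Partition study samples into ``n_clusters`` clinically homogeneous
    groups (Ward linkage on standardized age/BMI plus 0/1 risk-factor flags
    and sex) and append one replicate group per QC sample type present."""
    study = clinical[clinical["role"] == "study"]
    if n_clusters > len(study):
        raise ConfigurationError(
            f"n_clusters ({n_clusters}) exceeds number of study samples ({len(study)})"
        )
    cont = study[_CLUSTER_CONTINUOUS].to_numpy(float)
    sd = cont.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    cont = (cont - cont.mean(axis=0)) / sd
    binary = np.column_stack(
        [study[c].astype(bool).to_numpy(float) for c in _CLUSTER_BINARY]
        + [(study["sex"] == "F").to_numpy(float)]
    )
    features = np.column_stack([cont, binary])
    cluster_of = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward").fit_predict(
        features
    )

    group_names = [f"cluster_{g:03d}" for g in range(n_clusters)]
    assignments = {sid: int(g) for sid, g in zip(study["sample_id"], cluster_of)}
    qc = clinical[clinical["role"] != "study"]
    for role in ("pooled_qc", "technical_qc", "blank", "nist1950"):
        members = qc.loc[qc["role"] == role, "sample_id"]
        if len(members):
            idx = len(group_names)
            group_names.append(role)
            for sid in members:
                assignments[sid] = idx

    sample_ids = list(clinical["sample_id"])
    M = np.zeros((len(sample_ids), len(group_names)))
    for i, sid in enumerate(sample_ids):
        M[i, assignments[sid]] = 1.0
    return ReplicateStructure(membership=M, sample_ids=sample_ids, group_names=group_names)


def select_control_features(
    X: pd.DataFrame,
    clinical: pd.DataFrame,
    batch_fdr: float = 0.05,
    bio_p: float = 0.05,
    labels: pd.Series | None = None,
) -> np.ndarray:
    """Negative-control species: significantly associated with batch (one-way
    ANOVA, BH-FDR < ``batch_fdr``) but not with age (correlation test) or sex
    (two-sample t test) at raw p > ``bio_p``. Computed on study samples.

    Negative controls must carry no wanted variation, or the factors
    estimated from them will subtract it. Age and sex are the observable
    proxies for biology, but when class ``labels`` are supplied (fitting-
    cohort labels only), species associated with the class at p < ``bio_p``
    (two-sample t test) are additionally excluded — important when disease
    effects are large relative to technical noise.
    """
    meta = clinical.set_index("sample_id").reindex(X.index)
    study_mask = (meta["role"] == "study").to_numpy()
    Xs = X.to_numpy(float)[study_mask]
    meta = meta[study_mask]
    batches = meta["batch"].to_numpy()
    if len(np.unique(batches)) < 2:
        raise DataError("need at least 2 batches to select control features")

    groups = [Xs[batches == b] for b in np.unique(batches)]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p_batch = stats.f_oneway(*groups, axis=0)
    p_batch = np.nan_to_num(p_batch, nan=1.0)
    batch_sig = multipletests(p_batch, method="fdr_bh")[1] < batch_fdr

    # age: t test on the Pearson correlation
    age = meta["age"].to_numpy(float)
    age_c = age - age.mean()
    Xc = Xs - Xs.mean(axis=0, keepdims=True)
    denom = np.sqrt((age_c**2).sum() * (Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (age_c @ Xc) / denom, 0.0)
    n = len(age)
    r = np.clip(r, -0.9999999, 0.9999999)
    t_age = r * np.sqrt((n - 2) / (1.0 - r**2))
    p_age = 2.0 * stats.t.sf(np.abs(t_age), df=n - 2)

    female = (meta["sex"] == "F").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p_sex = stats.ttest_ind(Xs[female], Xs[~female], axis=0)
    p_sex = np.nan_to_num(p_sex, nan=1.0)

    keep = batch_sig & (p_age > bio_p) & (p_sex > bio_p)
    if labels is not None:
        lab = labels.reindex(meta.index)
        cls = lab.isin(["sCAD_minus", "sCAD_plus"])
        if cls.sum() >= 4 and lab[cls].nunique() == 2:
            pos = (lab == "sCAD_plus").to_numpy() & cls.to_numpy()
            neg = (lab == "sCAD_minus").to_numpy() & cls.to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p_cls = stats.ttest_ind(Xs[pos], Xs[neg], axis=0)
            keep &= np.nan_to_num(p_cls, nan=1.0) > bio_p
    controls = np.flatnonzero(keep)
    if controls.size == 0:
        raise AnalysisError(
            "no control features satisfy the criteria; relax batch_fdr or bio_p"
        )
    return controls


def _solve_w(Y: np.ndarray, alpha: np.ndarray, controls: np.ndarray) -> np.ndarray:
    alpha_c = alpha[:, controls]
    gram = alpha_c @ alpha_c.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise AnalysisError(
            "alpha restricted to the control set is numerically singular; "
            "reduce k or enlarge the control set"
        )
    return Y[:, controls] @ alpha_c.T @ np.linalg.inv(gram)


def ruv3_fit(
    X: pd.DataFrame,
    M: ReplicateStructure,
    controls: np.ndarray,
    k: int = 8,
) -> tuple[RuvModel, pd.DataFrame]:
    """Fit RUV-III and return the model together with the adjusted matrix."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    controls = np.asarray(controls, dtype=int)
    if controls.size == 0:
        raise ConfigurationError("control set must be nonempty")
    if list(X.index) != list(M.sample_ids):
        raise DataError("lipid matrix rows and replicate structure are misaligned")
    Mmat = np.asarray(M.membership, dtype=float)
    n, m = Mmat.shape
    if k > n - m:
        raise ConfigurationError(
            f"k = {k} exceeds the residual rank n - m = {n - m} "
            "left by the replicate structure"
        )

    means = X.to_numpy(float).mean(axis=0)
    Y = X.to_numpy(float) - means
    # group-mean residual: M (M'M)^-1 M' Y computed without forming n x n
    group_sums = Mmat.T @ Y
    group_sizes = Mmat.sum(axis=0)[:, None]
    Y0 = Y - Mmat @ (group_sums / group_sizes)

    U, _, _ = np.linalg.svd(Y0, full_matrices=False)
    alpha = U[:, :k].T @ Y  # k x p
    W = _solve_w(Y, alpha, controls)
    adjusted = Y - W @ alpha + means

    model = RuvModel(
        alpha=alpha, k=k, controls=controls, species=list(X.columns), feature_means=means
    )
    return model, pd.DataFrame(adjusted, index=X.index, columns=X.columns)


def ruv3_transfer(
    X_new: pd.DataFrame, model: RuvModel, restore: str = "own"
) -> pd.DataFrame:
    """Apply a frozen RUV-III model to a new cohort.

    The new matrix is centered on its own column means, sample scores W are
    re-estimated from its control features with the stored alpha, and the
    product is subtracted. ``restore`` controls which feature-wise means are
    added back: ``"own"`` (default) restores the new cohort's means, so the
    output's column means equal the input's exactly; ``"model"`` restores
    the fitting cohort's stored means, aligning the new cohort's level with
    the fitting cohort — required when a risk model trained on the fitting
    cohort is applied to the adjusted values, because cohort-specific means
    contain cohort-specific batch offsets.
    """
    if restore not in ("own", "model"):
        raise ConfigurationError("restore must be 'own' or 'model'")
    if list(X_new.columns) != list(model.species):
        diff = set(X_new.columns) ^ set(model.species)
        raise DataError(f"species mismatch between matrix and model: {sorted(diff)[:10]}")
    means = X_new.to_numpy(float).mean(axis=0)
    Y = X_new.to_numpy(float) - means
    W = _solve_w(Y, model.alpha, model.controls)
    back = means if restore == "own" else model.feature_means
    adjusted = Y - W @ model.alpha + back
    return pd.DataFrame(adjusted, index=X_new.index, columns=X_new.columns)
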