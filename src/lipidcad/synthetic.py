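"""Synthetic lipidomic cohort generator with planted ground truth.

Real plasma-lipidomics cohorts with CT-derived coronary calcium labels are
not publicly shareable, so every downstream stage of this package is
exercised on simulated cohorts that reproduce the statistical structure the
analysis assumes:

* clinical covariates drawn to match the marginals of a typical CTCA-referral
  cohort (mean age 61 y, 45% female, mean BMI 26.9 kg/m², 39% hypertensive,
  8.7% diabetic, 59% hypercholesterolemic, 6.4% current smokers);
* a zero-inflated log-normal coronary artery calcium (CAC) score whose
  point mass at zero shrinks with age and male sex and whose positive part
  grows with both, plus a tunable contribution of the modifiable risk
  factors (so a Framingham-type score has signal on the resulting labels);
* log-normal lipid concentrations with additive batch offsets on the log
  scale, mild age/sex loadings on a subset of species, and a sparse set of
  disease-associated species whose effect size switches at BMI 25 kg/m²;
* quality-control structure: pooled-QC samples at the pooled study mean,
  technical-QC replicates of one reference aliquot, near-floor blanks, and
  a NIST SRM 1950 style reference plasma, all carrying the batch offsets of
  the batch they were measured in.

The generator returns a :class:`SimTruth` oracle recording exactly which
species carry class effects, with what magnitude, and what the planted batch
loadings were, so recovery can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "simulate_clinical",
    "simulate_cac",
    "simulate_lipidome",
    "simulate_cohort",
    "write_cohort",
]

#: sample roles understood throughout the package
ROLES = ("study", "pooled_qc", "technical_qc", "blank", "nist1950")

#: log-scale offset of blank samples below the species baseline
BLANK_OFFSET = -5.0


def _default_covariate_params() -> dict:
    return {
        "age_mean": 61.0,
        "age_sd": 12.0,
        "female_prob": 0.45,
        "bmi_mean": 26.9,
        "bmi_sd": 4.8,
        "hypertension_prob": 0.39,
        "diabetes_prob": 0.087,
        "hypercholesterolemia_prob": 0.59,
        "current_smoking_prob": 0.064,
        "sbp_mean": 130.0,
        "sbp_sd": 16.0,
        "tc_mean": 5.6,
        "tc_sd": 1.0,
        "hdl_mean": 1.4,
        "hdl_sd": 0.35,
    }


def _default_qc_counts() -> dict:
    return {"pooled_qc": 12, "technical_qc": 6, "blank": 6, "nist1950": 4}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``effect_low_bmi`` / ``effect_high_bmi`` are per-residual-SD log-odds of
    disease class per unit lipid, applied to the ``n_informative`` planted
    species in the BMI < 25 and BMI >= 25 strata respectively.
    ``cac_covariate_weight`` scales how strongly the modifiable risk factors
    (SBP, cholesterol, smoking, diabetes, hypertension) drive CAC; because
    class labels are age/sex-percentile-adjusted, this knob effectively sets
    how informative a traditional risk score is about the labels.
    """

    n_study: int = 600
    n_species: int = 683
    n_batches: int = 3
    batch_sd: float = 0.5
    n_informative: int = 30
    effect_low_bmi: float = 0.5
    effect_high_bmi: float = 0.5
    noise_sd: float = 0.3
    qc_noise_sd: float = 0.05
    statin_prob: float = 0.33
    cac_covariate_weight: float = 1.0
    age_loading_sd: float = 0.012
    sex_loading_sd: float = 0.03
    cac_zero_intercept: float = 0.4
    covariate_params: dict = field(default_factory=_default_covariate_params)
    qc_counts: dict = field(default_factory=_default_qc_counts)
    seed: int = 0

    def validate(self) -> None:
        if self.n_study < 1 or self.n_species < 1 or self.n_batches < 1:
            raise ConfigurationError("n_study, n_species, n_batches must be >= 1")
        if self.n_informative > self.n_species:
            raise ConfigurationError(
                f"n_informative ({self.n_informative}) exceeds "
                f"n_species ({self.n_species})"
            )
        if self.n_informative < 0:
            raise ConfigurationError("n_informative must be >= 0")
        for name in ("batch_sd", "noise_sd", "qc_noise_sd", "age_loading_sd", "sex_loading_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.statin_prob <= 1.0:
            raise ConfigurationError("statin_prob must lie in [0, 1]")
        cp = _default_covariate_params() | dict(self.covariate_params)
        for key, val in cp.items():
            if key.endswith("_prob") and not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"covariate_params[{key!r}] must lie in [0, 1]")
            if key.endswith("_sd") and val < 0:
                raise ConfigurationError(f"covariate_params[{key!r}] must be >= 0")
        self.covariate_params = cp
        for role, count in self.qc_counts.items():
            if role not in ROLES[1:]:
                raise ConfigurationError(f"unknown QC role {role!r}")
            if count < 0:
                raise ConfigurationError("QC counts must be >= 0")


@dataclass
class SimTruth:
    """Ground-truth record of a simulated cohort.

    ``true_effects`` holds one (low-BMI, high-BMI) per-SD log-odds pair per
    informative species; ``batch_loadings`` is the planted n_batches x
    n_species offset matrix on the log-concentration scale.
    """

    informative_species: np.ndarray  # column indices into the lipid matrix
    true_effects: np.ndarray  # (n_informative, 2): [:, 0] low-BMI, [:, 1] high-BMI
    batch_loadings: pd.DataFrame  # batches x species
    labels: pd.Series  # per-study-sample disease class

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_species": self.informative_species.tolist(),
            "true_effects": self.true_effects.tolist(),
            "batch_loadings": {
                "index": list(self.batch_loadings.index),
                "columns": list(self.batch_loadings.columns),
                "values": self.batch_loadings.to_numpy().tolist(),
            },
            "labels": {str(k): v for k, v in self.labels.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        bl = payload["batch_loadings"]
        return cls(
            informative_species=np.asarray(payload["informative_species"], dtype=int),
            true_effects=np.asarray(payload["true_effects"], dtype=float),
            batch_loadings=pd.DataFrame(
                np.asarray(bl["values"], dtype=float),
                index=bl["index"],
                columns=bl["columns"],
            ),
            labels=pd.Series(payload["labels"]),
        )


def _rng_for(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage, all rooted at config.seed
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=n), lo, hi)


def simulate_clinical(config: SimulationConfig) -> pd.DataFrame:
    """Draw the clinical table: study rows with full covariates, QC rows
    carrying only sample role and batch.

    Batches are assigned in contiguous recruitment blocks of size
    n_study / n_batches, mimicking consecutive recruitment with batched
    sample storage. QC samples are spread round-robin over the batches.
    """
    config.validate()
    rng = _rng_for(config, 0)
    cp = config.covariate_params
    n = config.n_study

    age = _truncated_normal(rng, cp["age_mean"], cp["age_sd"], 18.0, 95.0, n)
    sex = np.where(rng.random(n) < cp["female_prob"], "F", "M")
    bmi = _truncated_normal(rng, cp["bmi_mean"], cp["bmi_sd"], 15.0, 55.0, n)
    hypertension = rng.random(n) < cp["hypertension_prob"]
    diabetes = rng.random(n) < cp["diabetes_prob"]
    hyperchol = rng.random(n) < cp["hypercholesterolemia_prob"]
    smoking = rng.random(n) < cp["current_smoking_prob"]
    statin = rng.random(n) < config.statin_prob
    sbp = _truncated_normal(rng, cp["sbp_mean"], cp["sbp_sd"], 90.0, 220.0, n)
    tc = _truncated_normal(rng, cp["tc_mean"], cp["tc_sd"], 2.5, 10.0, n)
    hdl = _truncated_normal(rng, cp["hdl_mean"], cp["hdl_sd"], 0.5, 3.0, n)

    recruit_order = np.arange(1, n + 1)
    batch_idx = (np.arange(n) * config.n_batches) // n  # contiguous blocks
    batch = np.array([f"B{i + 1}" for i in batch_idx])

    width = max(4, len(str(n)))
    study = pd.DataFrame(
        {
            "sample_id": [f"S{i:0{width}d}" for i in recruit_order],
            "role": "study",
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "hypertension": hypertension,
            "diabetes": diabetes,
            "hypercholesterolemia": hyperchol,
            "current_smoking": smoking,
            "statin": statin,
            "sbp": sbp,
            "tc": tc,
            "hdl": hdl,
            "cac": np.nan,
            "batch": batch,
            "recruit_order": recruit_order,
        }
    )

    qc_rows = []
    prefixes = {"pooled_qc": "QCP", "technical_qc": "QCT", "blank": "BLK", "nist1950": "NIST"}
    for role in ROLES[1:]:
        count = int(config.qc_counts.get(role, 0))
        for j in range(count):
            qc_rows.append(
                {
                    "sample_id": f"{prefixes[role]}{j + 1:02d}",
                    "role": role,
                    "batch": f"B{(j % config.n_batches) + 1}",
                }
            )
    if qc_rows:
        qc = pd.DataFrame(qc_rows)
        table = pd.concat([study, qc], ignore_index=True)
    else:
        table = study
    return table.reset_index(drop=True)


def simulate_cac(
    clinical: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    zero_prob_intercept: float | None = None,
) -> pd.Series:
    """Simulate coronary artery calcium scores for the study rows.

    The score is zero-inflated: the probability of CAC = 0 decreases with
    age and is larger for females; the positive part is log-normal with
    location increasing in age and male sex. The modifiable-risk-factor
    linear predictor enters both parts scaled by
    ``config.cac_covariate_weight``. ``zero_prob_intercept`` defaults to
    ``config.cac_zero_intercept`` (0.4, which leaves roughly half the cohort
    at zero under the default covariate mix); ``numpy.inf`` forces the
    entire point mass (all scores zero).

    Returns a Series aligned to ``clinical`` with NaN on non-study rows.
    """
    config.validate()
    if rng is None:
        rng = _rng_for(config, 1)
    if zero_prob_intercept is None:
        zero_prob_intercept = config.cac_zero_intercept
    mask = (clinical["role"] == "study").to_numpy()
    if not mask.any():
        raise ConfigurationError("clinical table contains no study rows")
    sub = clinical.loc[mask]
    cp = config.covariate_params

    age_z = (sub["age"].to_numpy(float) - 60.0) / 10.0
    male = (sub["sex"] == "M").to_numpy(float)
    rf = (
        0.25 * (sub["sbp"].to_numpy(float) - cp["sbp_mean"]) / cp["sbp_sd"]
        + 0.30 * (sub["tc"].to_numpy(float) - cp["tc_mean"]) / cp["tc_sd"]
        - 0.30 * (sub["hdl"].to_numpy(float) - cp["hdl_mean"]) / cp["hdl_sd"]
        + 0.40 * sub["current_smoking"].to_numpy(float)
        + 0.40 * sub["diabetes"].to_numpy(float)
        + 0.30 * sub["hypertension"].to_numpy(float)
    )
    w = config.cac_covariate_weight
    eta_zero = zero_prob_intercept - 0.9 * age_z - 0.6 * male - 0.5 * w * rf
    with np.errstate(over="ignore"):
        p_zero = 1.0 / (1.0 + np.exp(-eta_zero))
    is_zero = rng.random(mask.sum()) < p_zero
    log_cac = 3.0 + 0.8 * age_z + 0.6 * male + 0.6 * w * rf + rng.normal(0.0, 1.2, mask.sum())
    cac = np.where(is_zero, 0.0, np.exp(log_cac))

    out = pd.Series(np.nan, index=clinical.index, name="cac")
    out.loc[mask] = cac
    return out


def simulate_lipidome(
    clinical: pd.DataFrame,
    labels: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate the log-scale lipid concentration matrix and its truth record.

    Per study sample and species: baseline + batch offset + age/sex loading
    + class effect (informative species only, magnitude switched at BMI 25)
    + Gaussian noise. Pooled-QC rows sit at the pooled mean of the study
    signal, technical-QC rows replicate one reference aliquot, blanks sit at
    baseline + ``BLANK_OFFSET``; all QC rows carry their batch's offset and
    technical noise only.
    """
    config.validate()
    if rng is None:
        rng = _rng_for(config, 2)
    p = config.n_species
    species = [f"lipid_{j + 1:04d}" for j in range(p)]
    batch_names = [f"B{i + 1}" for i in range(config.n_batches)]

    baseline = rng.normal(np.log(10.0), 1.0, size=p)
    loadings = rng.normal(0.0, config.batch_sd, size=(config.n_batches, p)) \
        if config.batch_sd > 0 else np.zeros((config.n_batches, p))

    # mild biology on a quarter of the species each, so control-feature
    # selection has something to exclude
    age_load = np.zeros(p)
    sex_load = np.zeros(p)
    age_cols = rng.choice(p, size=max(1, p // 4), replace=False)
    sex_cols = rng.choice(p, size=max(1, p // 4), replace=False)
    # loadings kept small enough that the aggregated "lipidomic age/sex"
    # signal stays moderate (multivariate AUC ~0.6 against the class labels),
    # in line with the modest class signal real plasma lipidomes carry
    age_load[age_cols] = rng.normal(0.0, config.age_loading_sd, size=age_cols.size)
    sex_load[sex_cols] = rng.normal(0.0, config.sex_loading_sd, size=sex_cols.size)

    informative = np.sort(rng.choice(p, size=config.n_informative, replace=False))
    # per-SD log-odds -> log-concentration shift for class-positive samples
    delta_low = config.effect_low_bmi * config.noise_sd
    delta_high = config.effect_high_bmi * config.noise_sd

    study_mask = (clinical["role"] == "study").to_numpy()
    study = clinical.loc[study_mask]
    n = len(study)
    batch_of = study["batch"].map({b: i for i, b in enumerate(batch_names)}).to_numpy()

    age_z = (study["age"].to_numpy(float) - 60.0) / 10.0
    male = (study["sex"] == "M").to_numpy(float)
    lab = labels.reindex(study["sample_id"]).to_numpy()
    positive = (lab == "sCAD_plus").astype(float)
    low_bmi = (study["bmi"].to_numpy(float) < 25.0).astype(float)

    signal = (
        baseline[None, :]
        + age_z[:, None] * age_load[None, :]
        + male[:, None] * sex_load[None, :]
    )
    effect = np.zeros((n, p))
    per_sample_delta = positive * (low_bmi * delta_low + (1.0 - low_bmi) * delta_high)
    effect[:, informative] = per_sample_delta[:, None]
    signal = signal + effect

    X_study = signal + loadings[batch_of, :] + rng.normal(0.0, config.noise_sd, size=(n, p))

    pooled_mean = signal.mean(axis=0)  # pooled plasma: average of study signal
    nist_offset = rng.normal(0.0, 0.3, size=p)  # a different reference matrix

    rows = [X_study]
    ids = [list(study["sample_id"])]
    qc = clinical.loc[~study_mask]
    if len(qc):
        qc_batch = qc["batch"].map({b: i for i, b in enumerate(batch_names)}).to_numpy()
        base_by_role = {
            "pooled_qc": pooled_mean,
            "technical_qc": baseline,
            "blank": baseline + BLANK_OFFSET,
            "nist1950": baseline + nist_offset,
        }
        qc_base = np.stack([base_by_role[r] for r in qc["role"]])
        X_qc = qc_base + loadings[qc_batch, :] + rng.normal(
            0.0, config.qc_noise_sd, size=(len(qc), p)
        )
        rows.append(X_qc)
        ids.append(list(qc["sample_id"]))

    X = pd.DataFrame(np.vstack(rows), index=np.concatenate(ids), columns=species)
    X.index.name = "sample_id"
    # restore the clinical row order
    X = X.loc[clinical["sample_id"].to_numpy()]

    truth = SimTruth(
        informative_species=informative,
        true_effects=np.column_stack(
            [
                np.full(informative.size, config.effect_low_bmi),
                np.full(informative.size, config.effect_high_bmi),
            ]
        ),
        batch_loadings=pd.DataFrame(loadings, index=batch_names, columns=species),
        labels=pd.Series(lab, index=study["sample_id"].to_numpy(), name="label"),
    )
    return X, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, SimTruth]:
    """End-to-end generation: clinical table with CAC, lipid matrix, labels, truth.

    Labels are produced by the same age/sex-percentile rule the analysis
    applies to real cohorts (see :func:`lipidcad.cohort.assign_scad_labels`),
    so the planted lipid effects are tied to the classes the pipeline will
    actually model.
    """
    from .cohort import assign_scad_labels  # local import: avoid cycle

    clinical = simulate_clinical(config)
    clinical["cac"] = simulate_cac(clinical, config)
    labels = assign_scad_labels(clinical)
    lipids, truth = simulate_lipidome(clinical, labels, config)
    return clinical, lipids, labels, truth


def write_cohort(
    clinical: pd.DataFrame,
    lipids: pd.DataFrame,
    out_dir: str | Path,
    truth: SimTruth | None = None,
) -> dict[str, Path]:
    """Write the standard package files: clinical CSV, lipid CSV (sample_id,
    role, batch, then one column per species), and optionally the truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": out / "clinical.csv",
        "lipids": out / "lipids.csv",
    }
    clinical.to_csv(paths["clinical"], index=False)
    meta = clinical.set_index("sample_id").loc[lipids.index, ["role", "batch"]]
    lipid_out = pd.concat([meta, lipids], axis=1)
    lipid_out.index.name = "sample_id"
    lipid_out.to_csv(paths["lipids"])
    if truth is not None:
        paths["truth"] = out / "truth.json"
        truth.to_json(paths["truth"])
    return paths
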