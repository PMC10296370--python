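"""Cohort loading, subclinical-CAD labeling, discovery/validation split,
and demographic summary tables.

Labeling rule: statin users are excluded outright (lipid-lowering therapy
perturbs the plasma lipidome); participants with zero coronary artery
calcium are the negative class (sCAD-); participants at or above the 50th
percentile of CAC for their sex and age decade are the positive class
(sCAD+); the remaining positive-but-below-median participants are excluded
as intermediate. The percentile reference is the within-cohort empirical
distribution of positive CAC among non-statin participants of the stratum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, DataError

__all__ = [
    "CLINICAL_COLUMNS",
    "LABELS",
    "CohortSplit",
    "load_cohort",
    "assign_scad_labels",
    "split_by_recruitment",
    "summarize_cohort",
    "format_count_pct",
    "format_mean_sd",
]

CLINICAL_COLUMNS = [
    "sample_id", "role", "age", "sex", "bmi", "hypertension", "diabetes",
    "hypercholesterolemia", "current_smoking", "statin", "sbp", "tc", "hdl",
    "cac", "batch", "recruit_order",
]

#: label vocabulary
LABELS = ("sCAD_minus", "sCAD_plus", "excluded_statin", "excluded_intermediate")

_LIPID_META = ["sample_id", "role", "batch"]


@dataclass
class CohortSplit:
    """Disjoint discovery/validation partition of the analytical cohort."""

    discovery: list[str]
    validation: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.discovery) & set(self.validation)
        if overlap:
            raise DataError(f"discovery/validation overlap: {sorted(overlap)[:5]}")


def validate_clinical(clinical: pd.DataFrame) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise DataError(f"clinical table missing columns: {missing}")
    if clinical["sample_id"].duplicated().any():
        dupes = clinical.loc[clinical["sample_id"].duplicated(), "sample_id"]
        raise DataError(f"duplicate sample_id values: {sorted(set(dupes))[:5]}")
    study = clinical[clinical["role"] == "study"]
    if (study["cac"].dropna() < 0).any():
        raise DataError("negative CAC scores present")


def load_cohort(
    clinical_path, lipid_path, raw_scale: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the clinical CSV and the lipid CSV and align them.

    The lipid file carries ``sample_id, role, batch`` followed by one column
    per species. With ``raw_scale=True`` concentrations are natural-log
    transformed on load; otherwise they are taken as already log scale.
    """
    clinical = pd.read_csv(clinical_path)
    validate_clinical(clinical)
    lipids = pd.read_csv(lipid_path)
    missing_meta = [c for c in _LIPID_META if c not in lipids.columns]
    if missing_meta:
        raise DataError(f"lipid file missing columns: {missing_meta}")
    lipids = lipids.set_index("sample_id")
    species_cols = [c for c in lipids.columns if c not in ("role", "batch")]

    values = lipids[species_cols]
    non_numeric = values.columns[
        ~values.apply(lambda col: pd.to_numeric(col, errors="coerce").notna().all())
    ]
    if len(non_numeric):
        raise DataError(f"non-numeric concentrations in species: {list(non_numeric)[:5]}")
    values = values.astype(float)

    clin_ids = set(clinical["sample_id"])
    lip_ids = set(lipids.index)
    if clin_ids != lip_ids:
        only_clin = sorted(clin_ids - lip_ids)
        only_lip = sorted(lip_ids - clin_ids)
        raise AlignmentError(
            f"sample mismatch; clinical-only: {only_clin[:10]}, lipid-only: {only_lip[:10]}"
        )
    values = values.loc[clinical["sample_id"].to_numpy()]
    if raw_scale:
        if (values.to_numpy() <= 0).any():
            raise DataError("raw-scale concentrations must be positive for log transform")
        values = np.log(values)
    return clinical.reset_index(drop=True), values


def _age_decade(age: float) -> str:
    lo = int(age // 10) * 10
    return f"{lo}-{lo + 9}"


def assign_scad_labels(clinical: pd.DataFrame) -> pd.Series:
    """Label every study sample as sCAD-, sCAD+, excluded_statin, or
    excluded_intermediate.

    Strata are sex x age decade; the 50th percentile is the empirical median
    of positive CAC among non-statin members of the stratum. The comparison
    is inclusive (CAC equal to the median is sCAD+). Strata with fewer than
    two positive-CAC members fall back to a sex-only stratum with a warning.
    """
    study = clinical[clinical["role"] == "study"].copy()
    if study["cac"].isna().any():
        bad = study.loc[study["cac"].isna(), "sample_id"].tolist()
        raise DataError(f"study samples without CAC: {bad[:5]}")

    study["_decade"] = study["age"].map(_age_decade)
    eligible = study[~study["statin"].astype(bool)]
    pos = eligible[eligible["cac"] > 0]

    med_by_stratum = pos.groupby(["sex", "_decade"], observed=True)["cac"].agg(["median", "size"])
    med_by_sex = pos.groupby("sex", observed=True)["cac"].median()
    overall_median = float(pos["cac"].median()) if len(pos) else math.inf

    def threshold(sex: str, decade: str) -> float:
        key = (sex, decade)
        if key in med_by_stratum.index and med_by_stratum.loc[key, "size"] >= 2:
            return float(med_by_stratum.loc[key, "median"])
        warnings.warn(
            f"stratum {sex}/{decade} has < 2 positive-CAC members; "
            "falling back to sex-only stratum",
            stacklevel=2,
        )
        if sex in med_by_sex.index:
            return float(med_by_sex.loc[sex])
        return overall_median

    labels = []
    for _, row in study.iterrows():
        if bool(row["statin"]):
            labels.append("excluded_statin")
        elif row["cac"] == 0:
            labels.append("sCAD_minus")
        elif row["cac"] >= threshold(row["sex"], row["_decade"]):
            labels.append("sCAD_plus")
        else:
            labels.append("excluded_intermediate")
    return pd.Series(labels, index=study["sample_id"].to_numpy(), name="label")


def split_by_recruitment(
    labels: pd.Series, clinical: pd.DataFrame, discovery_fraction: float
) -> CohortSplit:
    """Split the analytical cohort (sCAD-/sCAD+ samples) by recruitment order:
    the first ceil(fraction * n) recruited go to discovery, the rest to
    validation."""
    if not 0.0 < discovery_fraction < 1.0:
        raise ConfigurationError("discovery_fraction must lie strictly in (0, 1)")
    analytical = labels[labels.isin(["sCAD_minus", "sCAD_plus"])].index
    if len(analytical) == 0:
        raise DataError("analytical cohort is empty")
    order = (
        clinical.set_index("sample_id")
        .loc[analytical, "recruit_order"]
        .astype(float)
        .sort_values(kind="stable")
    )
    n_disc = math.ceil(discovery_fraction * len(order))
    ids = list(order.index)
    return CohortSplit(discovery=ids[:n_disc], validation=ids[n_disc:])


def format_count_pct(count: int, total: int) -> str:
    """``count (pct%)`` with the percentage to two significant digits."""
    if total <= 0:
        raise ConfigurationError("total must be positive")
    pct = 100.0 * count / total
    if pct >= 99.5:
        text = f"{pct:.0f}"
    else:
        text = f"{pct:.2g}"
    return f"{count} ({text}%)"


def format_mean_sd(values: pd.Series, decimals: int = 1) -> str:
    vals = pd.Series(values).dropna().astype(float)
    if len(vals) == 0:
        return "NA"
    sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
    return f"{vals.mean():.{decimals}f} ({sd:.{decimals}f})"


_CATEGORICAL_ROWS = [
    ("Female", lambda d: d["sex"] == "F"),
    ("Hypertension", lambda d: d["hypertension"].astype(bool)),
    ("Diabetes Mellitus", lambda d: d["diabetes"].astype(bool)),
    ("Hypercholesterolaemia", lambda d: d["hypercholesterolemia"].astype(bool)),
    ("Current Smoking Status", lambda d: d["current_smoking"].astype(bool)),
    ("Statin", lambda d: d["statin"].astype(bool)),
]

_CONTINUOUS_ROWS = [
    ("Age, years", "age", 0),
    ("BMI, kg/m2", "bmi", 1),
    ("Coronary Artery Calcium Score", "cac", 0),
]


def summarize_cohort(
    clinical: pd.DataFrame, labels: pd.Series, split: CohortSplit | None = None
) -> pd.DataFrame:
    """Demographic/clinical summary: categorical rows as ``count (pct%)``,
    continuous rows as ``mean (SD)``, per sub-cohort column."""
    study = clinical[clinical["role"] == "study"].set_index("sample_id")
    columns: dict[str, pd.DataFrame] = {f"Whole cohort (n={len(study)})": study}
    if split is not None:
        groups = [
            ("Discovery", split.discovery),
            ("Validation", split.validation),
        ]
        for name, ids in groups:
            for cls, suffix in [("sCAD_minus", "sCAD-"), ("sCAD_plus", "sCAD+")]:
                members = [i for i in ids if labels.get(i) == cls]
                columns[f"{name} {suffix} (n={len(members)})"] = study.loc[members]

    rows: dict[str, dict[str, str]] = {}
    for col_name, frame in columns.items():
        n = len(frame)
        for row_name, fn in _CATEGORICAL_ROWS:
            count = int(fn(frame).sum()) if n else 0
            rows.setdefault(row_name, {})[col_name] = (
                format_count_pct(count, n) if n else "NA"
            )
        for row_name, var, dec in _CONTINUOUS_ROWS:
            rows.setdefault(row_name, {})[col_name] = format_mean_sd(frame[var], dec)
    return pd.DataFrame(rows).T[list(columns)]
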