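"""End-to-end pipeline: simulate/load -> label & split -> RUV-III normalize
(fit on discovery, frozen transfer to validation) -> per-species association
-> risk models (FRS / LRS / combined) -> classifiability & stratification ->
evaluation. One master seed drives every stochastic stage through derived
per-stage seeds; every run writes a manifest with the config hash, seed,
and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import ADJUSTMENT_COVARIATES, fit_lipid_associations, export_forest_data
from .classifiability import compute_ics, find_modifying_variable, stratify_cohort
from .cohort import assign_scad_labels, load_cohort, split_by_recruitment, summarize_cohort
from .errors import ConfigurationError, LipidcadError
from .evaluation import compare_model_targets, delong_test, evaluate_subcohorts, roc_auc
from .risk import (
    fit_combined,
    fit_frs_model,
    fit_ridge_logistic,
    framingham_risk,
    predict_risk,
    select_lrs_features,
)
from .ruv import make_pseudo_replicates, pca_diagnostics, ruv3_fit, ruv3_transfer, select_control_features
from .synthetic import SimulationConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Single structured configuration for the whole pipeline.

    Stage defaults: k = 8 unwanted factors, 80 clinical pseudo-replicate
    clusters, top 200 species, 50-repeat 5-fold cross-validation, BMI cutoff
    25 kg/m2, BH false discovery rate 0.05.
    """

    clinical_path: str | None = None
    lipid_path: str | None = None
    simulate: dict | None = None  # SimulationConfig fields; used when paths absent
    discovery_fraction: float = 394 / 580
    k: int = 8
    n_clusters: int = 80
    batch_fdr: float = 0.05
    bio_p: float = 0.05
    fdr: float = 0.05
    n_features: int = 200
    ridge_penalty: float | None = None  # None -> bootstrap-selected
    selection_grid: list | None = None
    n_boot: int = 100
    ics_repeats: int = 50
    ics_folds: int = 5
    bmi_cutoff: float = 25.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: int) -> int:
    # derived, reproducible, < 2**31
    return int(np.random.SeedSequence([int(master), stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; write artifacts under ``out_dir``; return the
    in-memory results dictionary. Any stage failure is re-raised with the
    stage name prepended."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        stage = "load"
        if config.clinical_path and config.lipid_path:
            clinical, lipids = load_cohort(config.clinical_path, config.lipid_path)
            stage = "label"
            labels = assign_scad_labels(clinical)
        else:
            sim_cfg = SimulationConfig(**(config.simulate or {}))
            if "seed" not in (config.simulate or {}):
                sim_cfg.seed = _stage_seed(config.seed, 0)
            clinical, lipids, labels, truth = simulate_cohort(sim_cfg)
            write_cohort(clinical, lipids, out, truth=truth)
            results["truth"] = truth

        stage = "split"
        split = split_by_recruitment(labels, clinical, config.discovery_fraction)
        summary = summarize_cohort(clinical, labels, split)
        summary.to_csv(out / "cohort_summary.csv")
        results.update(clinical=clinical, labels=labels, split=split, summary=summary)

        stage = "normalize"
        qc_ids = clinical.loc[clinical["role"] != "study", "sample_id"].tolist()
        disc_rows = clinical[clinical["sample_id"].isin(set(split.discovery) | set(qc_ids))]
        X_disc_fit = lipids.loc[disc_rows["sample_id"]]
        replicates = make_pseudo_replicates(disc_rows, n_clusters=min(config.n_clusters, len(split.discovery)))
        controls = select_control_features(
            X_disc_fit, clinical, config.batch_fdr, config.bio_p,
            labels=labels.reindex(split.discovery),
        )
        ruv_model, X_disc_adj = ruv3_fit(X_disc_fit, replicates, controls, k=config.k)
        X_val = lipids.loc[split.validation]
        # model-mean restoration aligns validation levels with discovery so
        # discovery-trained risk scores stay calibrated on validation
        X_val_adj = ruv3_transfer(X_val, ruv_model, restore="model")
        diag_pre = pca_diagnostics(X_disc_fit.loc[split.discovery], clinical)
        diag_post = pca_diagnostics(X_disc_adj.loc[split.discovery], clinical)
        diag_pre.to_csv(out / "pca_diagnostics_pre.csv")
        diag_post.to_csv(out / "pca_diagnostics_post.csv")
        results.update(
            ruv_model=ruv_model,
            X_discovery=X_disc_adj.loc[split.discovery],
            X_validation=X_val_adj,
            pca_pre=diag_pre,
            pca_post=diag_post,
            controls=controls,
        )

        stage = "associate"
        X_combined = pd.concat([results["X_discovery"], X_val_adj])
        covs = clinical.set_index("sample_id").loc[X_combined.index, ADJUSTMENT_COVARIATES]
        assoc = fit_lipid_associations(X_combined, labels, covariates=covs)
        assoc.to_csv(out / "associations.csv", index=False)
        forest = export_forest_data(assoc, fdr=config.fdr)
        forest.to_csv(out / "forest_data.csv", index=False)
        results.update(associations=assoc, forest=forest)

        stage = "train"
        Xd = results["X_discovery"]
        yd = labels.reindex(Xd.index)
        if config.ridge_penalty is None or config.n_features is None:
            selection = select_lrs_features(
                Xd, yd,
                grid=[tuple(g) for g in config.selection_grid] if config.selection_grid else None,
                n_boot=config.n_boot,
                seed=_stage_seed(config.seed, 1),
                discovery_ids=set(split.discovery),
            )
            penalty = config.ridge_penalty or selection.chosen_penalty
            n_feat = config.n_features or selection.chosen_n
            ranking = selection.ranking
            results["selection"] = selection
        else:
            penalty, n_feat = config.ridge_penalty, config.n_features
            selection = select_lrs_features(
                Xd, yd, grid=[(penalty, min(n_feat, Xd.shape[1]))],
                n_boot=max(10, config.n_boot // 5),
                seed=_stage_seed(config.seed, 1),
                discovery_ids=set(split.discovery),
            )
            ranking = selection.ranking
        top = ranking[: min(n_feat, len(ranking))]
        clin_idx = clinical.set_index("sample_id")
        frs_all = framingham_risk(clin_idx.loc[list(Xd.index) + list(X_val_adj.index)])
        lrs_model = fit_ridge_logistic(Xd[top], yd, penalty, kind="LRS",
                                       training_meta={"seed": config.seed, "n_boot": config.n_boot})
        frs_model = fit_frs_model(frs_all.reindex(Xd.index), yd)
        combined_model = fit_combined(Xd[top], frs_all, yd, penalty)
        for name, model in [("lrs", lrs_model), ("frs", frs_model), ("combined", combined_model)]:
            model.to_json(out / f"model_{name}.json")
        results.update(lrs_model=lrs_model, frs_model=frs_model, combined_model=combined_model,
                       top_species=top, penalty=penalty, frs_values=frs_all)

        stage = "ics"
        ics = compute_ics(
            Xd, yd, penalty=penalty, features=top,
            r=config.ics_repeats, f=config.ics_folds, seed=_stage_seed(config.seed, 2),
        )
        ics.scores.to_csv(out / "ics_scores.csv")
        scan = find_modifying_variable(ics, clinical)
        scan.table.to_csv(out / "modifier_scan.csv", index=False)
        # the stratification variable is BMI at the clinical cutoff; the scan
        # result is reported alongside so a different winner is visible
        low_ids, high_ids = stratify_cohort(
            clinical, ids=split.validation, variable="bmi", cutoff=config.bmi_cutoff
        )
        results.update(ics=ics, scan=scan, strata={"bmi_low": low_ids, "bmi_high": high_ids})

        stage = "evaluate"
        frs_val = frs_all.reindex(X_val_adj.index).to_frame("frs")
        lrs_risk, lrs_call = predict_risk(lrs_model, X_val_adj)
        frs_risk, frs_call = predict_risk(frs_model, frs_val)
        comb_X = X_val_adj[top].copy()
        comb_X["frs"] = frs_val["frs"]
        comb_risk, _ = predict_risk(combined_model, comb_X)
        y_val = labels.reindex(X_val_adj.index)
        scores = {"LRS": lrs_risk, "FRS": frs_risk, "FRS_plus_LRS": comb_risk}
        strata = {"all": list(X_val_adj.index), "bmi_low": low_ids, "bmi_high": high_ids}
        auc_table = evaluate_subcohorts(scores, y_val, strata)
        auc_table.to_csv(out / "auc_table.csv", index=False)
        delong = delong_test(lrs_risk.to_numpy(), frs_risk.to_numpy(), y_val.to_numpy())
        overlap = compare_model_targets(lrs_call.to_numpy(), frs_call.to_numpy(), y_val.to_numpy())
        roc_lrs = roc_auc(lrs_risk.to_numpy(), y_val.to_numpy())
        roc_frs = roc_auc(frs_risk.to_numpy(), y_val.to_numpy())
        pd.DataFrame({
            "threshold": roc_lrs.thresholds,
            "sensitivity": roc_lrs.sensitivity,
            "specificity": roc_lrs.specificity,
        }).to_csv(out / "roc_lrs.csv", index=False)
        report = {
            "auc": {r["model"] + "/" + r["stratum"]: r["auc"] for r in auc_table.to_dict("records")},
            "delong": {"auc_lrs": delong.auc1, "auc_frs": delong.auc2,
                       "z": delong.z, "p": delong.p},
            "overlap": {"both": overlap.both, "lrs_only": overlap.lrs_only,
                        "frs_only": overlap.frs_only, "neither": overlap.neither,
                        "percentages": overlap.percentages()},
            "modifier": scan.winner,
        }
        (out / "evaluation.json").write_text(json.dumps(report, indent=2, default=float))
        results.update(auc_table=auc_table, delong=delong, overlap=overlap,
                       roc={"LRS": roc_lrs, "FRS": roc_frs}, report=report,
                       scores=scores, calls={"LRS": lrs_call, "FRS": frs_call})

        manifest = {
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
            "config": dataclasses.asdict(config),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return results
    except LipidcadError as err:
        raise type(err)(f"[stage: {stage}] {err}") from err
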