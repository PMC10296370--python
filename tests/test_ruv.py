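"""RUV-III normalization tests: PCA diagnostics, pseudo-replicates,
control-feature selection, fit/transfer algebra, and batch-removal power."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import subspace_angles

import lipidcad as lc
from lipidcad.errors import AnalysisError, ConfigurationError, DataError
from lipidcad.ruv import (
    ReplicateStructure,
    make_pseudo_replicates,
    pca_diagnostics,
    ruv3_fit,
    ruv3_transfer,
    select_control_features,
)

from conftest import make_clinical_frame


def _lipid_frame(values, clinical):
    return pd.DataFrame(
        values,
        index=clinical["sample_id"].to_numpy(),
        columns=[f"lipid_{j:03d}" for j in range(values.shape[1])],
    )


class TestPcaDiagnostics:
    def test_pc_equal_to_batch_dummy_has_unit_r2(self, rng):
        n = 60
        clinical = make_clinical_frame(n, batch=np.repeat(["B1", "B2"], n // 2))
        dummy = np.repeat([0.0, 1.0], n // 2)
        X = _lipid_frame(np.outer(dummy, np.ones(10)) * 5 + rng.normal(0, 1e-4, (n, 10)),
                         clinical)
        diag = pca_diagnostics(X, clinical, n_pcs=3)
        assert diag["r2_batch"].iloc[0] > 0.999

    def test_null_r2_matches_expectation(self, rng):
        n = 500
        clinical = make_clinical_frame(n, batch=np.repeat(["B1", "B2"], n // 2))
        X = _lipid_frame(rng.normal(size=(n, 100)), clinical)
        diag = pca_diagnostics(X, clinical, n_pcs=30)
        # under independence E[R^2] = (B-1)/(n-1)
        assert diag["r2_batch"].mean() < 0.02
        assert diag["r2_batch"].mean() == pytest.approx(1 / (n - 1), abs=0.005)

    def test_row_count_equals_requested_pcs(self, small_cohort):
        _, clinical, lipids, _, _ = small_cohort
        study = clinical.loc[clinical["role"] == "study", "sample_id"]
        diag = pca_diagnostics(lipids.loc[study], clinical, n_pcs=30)
        assert len(diag) == 30
        assert ((diag.filter(like="r2_") >= 0) & (diag.filter(like="r2_") <= 1)).all().all()

    def test_constant_variable_reports_zero_with_warning(self, rng):
        n = 40
        clinical = make_clinical_frame(n, sex="M")
        X = _lipid_frame(rng.normal(size=(n, 8)), clinical)
        with pytest.warns(UserWarning, match="constant"):
            diag = pca_diagnostics(X, clinical, n_pcs=2, variables=("sex",))
        assert (diag["r2_sex"] == 0).all()


class TestPseudoReplicates:
    def test_default_group_count_with_qc(self, small_cohort):
        _, clinical, _, _, _ = small_cohort
        reps = make_pseudo_replicates(clinical, n_clusters=80)
        assert len(reps.group_names) == 84
        assert reps.membership.shape == (len(clinical), 84)

    def test_rows_sum_to_one_and_groups_nonempty(self, small_cohort):
        _, clinical, _, _, _ = small_cohort
        reps = make_pseudo_replicates(clinical, n_clusters=40)
        np.testing.assert_array_equal(reps.membership.sum(axis=1), 1.0)
        assert (reps.membership.sum(axis=0) > 0).all()

    def test_duplicate_rows_cluster_together(self):
        clinical = make_clinical_frame(30)
        clinical.loc[1, clinical.columns[2:]] = clinical.loc[0, clinical.columns[2:]]
        reps = make_pseudo_replicates(clinical, n_clusters=10)
        assert np.array_equal(reps.membership[0], reps.membership[1])

    def test_too_many_clusters_raises(self):
        with pytest.raises(ConfigurationError):
            make_pseudo_replicates(make_clinical_frame(10), n_clusters=11)

    def test_invalid_membership_rejected(self):
        with pytest.raises(DataError):
            ReplicateStructure(np.zeros((3, 2)), ["a", "b", "c"], ["g1", "g2"])


class TestControlFeatures:
    def test_pure_batch_species_selected_age_species_excluded(self, rng):
        n = 300
        clinical = make_clinical_frame(n, batch=np.repeat(["B1", "B2", "B3"], n // 3))
        batch_offset = clinical["batch"].map({"B1": 0.0, "B2": 1.0, "B3": 2.0}).to_numpy()
        age = clinical["age"].to_numpy()
        X = rng.normal(0, 0.3, size=(n, 20))
        X[:, 0] += batch_offset  # pure batch
        X[:, 1] += batch_offset + 0.05 * age  # batch + strong age trend
        lipids = _lipid_frame(X, clinical)
        controls = select_control_features(lipids, clinical)
        assert 0 in controls
        assert 1 not in controls

    def test_all_noise_matrix_yields_no_controls(self, rng):
        n = 200
        clinical = make_clinical_frame(n, batch=np.repeat(["B1", "B2"], n // 2))
        lipids = _lipid_frame(rng.normal(size=(n, 300)), clinical)
        try:
            controls = select_control_features(lipids, clinical)
        except AnalysisError:
            controls = np.array([])
        # FDR control: essentially no false control selections on pure noise
        assert len(controls) <= 3

    def test_class_associated_species_excluded_when_labels_given(self, small_cohort):
        cfg, clinical, lipids, labels, truth = small_cohort
        base = set(select_control_features(lipids, clinical))
        screened = set(select_control_features(lipids, clinical, labels=labels))
        assert screened <= base


@pytest.fixture(scope="module")
def fitted_ruv(small_cohort):
    _, clinical, lipids, labels, _ = small_cohort
    reps = make_pseudo_replicates(clinical, n_clusters=60)
    controls = select_control_features(lipids, clinical, labels=labels)
    model, adjusted = ruv3_fit(lipids, reps, controls, k=8)
    return clinical, lipids, reps, controls, model, adjusted


class TestRuvFit:
    def test_near_identity_without_unwanted_variation(self):
        # default problem size, but without batch effects or planted signal
        cfg = lc.SimulationConfig(
            n_study=600, n_species=683, batch_sd=0.0, n_informative=0, seed=31
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clinical, lipids, labels, _ = lc.simulate_cohort(cfg)
        reps = make_pseudo_replicates(clinical, n_clusters=80)
        controls = np.arange(lipids.shape[1])  # no batch signal: use all species
        _, adjusted = ruv3_fit(lipids, reps, controls, k=8)
        rel = np.linalg.norm(adjusted.to_numpy() - lipids.to_numpy()) / np.linalg.norm(
            lipids.to_numpy()
        )
        assert rel < 0.05

    def test_recovers_planted_batch_subspace(self, small_cohort):
        cfg, clinical, lipids, labels, truth = small_cohort
        reps = make_pseudo_replicates(clinical, n_clusters=60)
        bio = set(truth.informative_species.tolist())
        true_controls = np.array([j for j in range(cfg.n_species) if j not in bio])
        model, _ = ruv3_fit(lipids, reps, true_controls, k=3)
        L = truth.batch_loadings.to_numpy()
        L_centered = L - L.mean(axis=0, keepdims=True)  # rank B-1 visible after centering
        angles = subspace_angles(model.alpha.T, L_centered.T)
        assert np.degrees(angles).max() < 10.0

    def test_batch_r2_reduced_below_pre_fit(self, fitted_ruv):
        clinical, lipids, _, _, _, adjusted = fitted_ruv
        study = clinical.loc[clinical["role"] == "study", "sample_id"]
        pre = pca_diagnostics(lipids.loc[study], clinical)["r2_batch"].max()
        post = pca_diagnostics(adjusted.loc[study], clinical)["r2_batch"].max()
        assert post < pre

    def test_removes_at_most_k_directions(self, fitted_ruv):
        _, lipids, _, _, model, adjusted = fitted_ruv
        delta = (lipids.to_numpy() - lipids.to_numpy().mean(0)) - (
            adjusted.to_numpy() - adjusted.to_numpy().mean(0)
        )
        assert np.linalg.matrix_rank(delta, tol=1e-8) <= model.k

    def test_batch_r2_reduction_monotone_in_k(self, small_cohort):
        _, clinical, lipids, labels, _ = small_cohort
        reps = make_pseudo_replicates(clinical, n_clusters=60)
        controls = select_control_features(lipids, clinical, labels=labels)
        study = clinical.loc[clinical["role"] == "study", "sample_id"]
        maxima = []
        for k in (1, 2, 3):
            _, adj = ruv3_fit(lipids, reps, controls, k=k)
            maxima.append(pca_diagnostics(adj.loc[study], clinical)["r2_batch"].max())
        # three batches span two centered directions: monotone up to k = 2,
        # at the noise floor beyond
        assert maxima[0] >= maxima[1]
        assert maxima[2] < 0.02

    def test_qc_within_group_variance_shrinks(self, fitted_ruv):
        clinical, lipids, _, _, _, adjusted = fitted_ruv
        pooled = clinical.loc[clinical["role"] == "pooled_qc", "sample_id"]
        before = lipids.loc[pooled].var().mean()
        after = adjusted.loc[pooled].var().mean()
        assert after < before

    def test_k_exceeding_residual_rank_raises(self, small_cohort):
        _, clinical, lipids, _, _ = small_cohort
        reps = make_pseudo_replicates(clinical, n_clusters=60)
        with pytest.raises(ConfigurationError):
            ruv3_fit(lipids, reps, np.arange(5), k=len(lipids))


class TestRuvTransfer:
    def test_transfer_on_fitting_cohort_is_self_consistent(self, fitted_ruv):
        _, lipids, _, _, model, adjusted = fitted_ruv
        again = ruv3_transfer(lipids, model)
        np.testing.assert_allclose(again.to_numpy(), adjusted.to_numpy(), atol=1e-8)

    def test_zero_batch_new_data_nearly_unchanged(self):
        # full species count: with p = 683 the k-dimensional noise projection
        # removed from clean data is a negligible fraction of the signal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clinical, lipids, labels, _ = lc.simulate_cohort(
                lc.SimulationConfig(n_study=400, n_species=683, seed=55)
            )
            reps = make_pseudo_replicates(clinical, n_clusters=60)
            controls = select_control_features(lipids, clinical, labels=labels)
            model, _ = ruv3_fit(lipids, reps, controls, k=8)
            _, lipids_clean, *_ = lc.simulate_cohort(
                lc.SimulationConfig(n_study=200, n_species=683, batch_sd=0.0,
                                    n_informative=0, seed=56)
            )
        X_new = lipids_clean.copy()
        X_new.columns = model.species
        adj = ruv3_transfer(X_new, model)
        rel = np.linalg.norm(adj.to_numpy() - X_new.to_numpy()) / np.linalg.norm(
            X_new.to_numpy()
        )
        assert rel < 0.05

    def test_column_means_preserved_exactly(self, fitted_ruv, small_cohort):
        *_, model, _ = fitted_ruv
        _, clinical, lipids, _, _ = small_cohort
        X_val = lipids.iloc[200:]
        adj = ruv3_transfer(X_val, model)
        np.testing.assert_allclose(adj.mean().to_numpy(), X_val.mean().to_numpy(),
                                   atol=1e-10)

    def test_species_mismatch_raises(self, fitted_ruv):
        _, lipids, _, _, model, _ = fitted_ruv
        bad = lipids.rename(columns={lipids.columns[0]: "other"})
        with pytest.raises(DataError, match="other"):
            ruv3_transfer(bad, model)
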