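"""Ensemble averaging, exact affine generation, and the Model-3 hookup."""

import numpy as np
import pandas as pd
import pytest

from stressmtl.generation import (
    average_ensemble,
    generate_features,
    predict_aporfs_from_generated,
    unmeasured_patients,
)
from stressmtl.immune import RidgeConfig, RidgeEnsemble, grouped_repeated_cv
from stressmtl.nn import NetworkConfig
from stressmtl.prep import FeatureMatrix
from stressmtl.synthetic import (
    CohortSpec,
    ImmunePanelSpec,
    generate_cohort,
    generate_immune_panel,
)


def _ensemble(coefs, intercepts=None, n_psf=2):
    coefs = np.asarray(coefs, dtype=np.float32)
    s, m, p = coefs.shape
    if intercepts is None:
        intercepts = np.zeros((s, m), dtype=np.float32)
    return RidgeEnsemble(
        coefs=coefs,
        intercepts=np.asarray(intercepts, dtype=np.float32),
        scaler_mean=np.zeros((s, p), dtype=np.float32),
        scaler_sd=np.ones((s, p), dtype=np.float32),
        predictor_names=[f"psf_{i:03d}" for i in range(n_psf)] + ["timepoint"],
        immune_feature_names=[f"imm_{j}" for j in range(m)],
    )


def test_average_of_opposite_slices_is_zero():
    c = np.random.default_rng(0).normal(size=(1, 3, 3)).astype(np.float32)
    gen = average_ensemble(_ensemble(np.concatenate([c, -c])))
    assert np.allclose(gen.W, 0.0)


def test_single_slice_identity():
    c = np.random.default_rng(1).normal(size=(1, 3, 3)).astype(np.float32)
    gen = average_ensemble(_ensemble(c))
    assert np.allclose(gen.W, c[0])


def test_three_slice_elementwise_mean():
    c = np.random.default_rng(2).normal(size=(3, 4, 3)).astype(np.float32)
    ic = np.random.default_rng(3).normal(size=(3, 4)).astype(np.float32)
    gen = average_ensemble(_ensemble(c, ic))
    assert np.allclose(gen.W, c.mean(axis=0), atol=1e-7)
    assert np.allclose(gen.b, ic.mean(axis=0), atol=1e-7)


def test_empty_ensemble_rejected():
    with pytest.raises(ValueError, match="no fitted slices"):
        average_ensemble(_ensemble(np.zeros((0, 2, 3))))


def test_zero_generator_emits_zero_rows():
    gen = average_ensemble(_ensemble(np.zeros((1, 3, 3))))
    fm = FeatureMatrix(
        values=pd.DataFrame(np.zeros((5, 2)),
                            columns=["psf_000", "psf_001"])
    )
    out = generate_features(gen, fm, timepoint=1)
    assert out.shape == (5, 3)
    assert np.allclose(out, 0.0)


def test_predictor_mismatch_reported():
    gen = average_ensemble(_ensemble(np.zeros((1, 3, 3))))
    fm = FeatureMatrix(values=pd.DataFrame(np.zeros((2, 2)),
                                           columns=["psf_000", "wrong"]))
    with pytest.raises(ValueError, match="predictor mismatch"):
        generate_features(gen, fm)


def test_generation_deterministic_affine():
    rng = np.random.default_rng(4)
    gen = average_ensemble(_ensemble(rng.normal(size=(2, 3, 3))))
    fm = FeatureMatrix(values=pd.DataFrame(rng.normal(size=(6, 2)),
                                           columns=["psf_000", "psf_001"]))
    a = generate_features(gen, fm, timepoint=2)
    b = generate_features(gen, fm, timepoint=2)
    pd.testing.assert_frame_equal(a, b)  # bitwise identical


def test_average_then_generate_equals_generate_then_average():
    """Linearity: averaging coefficients commutes with generation."""
    rng = np.random.default_rng(5)
    coefs = rng.normal(size=(4, 3, 3)).astype(np.float32)
    ints = rng.normal(size=(4, 3)).astype(np.float32)
    fm = FeatureMatrix(values=pd.DataFrame(rng.normal(size=(7, 2)),
                                           columns=["psf_000", "psf_001"]))
    ens = _ensemble(coefs, ints)
    pooled = generate_features(average_ensemble(ens), fm, timepoint=3)
    per_slice = [
        generate_features(average_ensemble(_ensemble(coefs[i:i + 1],
                                                     ints[i:i + 1])),
                          fm, timepoint=3)
        for i in range(4)
    ]
    mean_of = sum(per_slice) / 4
    assert np.allclose(pooled, mean_of, atol=1e-5)


@pytest.fixture(scope="module")
def fitted_generator():
    cohort = generate_cohort(CohortSpec(seed=41))
    fm = FeatureMatrix(values=cohort.psf_frame())
    panel = generate_immune_panel(
        cohort,
        ImmunePanelSpec(n_immune_features=25, n_true_signal_features=25,
                        noise_sd=0.0, seed=41),
    )
    res = grouped_repeated_cv(panel, fm, RidgeConfig(n_repetitions=2, seed=6))
    return cohort, fm, panel, average_ensemble(res.ensemble)


def test_generation_covers_exactly_186_patients(fitted_generator):
    cohort, fm, panel, gen = fitted_generator
    rest = unmeasured_patients(cohort, panel.patient_ids)
    assert len(rest) == 186
    out = generate_features(
        gen, FeatureMatrix(values=fm.values.loc[rest]), timepoint=1
    )
    assert out.shape == (186, 25)


@pytest.fixture(scope="module")
def identified_generator():
    """Noiseless panel with more distinct patients than predictors, so the
    planted linear map is identifiable from the training rows."""
    cohort = generate_cohort(
        CohortSpec(n_patients=260,
                   outcome_case_counts=dict(hypertension=20, diabetes=12,
                                            gestational_diabetes=30,
                                            superimposed_pree=7,
                                            severe_pree=14, preterm=18),
                   n_any_aporf=None, psf_missing_rate=0.0, seed=42)
    )
    fm = FeatureMatrix(values=cohort.psf_frame())
    panel = generate_immune_panel(
        cohort,
        ImmunePanelSpec(n_immune_patients=140, n_immune_features=15,
                        n_true_signal_features=15, noise_sd=0.0, seed=42),
    )
    res = grouped_repeated_cv(panel, fm, RidgeConfig(n_repetitions=2, seed=6))
    return cohort, fm, panel, average_ensemble(res.ensemble)


def test_noiseless_generator_matches_planted_forward_map(identified_generator):
    """On held-out patients the averaged generator reproduces the planted
    linear map almost exactly when the panel is noiseless."""
    cohort, fm, panel, gen = identified_generator
    rest = unmeasured_patients(cohort, panel.patient_ids)
    got = generate_features(
        gen, FeatureMatrix(values=fm.values.loc[rest]), timepoint=1
    )
    from stressmtl.synthetic import scaled_psf_design

    X = scaled_psf_design(cohort, rest)
    truth = (
        X.to_numpy() @ panel.planted_coefficients.to_numpy()
        + panel.timepoint_effect[0]
    )
    corr = np.corrcoef(got.to_numpy().ravel(), truth.ravel())[0, 1]
    assert corr > 0.98


def test_measured_patient_overlap_is_hard_error(fitted_generator):
    cohort, fm, panel, gen = fitted_generator
    out = generate_features(gen, fm, timepoint=1)  # all 200 patients
    with pytest.raises(ValueError, match="immune-measured"):
        predict_aporfs_from_generated(
            out,
            cohort.outcome_frame(),
            NetworkConfig(n_features=25, task_specs=[("hypertension", "binary")]),
            measured_patient_ids=panel.patient_ids,
        )


def test_model_sees_exactly_the_unmeasured_patients(fitted_generator):
    cohort, fm, panel, gen = fitted_generator
    rest = unmeasured_patients(cohort, panel.patient_ids)
    out = generate_features(
        gen, FeatureMatrix(values=fm.values.loc[rest]), timepoint=1
    )
    cfg = NetworkConfig(
        n_features=25,
        task_specs=[("gestational_diabetes", "binary")],
        hidden_units=8,
        seed=1,
    )
    res = predict_aporfs_from_generated(
        out, cohort.outcome_frame(), cfg,
        measured_patient_ids=panel.patient_ids,
        n_repetitions=1,
    )
    seen = res.predictions["patient_id"].unique()
    assert len(seen) == 186
    assert not set(seen) & set(panel.patient_ids)
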