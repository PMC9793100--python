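"""Ridge oracle checks, BH step-up, and the grouped repeated screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stressmtl.immune import (
    RidgeConfig,
    add_timepoint,
    bh_correct,
    grouped_repeated_cv,
    ridge_fit,
)
from stressmtl.prep import FeatureMatrix
from stressmtl.synthetic import (
    CohortSpec,
    ImmunePanelSpec,
    generate_cohort,
    generate_immune_panel,
)


def test_ridge_noiseless_ols_recovers_slope():
    x = np.arange(1.0, 8.0)[:, None]
    y = 2.0 * x[:, 0]
    f = ridge_fit(x, y, alpha=0.0)
    assert f.coef[0] == pytest.approx(2.0)
    assert float(f.intercept) == pytest.approx(0.0, abs=1e-10)


def test_ridge_matches_closed_form_oracle():
    X = np.array([[1.0, 0.5], [0.2, -1.0], [-0.7, 0.3]])
    y = np.array([1.0, -0.5, 0.2])
    alpha = 0.1
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    oracle = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(2), Xc.T @ yc)
    f = ridge_fit(X, y, alpha)
    assert np.allclose(f.coef, oracle, atol=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 5000))
def test_ridge_shrinkage_monotone(seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((12, 4))
    y = rng.standard_normal(12)
    norms = [
        np.linalg.norm(ridge_fit(X, y, a).coef) for a in (0.0, 0.1, 1.0, 10.0)
    ]
    assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))


def test_ridge_rank_deficient_uses_minimum_norm():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((5, 9))  # p > n
    y = rng.standard_normal(5)
    f = ridge_fit(X, y, alpha=0.0)
    pred = X @ f.coef + f.intercept
    assert np.allclose(pred, y, atol=1e-8)  # interpolates
    # agrees with the lstsq minimum-norm solution on centred data
    Xc, yc = X - X.mean(0), y - y.mean()
    mn, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    assert np.allclose(f.coef, mn, atol=1e-8)


def test_add_timepoint_contracts():
    X = np.ones((4, 2))
    out = add_timepoint(X, [1, 2, 3, 4])
    assert out.shape == (4, 3)
    assert list(out[:, 2]) == [1.0, 2.0, 3.0, 4.0]
    shuffled = add_timepoint(X, [4, 1, 3, 2])
    assert list(shuffled[:, 2]) == [4.0, 1.0, 3.0, 2.0]
    assert add_timepoint(np.ones((0, 2)), []).shape == (0, 3)
    with pytest.raises(ValueError, match="unknown timepoint"):
        add_timepoint(X, [1, 2, 3, 7])


@pytest.mark.parametrize(
    "p,expected_rejects",
    [
        ([0.01, 0.02, 0.03, 0.04], 4),
        ([1.0, 1.0, 1.0], 0),
        ([0.001, 0.8, 0.9], 1),
    ],
)
def test_bh_known_cases(p, expected_rejects):
    q, rej = bh_correct(p, alpha=0.05)
    assert rej.sum() == expected_rejects


def _bh_brute(p, alpha):
    """Literal step-up: largest i with p_(i) <= i*alpha/m."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m:
            k = i
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    return rejected


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
       st.floats(0.01, 0.2))
def test_bh_matches_step_up_enumeration(p, alpha):
    _, rej = bh_correct(p, alpha)
    assert np.array_equal(rej, _bh_brute(p, alpha))


# --------------------------------------------------------------------------
# grouped repeated screen


@pytest.fixture(scope="module")
def small_screen():
    cohort = generate_cohort(CohortSpec(seed=21))
    fm = FeatureMatrix(values=cohort.psf_frame())
    panel = generate_immune_panel(
        cohort,
        ImmunePanelSpec(n_immune_features=40, n_true_signal_features=6,
                        noise_sd=0.3, seed=21),
    )
    res = grouped_repeated_cv(panel, fm, RidgeConfig(n_repetitions=2, seed=9))
    return cohort, fm, panel, res


def test_group_integrity(small_screen):
    """Each patient's four rows always share a fold; folds are disjoint."""
    _, _, panel, res = small_screen
    info = res.ensemble.slice_info
    for r in range(2):
        fold_sets = [set(s["test_patients"]) for s in info
                     if s["repetition"] == r]
        all_pat = [p for s in fold_sets for p in s]
        assert len(all_pat) == len(set(all_pat))  # disjoint
        assert set(all_pat) == set(panel.patient_ids)  # partition


def test_screen_reports_every_feature(small_screen):
    _, _, panel, res = small_screen
    assert list(res.table["feature"]) == panel.feature_names
    assert res.table["mean_rho"].between(-1, 1).all()
    assert (res.table["significant"] == (res.table["q"] < 0.05)).all()


def test_mean_p_is_arithmetic_mean_over_repetitions(small_screen):
    _, _, _, res = small_screen
    assert np.allclose(
        res.table["mean_p"].to_numpy(),
        res.per_repetition_p.mean(axis=0).to_numpy(),
        equal_nan=True,
    )


def test_alpha_selection_ignores_test_fold_data(small_screen):
    """Poisoning one patient's immune values leaves every fit in which that
    patient was held out bitwise unchanged (no train-side leakage)."""
    cohort, fm, panel, res = small_screen
    victim = panel.patient_ids[0]
    poisoned = panel.data.copy()
    rows = poisoned["patient_id"] == victim
    rng = np.random.default_rng(0)
    poisoned.loc[rows, panel.feature_names] = rng.standard_normal(
        (rows.sum(), len(panel.feature_names))
    )
    panel2 = type(panel)(
        data=poisoned,
        feature_names=panel.feature_names,
        signal_features=panel.signal_features,
        planted_coefficients=panel.planted_coefficients,
        timepoint_effect=panel.timepoint_effect,
        design=panel.design,
    )
    res2 = grouped_repeated_cv(panel2, fm, RidgeConfig(n_repetitions=2, seed=9))
    for i, info in enumerate(res.ensemble.slice_info):
        if victim in info["test_patients"]:
            assert np.array_equal(res.ensemble.coefs[i], res2.ensemble.coefs[i])
            assert np.array_equal(
                res.ensemble.intercepts[i], res2.ensemble.intercepts[i]
            )


def test_noiseless_signal_feature_is_significant():
    """An exactly linear feature is recovered with near-perfect rho."""
    cohort = generate_cohort(
        CohortSpec(
            n_patients=220,
            outcome_case_counts={"hypertension": 18, "diabetes": 11,
                                 "gestational_diabetes": 29,
                                 "superimposed_pree": 6, "severe_pree": 13,
                                 "preterm": 17},
            n_any_aporf=None,
            psf_missing_rate=0.0,  # imputation would break exact linearity
            seed=22,
        )
    )
    fm = FeatureMatrix(values=cohort.psf_frame())
    # identifiability needs more distinct patients than predictors: the four
    # rows of one patient share a single PSF vector
    panel = generate_immune_panel(
        cohort,
        ImmunePanelSpec(n_immune_patients=150, n_immune_features=10,
                        n_true_signal_features=3, noise_sd=0.0, seed=22),
    )
    res = grouped_repeated_cv(panel, fm, RidgeConfig(n_repetitions=2, seed=3))
    tab = res.table.set_index("feature").loc[panel.signal_features]
    assert (tab["mean_rho"] >= 0.99).all()
    assert tab["significant"].all()


def test_power_monotone_in_signal_scale():
    """More planted effect size -> no fewer discoveries (3-point check)."""
    cohort = generate_cohort(CohortSpec(seed=23))
    fm = FeatureMatrix(values=cohort.psf_frame())
    counts = []
    for scale in (0.0, 0.08, 0.8):
        panel = generate_immune_panel(
            cohort,
            ImmunePanelSpec(n_immune_features=30, n_true_signal_features=10,
                            signal_coefficient_scale=scale, noise_sd=0.3,
                            timepoint_effect=(0.0, 0.0, 0.0, 0.0),
                            seed=23),
        )
        res = grouped_repeated_cv(panel, fm,
                                  RidgeConfig(n_repetitions=2, seed=4))
        counts.append(int(res.table["significant"].sum()))
    assert counts[0] <= counts[1] <= counts[2]


def test_too_few_patients_raises(small_screen):
    cohort, fm, panel, _ = small_screen
    few = panel.data[panel.data["patient_id"].isin(panel.patient_ids[:5])]
    panel2 = type(panel)(
        data=few, feature_names=panel.feature_names,
        signal_features=panel.signal_features,
        planted_coefficients=panel.planted_coefficients,
        timepoint_effect=panel.timepoint_effect, design=panel.design,
    )
    with pytest.raises(ValueError, match="k_outer"):
        grouped_repeated_cv(panel2, fm, RidgeConfig(seed=0))
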