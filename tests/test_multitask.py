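"""Network construction, training behaviour, K-fold evaluation, comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from stressmtl.multitask import (
    PerformanceDistribution,
    auroc,
    compare_models,
    evaluate_repeated_kfold,
    stars,
)
from stressmtl.nn import MultitaskNet, NetworkConfig
from stressmtl.prep import FeatureMatrix

SEVEN_TASKS = [
    ("gestational_diabetes", "binary"), ("severe_pree", "binary"),
    ("superimposed_pree", "binary"), ("diabetes", "binary"),
    ("hypertension", "binary"), ("ga_delivery", "numeric"), ("bmi", "numeric"),
]


def _affine(n_in, n_out):
    return n_in * n_out + n_out


def _module_params(h):
    # task module: affine + batch-norm scale/shift
    return _affine(h, h) + 2 * h


def test_multitask_model_exposes_all_named_outputs():
    cfg = NetworkConfig(n_features=79, task_specs=SEVEN_TASKS, seed=0)
    net = MultitaskNet(cfg)
    X = np.zeros((4, 79))
    preds = net.predict(X)
    assert set(preds) == {n for n, _ in SEVEN_TASKS}


def test_singletask_with_two_tasks_rejected():
    cfg = NetworkConfig(n_features=5, task_specs=SEVEN_TASKS[:2], seed=0)
    with pytest.raises(ValueError, match="exactly one task"):
        MultitaskNet(cfg, multitask=False)


def test_parameter_count_matches_closed_form():
    """Single-task net = multitask net restricted to one head."""
    h = 150
    cfg = NetworkConfig(n_features=79, task_specs=SEVEN_TASKS, seed=0)
    net = MultitaskNet(cfg)
    shared = _affine(79, h) + 2 * (_module_params(h))
    per_task = _module_params(h) + _affine(h, 1)
    assert net.n_parameters() == shared + 7 * per_task
    scfg = NetworkConfig(n_features=79, task_specs=[SEVEN_TASKS[0]], seed=0)
    snet = MultitaskNet(scfg, multitask=False)
    assert snet.n_parameters() == shared + per_task


def test_separable_task_reaches_perfect_training_auroc():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 5))
    X[:, 0] = np.sign(X[:, 0]) * (0.5 + np.abs(X[:, 0]))  # margin at 0
    y = (X[:, 0] > 0).astype(float)
    cfg = NetworkConfig(n_features=5, task_specs=[("t", "binary")], seed=0,
                        learning_rate=1e-2)
    net = MultitaskNet(cfg, multitask=False).fit(X, {"t": y})
    assert auroc(y, net.predict(X)["t"]) == 1.0
    assert net.n_epochs_run <= 35


def test_constant_zero_loss_stops_via_patience():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((40, 3))
    y = rng.standard_normal(40)
    cfg = NetworkConfig(
        n_features=3, task_specs=[("v", "numeric")], mse_scale=0.0, seed=0
    )
    net = MultitaskNet(cfg, multitask=False).fit(X, {"v": y})
    assert net.n_epochs_run <= 1 + cfg.patience


def test_missing_inputs_rejected():
    cfg = NetworkConfig(n_features=2, task_specs=[("t", "binary")], seed=0)
    X = np.array([[1.0, np.nan]] * 10)
    with pytest.raises(ValueError, match="missing"):
        MultitaskNet(cfg).fit(X, {"t": np.zeros(10)})


@pytest.mark.parametrize(
    "y_true,y_score,expected",
    [
        ([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], 1.0),
        ([0, 1, 0, 1], [0.9, 0.8, 0.2, 0.1], 0.25),
    ],
)
def test_auroc_known_values(y_true, y_score, expected):
    assert auroc(y_true, y_score) == pytest.approx(expected)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 12), st.integers(2, 12))
def test_auroc_equals_mann_whitney_oracle(seed, npos, nneg):
    """AUROC == U / (n+ * n-) with ties counted half."""
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 6, npos + nneg).astype(float)  # force ties
    y = np.r_[np.ones(npos), np.zeros(nneg)]
    pos, neg = scores[:npos], scores[npos:]
    u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    assert auroc(y, scores) == pytest.approx(u / (npos * nneg))


def _tiny_eval(n_repetitions=2):
    from stressmtl.synthetic import CohortSpec, generate_cohort

    c = generate_cohort(
        CohortSpec(
            n_patients=80,
            outcome_case_counts={"a": 16, "b": 10},
            n_any_aporf=20,
            psf_block_sizes=[5, 5, 5],
            seed=3,
        )
    )
    fm = FeatureMatrix(values=c.psf_frame())
    Y = c.data[["a", "b"]]
    cfg = NetworkConfig(
        n_features=15, task_specs=[("a", "binary"), ("b", "binary")],
        hidden_units=16, seed=5,
    )
    return evaluate_repeated_kfold(fm, Y, cfg, k=5, n_repetitions=n_repetitions)


def test_kfold_split_integrity_and_shared_splits():
    """Folds partition patients; both model classes see identical splits."""
    res = _tiny_eval()
    assert res.split_hashes["multitask"] == res.split_hashes["singletask"]
    preds = res.predictions
    for (task, mc, rep), grp in preds.groupby(["task", "model_class",
                                               "repetition"]):
        # each patient held out exactly once per repetition
        assert grp["patient_id"].is_unique
        assert len(grp) == 80


def test_kfold_stratification_balance():
    """Composite positives per fold deviate from n_pos/k by at most 1."""
    res = _tiny_eval(n_repetitions=1)
    preds = res.predictions
    mt = preds[(preds.model_class == "multitask")]
    pos_by_patient = (
        mt.pivot_table(index="patient_id", columns="task", values="y_true")
        .gt(0).any(axis=1)
    )
    fold_of = mt.drop_duplicates("patient_id").set_index("patient_id")["fold"]
    per_fold = pos_by_patient.groupby(fold_of).sum()
    expected = pos_by_patient.sum() / 5
    assert (per_fold - expected).abs().max() <= 1.0


def test_stars_thresholds():
    assert stars(0.2) == "ns"
    assert stars(0.03) == "*"
    assert stars(0.009) == "**"
    assert stars(0.0009) == "***"
    assert stars(0.00009) == "****"


def _exact_signed_rank_p(d):
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = 0
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.asarray(w_all)
    mu = w_all.mean()
    extreme = np.sum(np.abs(w_all - mu) >= abs(w_obs - mu) - 1e-9)
    return extreme / len(w_all)


def test_compare_models_identical_is_ns():
    a = PerformanceDistribution("t", "multitask", "auroc", np.full(10, 0.7))
    b = PerformanceDistribution("t", "singletask", "auroc", np.full(10, 0.7))
    p, s = compare_models(a, b)
    assert p == 1.0 and s == "ns"


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 5000), st.integers(5, 9))
def test_paired_wilcoxon_matches_exact_enumeration(seed, n):
    rng = np.random.default_rng(seed)
    xa = rng.standard_normal(n)
    xb = xa + rng.standard_normal(n) * 0.5 + 0.3
    a = PerformanceDistribution("t", "multitask", "auroc", xa)
    b = PerformanceDistribution("t", "singletask", "auroc", xb)
    p, _ = compare_models(a, b)
    assert p == pytest.approx(_exact_signed_rank_p(xa - xb), abs=1e-9)


def test_unpaired_ranksum_variant():
    a = PerformanceDistribution("t", "multitask", "auroc",
                                np.array([0.9, 0.8, 0.85, 0.95]))
    b = PerformanceDistribution("t", "singletask", "auroc",
                                np.array([0.5, 0.55, 0.52]))
    p, _ = compare_models(a, b, paired=False)
    assert p == pytest.approx(stats.ranksums(a.samples, b.samples).pvalue)
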