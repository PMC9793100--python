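"""Repeated stratified K-fold comparison of multitask vs single-task nets.

Both model classes are evaluated on identical stratified 5-fold splits
within each repetition; held-out predictions are pooled over the folds of
a repetition and summarised as one AUROC (binary tasks) or Spearman rho
(numeric tasks) per task per repetition.  Distributions over repetitions
are compared with the Wilcoxon test and annotated with the usual
significance stars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .nn import MultitaskNet, NetworkConfig
from .prep import FeatureMatrix, scale_features

log = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class PerformanceDistribution:
    task: str
    model_class: str  # "multitask" | "singletask"
    metric: str  # "auroc" | "spearman_rho"
    samples: np.ndarray


@dataclass
class KFoldResult:
    distributions: list[PerformanceDistribution]
    predictions: pd.DataFrame  # task, model_class, repetition, fold, patient_id, y_true, y_score
    split_hashes: dict[str, list[int]] = field(default_factory=dict)

    def get(self, task: str, model_class: str) -> PerformanceDistribution:
        for d in self.distributions:
            if d.task == task and d.model_class == model_class:
                return d
        raise KeyError((task, model_class))

    def comparison_table(self, paired: bool = True) -> pd.DataFrame:
        rows = []
        tasks = sorted({d.task for d in self.distributions})
        for t in tasks:
            mt, st = self.get(t, "multitask"), self.get(t, "singletask")
            p, star = compare_models(mt, st, paired=paired)
            rows.append(
                {
                    "task": t,
                    "metric": mt.metric,
                    "multitask_median": float(np.median(mt.samples)),
                    "singletask_median": float(np.median(st.samples)),
                    "p_value": p,
                    "stars": star,
                }
            )
        return pd.DataFrame(rows)


def _as_matrix(X, train_idx, test_idx):
    """Per-fold scaling for a FeatureMatrix; passthrough for arrays."""
    if isinstance(X, FeatureMatrix):
        scaled = scale_features(X, fit_rows=X.values.index[train_idx])
        arr = scaled.values.to_numpy()
        return arr[train_idx], arr[test_idx]
    arr = np.asarray(X, dtype=float)
    return arr[train_idx], arr[test_idx]


def _composite_label(Y: pd.DataFrame, cfg: NetworkConfig) -> np.ndarray:
    """Stratification label: any-positive across the binary tasks."""
    binary = [n for n, k in cfg.task_specs if k == "binary"]
    if not binary:
        return np.zeros(len(Y), dtype=int)
    return (Y[binary].to_numpy() > 0).any(axis=1).astype(int)


def evaluate_repeated_kfold(
    X,
    Y: pd.DataFrame,
    cfg: NetworkConfig,
    k: int = 5,
    n_repetitions: int = 20,
    model_classes: tuple[str, ...] = ("multitask", "singletask"),
    keep_predictions: bool = True,
) -> KFoldResult:
    """Repeated stratified K-fold evaluation of both model classes.

    ``X`` is a FeatureMatrix (scaled per fold on training rows only) or a
    complete numeric array; ``Y`` a DataFrame with one column per task in
    ``cfg.task_specs``.  Numeric targets are standardised with
    training-fold statistics.  Returns per-repetition metric distributions
    for every task under every requested model class, computed on the
    pooled held-out predictions of each repetition.
    """
    cfg.validate()
    n = len(Y)
    strat = _composite_label(Y, cfg)
    ids = (
        X.values.index.to_numpy()
        if isinstance(X, FeatureMatrix)
        else Y.index.to_numpy()
    )

    samples: dict[tuple[str, str], list[float]] = {
        (name, mc): [] for name, _ in cfg.task_specs for mc in model_classes
    }
    pred_rows = []
    split_hashes: dict[str, list[int]] = {mc: [] for mc in model_classes}

    for rep in range(n_repetitions):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed + rep)
        folds = list(skf.split(np.zeros(n), strat))
        pooled: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = {
            key: [] for key in samples
        }
        for fold_idx, (tr, te) in enumerate(folds):
            Xtr, Xte = _as_matrix(X, tr, te)
            fold_seed = cfg.seed + 1000 * rep + 10 * fold_idx
            ytr_raw = {name: Y[name].to_numpy()[tr] for name, _ in cfg.task_specs}
            yte_raw = {name: Y[name].to_numpy()[te] for name, _ in cfg.task_specs}
            # standardise numeric targets on training-fold statistics
            ytr = dict(ytr_raw)
            for name, kind in cfg.task_specs:
                if kind == "numeric":
                    mu, sd = ytr_raw[name].mean(), ytr_raw[name].std()
                    ytr[name] = (ytr_raw[name] - mu) / (sd if sd > 0 else 1.0)

            for mc in model_classes:
                if mc == "multitask":
                    mcfg = _with(cfg, seed=fold_seed)
                    net = MultitaskNet(mcfg, multitask=True).fit(Xtr, ytr)
                    preds = net.predict(Xte)
                else:
                    preds = {}
                    for ti, (name, kind) in enumerate(cfg.task_specs):
                        scfg = _with(
                            cfg,
                            task_specs=[(name, kind)],
                            seed=fold_seed + 100000 * (ti + 1),
                        )
                        net = MultitaskNet(scfg, multitask=False).fit(
                            Xtr, {name: ytr[name]}
                        )
                        preds[name] = net.predict(Xte)[name]
                for name, kind in cfg.task_specs:
                    pooled[(name, mc)].append((yte_raw[name], preds[name]))
                    if keep_predictions:
                        for pid, yt, ys in zip(ids[te], yte_raw[name], preds[name]):
                            pred_rows.append(
                                (name, mc, rep, fold_idx, pid, float(yt), float(ys))
                            )
                split_hashes[mc].append(
                    hash(tuple(np.sort(te).tolist()) + (rep,))
                )

        for (name, mc), chunks in pooled.items():
            y_true = np.concatenate([c[0] for c in chunks])
            y_score = np.concatenate([c[1] for c in chunks])
            kind = dict(cfg.task_specs)[name]
            if kind == "binary":
                if len(np.unique(y_true)) < 2:
                    log.warning(
                        "repetition %d: single-class truth for %s; metric skipped",
                        rep, name,
                    )
                    continue
                samples[(name, mc)].append(float(roc_auc_score(y_true, y_score)))
            else:
                rho = stats.spearmanr(y_true, y_score).statistic
                samples[(name, mc)].append(float(rho))

    dists = [
        PerformanceDistribution(
            task=name,
            model_class=mc,
            metric="auroc" if dict(cfg.task_specs)[name] == "binary" else "spearman_rho",
            samples=np.asarray(vals),
        )
        for (name, mc), vals in samples.items()
    ]
    preds_df = pd.DataFrame(
        pred_rows,
        columns=["task", "model_class", "repetition", "fold", "patient_id",
                 "y_true", "y_score"],
    )
    return KFoldResult(distributions=dists, predictions=preds_df,
                       split_hashes=split_hashes)


def _with(cfg: NetworkConfig, **kw) -> NetworkConfig:
    d = {**cfg.__dict__}
    d.update(kw)
    return NetworkConfig(**d)


def stars(p: float) -> str:
    if np.isnan(p) or p > 0.05:
        return "ns"
    for thr, s in STAR_THRESHOLDS:
        if p <= thr:
            return s
    return "ns"


def compare_models(
    a: PerformanceDistribution, b: PerformanceDistribution, paired: bool = True
) -> tuple[float, str]:
    """Wilcoxon comparison of two metric distributions.

    Paired (signed-rank, matched by repetition — the default, since both
    model classes share splits) or unpaired (rank-sum).  All-equal paired
    samples give p = 1, "ns".
    """
    xa, xb = np.asarray(a.samples), np.asarray(b.samples)
    if paired:
        if len(xa) != len(xb):
            raise ValueError("paired comparison requires equal sample counts")
        if np.allclose(xa, xb):
            return 1.0, "ns"
        p = float(stats.wilcoxon(xa, xb).pvalue)
    else:
        p = float(stats.ranksums(xa, xb).pvalue)
    return p, stars(p)


def auroc(y_true, y_score) -> float:
    """Area under the ROC curve (probability of concordance)."""
    return float(roc_auc_score(np.asarray(y_true), np.asarray(y_score)))
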