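"""Ridge-regression screen linking stress factors to immune features.

Each immune feature is predicted from the questionnaire predictors plus a
timepoint integer (1-4: first/second/third trimester, postpartum) with
ridge regression.  Cross-validation is grouped by patient — all four
timepoints of a patient share a fold — shuffled, 10-fold, and repeated;
the penalty is chosen per feature by an inner grouped grid search over
(1, 0.1, 0.01, 0.001, 0.0001, 0), where alpha = 0 means minimum-norm least
squares (the design has more predictors than training rows).  Spearman rho
and p are computed per feature over each repetition's pooled held-out
predictions, averaged over repetitions, and screened with
Benjamini-Hochberg FDR at alpha 0.05.  Every fitted coefficient vector is
retained in a :class:`RidgeEnsemble` for the downstream linear generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .prep import FeatureMatrix
from .synthetic import ImmunePanel

DEFAULT_ALPHA_GRID = (1.0, 0.1, 0.01, 0.001, 0.0001, 0.0)
TIMEPOINT_CODES = (1, 2, 3, 4)


@dataclass
class RidgeConfig:
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID
    k_outer: int = 10
    k_inner: int = 5
    n_repetitions: int = 50
    fdr_alpha: float = 0.05
    p_combine: str = "mean"  # "mean" (as screened) or "median"
    seed: int = 0

    def validate(self) -> None:
        if any(a < 0 for a in self.alpha_grid):
            raise ValueError("alphas must be >= 0")
        if self.k_outer < 2:
            raise ValueError("k_outer must be >= 2")
        if self.p_combine not in ("mean", "median"):
            raise ValueError("p_combine must be 'mean' or 'median'")


class RidgeFit(NamedTuple):
    coef: np.ndarray  # (n_pred,) or (n_pred, n_targets)
    intercept: np.ndarray  # scalar array or (n_targets,)


def ridge_fit(X: np.ndarray, y: np.ndarray, alpha: float) -> RidgeFit:
    """Closed-form ridge with intercept; alpha = 0 is minimum-norm OLS.

    Minimises ||y - X b - c||^2 + alpha ||b||^2.  X and y are centred
    internally so the intercept is exact; supports multi-target y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = X.mean(axis=0)
    ym = np.atleast_1d(y.mean(axis=0))
    Xc = X - xm
    yc = y - y.mean(axis=0)
    if alpha > 0:
        p = X.shape[1]
        coef = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(p), Xc.T @ yc)
    else:
        coef = np.linalg.pinv(Xc) @ yc
    intercept = np.squeeze(ym - xm @ coef.reshape(X.shape[1], -1))
    return RidgeFit(coef=coef, intercept=intercept)


def add_timepoint(X: np.ndarray | pd.DataFrame, timepoints: Sequence[int]):
    """Append the timepoint integer as one extra predictor column."""
    tps = np.asarray(timepoints)
    bad = set(np.unique(tps)) - set(TIMEPOINT_CODES)
    if bad:
        raise ValueError(f"unknown timepoint code(s): {sorted(bad)}")
    if isinstance(X, pd.DataFrame):
        out = X.copy()
        out["timepoint"] = tps.astype(float)
        return out
    if len(X) == 0:
        return np.empty((0, X.shape[1] + 1))
    return np.column_stack([X, tps.astype(float)])


def bh_correct(p: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted q-values and rejection mask."""
    p = np.asarray(p, dtype=float)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class RidgeEnsemble:
    """Every per-(repetition, fold) ridge fit of the screen.

    Coefficients live in the space [unit-variance-scaled PSFs, raw
    timepoint]; the per-slice training scaler (mean, sd per predictor, with
    identity entries for the timepoint) is retained so the averaged
    generator can be applied to raw questionnaire features.
    """

    coefs: np.ndarray  # (n_slices, n_immune, n_pred) float32
    intercepts: np.ndarray  # (n_slices, n_immune)
    scaler_mean: np.ndarray  # (n_slices, n_pred)
    scaler_sd: np.ndarray  # (n_slices, n_pred)
    predictor_names: list[str]
    immune_feature_names: list[str]
    slice_info: list[dict] = field(default_factory=list)  # rep, fold, test patients
    provenance: dict = field(default_factory=dict)

    @property
    def n_slices(self) -> int:
        return self.coefs.shape[0]


@dataclass
class ScreenResult:
    """Per-immune-feature predictability plus the fitted ensemble."""

    table: pd.DataFrame  # feature, mean_rho, mean_p, q, significant
    per_repetition_rho: pd.DataFrame  # repetitions x features
    per_repetition_p: pd.DataFrame
    ensemble: RidgeEnsemble
    config: RidgeConfig

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "feature"])


def _rank(a: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, a)


def _spearman_columns(truth: np.ndarray, pred: np.ndarray):
    """Per-column Spearman rho and two-sided t-approximation p."""
    n = truth.shape[0]
    rt, rp = _rank(truth), _rank(pred)
    rt = rt - rt.mean(axis=0)
    rp = rp - rp.mean(axis=0)
    denom = np.sqrt((rt**2).sum(axis=0) * (rp**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rt * rp).sum(axis=0) / denom
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(rho)] = np.nan
    return rho, p


def _patient_folds(rng: np.random.Generator, patients: np.ndarray, k: int):
    order = rng.permutation(patients)
    return [fold for fold in np.array_split(order, k) if len(fold)]


def _scale_train(Xtr: np.ndarray, Xte: np.ndarray, n_psf: int):
    """Unit-variance scale + centre the PSF columns on training rows;
    mean-impute missing; centre (but do not rescale) nothing else."""
    mean = np.nanmean(Xtr[:, :n_psf], axis=0)
    sd = np.nanstd(Xtr[:, :n_psf], axis=0, ddof=1)
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    mean[~np.isfinite(mean)] = 0.0

    def apply(X):
        out = X.copy()
        out[:, :n_psf] = (out[:, :n_psf] - mean) / sd
        out[:, :n_psf] = np.nan_to_num(out[:, :n_psf], nan=0.0)
        return out

    full_mean = np.concatenate([mean, np.zeros(Xtr.shape[1] - n_psf)])
    full_sd = np.concatenate([sd, np.ones(Xtr.shape[1] - n_psf)])
    return apply(Xtr), apply(Xte), full_mean, full_sd


def grouped_repeated_cv(
    panel: ImmunePanel, fm: FeatureMatrix, cfg: RidgeConfig
) -> ScreenResult:
    """The full repeated, grouped, alpha-searched ridge screen.

    ``fm`` holds the raw (unscaled) questionnaire predictors for at least
    the panel's patients; scaling is re-estimated inside every outer
    training portion.  Repetition ``r`` uses seed ``cfg.seed + r`` so each
    repetition is individually reproducible.
    """
    cfg.validate()
    patients = np.asarray(panel.patient_ids)
    if len(patients) < cfg.k_outer:
        raise ValueError(
            f"need at least k_outer={cfg.k_outer} patients, have {len(patients)}"
        )
    missing = [p for p in patients if p not in fm.values.index]
    if missing:
        raise ValueError(f"panel patients missing from feature matrix: {missing}")

    psf_names = list(fm.values.columns)
    n_psf = len(psf_names)
    feat_names = panel.feature_names
    rows = panel.data
    X_raw = add_timepoint(
        fm.values.loc[rows["patient_id"]].to_numpy(),
        rows["timepoint"].to_numpy(),
    )
    Ytruth = rows[feat_names].to_numpy()
    row_patient = rows["patient_id"].to_numpy()
    n_rows, n_imm = Ytruth.shape
    grid = list(cfg.alpha_grid)

    rep_rho = np.empty((cfg.n_repetitions, n_imm))
    rep_p = np.empty((cfg.n_repetitions, n_imm))
    coef_slices, icpt_slices, mean_slices, sd_slices = [], [], [], []
    slice_info: list[dict] = []

    for r in range(cfg.n_repetitions):
        rng = np.random.default_rng(cfg.seed + r)
        folds = _patient_folds(rng, patients, cfg.k_outer)
        pred = np.full_like(Ytruth, np.nan)
        for fold_idx, test_patients in enumerate(folds):
            te = np.isin(row_patient, test_patients)
            tr = ~te
            Xtr, Xte, sc_mean, sc_sd = _scale_train(X_raw[tr], X_raw[te], n_psf)
            Ytr = Ytruth[tr]
            tr_patients = np.asarray(
                [p for p in patients if p not in set(test_patients)]
            )

            # inner grouped grid search: per-feature best alpha by MSE
            k_in = min(cfg.k_inner, len(tr_patients))
            in_folds = _patient_folds(rng, tr_patients, k_in)
            sse = np.zeros((len(grid), n_imm))
            tr_pat_rows = row_patient[tr]
            for val_patients in in_folds:
                val = np.isin(tr_pat_rows, val_patients)
                fit_rows = ~val
                for ai, alpha in enumerate(grid):
                    f = ridge_fit(Xtr[fit_rows], Ytr[fit_rows], alpha)
                    resid = Xtr[val] @ f.coef + f.intercept - Ytr[val]
                    sse[ai] += (resid**2).sum(axis=0)
            best_alpha_idx = np.argmin(sse, axis=0)

            # final fits on the whole training portion, one per grid alpha,
            # assembled per feature from the selected alpha
            coef = np.empty((X_raw.shape[1], n_imm))
            icpt = np.empty(n_imm)
            for ai, alpha in enumerate(grid):
                cols = np.flatnonzero(best_alpha_idx == ai)
                if cols.size == 0:
                    continue
                f = ridge_fit(Xtr, Ytr[:, cols], alpha)
                coef[:, cols] = f.coef.reshape(X_raw.shape[1], -1)
                icpt[cols] = np.atleast_1d(f.intercept)
            pred[te] = Xte @ coef + icpt

            coef_slices.append(coef.T.astype(np.float32))
            icpt_slices.append(icpt.astype(np.float32))
            mean_slices.append(sc_mean.astype(np.float32))
            sd_slices.append(sc_sd.astype(np.float32))
            slice_info.append(
                {"repetition": r, "fold": fold_idx,
                 "test_patients": list(test_patients)}
            )

        rho, p = _spearman_columns(Ytruth, pred)
        rep_rho[r] = rho
        rep_p[r] = p

    combine = np.nanmean if cfg.p_combine == "mean" else np.nanmedian
    mean_rho = np.nanmean(rep_rho, axis=0)
    mean_p = combine(rep_p, axis=0)
    q, reject = bh_correct(np.nan_to_num(mean_p, nan=1.0), cfg.fdr_alpha)

    table = pd.DataFrame(
        {
            "feature": feat_names,
            "mean_rho": mean_rho,
            "mean_p": mean_p,
            "q": q,
            "significant": reject,
        }
    )
    ensemble = RidgeEnsemble(
        coefs=np.stack(coef_slices),
        intercepts=np.stack(icpt_slices),
        scaler_mean=np.stack(mean_slices),
        scaler_sd=np.stack(sd_slices),
        predictor_names=psf_names + ["timepoint"],
        immune_feature_names=list(feat_names),
        slice_info=slice_info,
        provenance={
            "k_outer": cfg.k_outer,
            "n_repetitions": cfg.n_repetitions,
            "alpha_grid": list(map(float, grid)),
            "seed": cfg.seed,
        },
    )
    return ScreenResult(
        table=table,
        per_repetition_rho=pd.DataFrame(rep_rho, columns=feat_names),
        per_repetition_p=pd.DataFrame(rep_p, columns=feat_names),
        ensemble=ensemble,
        config=cfg,
    )
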