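"""Synthetic cohort, questionnaire, and immune-panel generators.

The study data behind this pipeline (a pregnancy cohort with a copyrighted
stress questionnaire and a CyTOF immune sub-panel) are not redistributable,
so every downstream stage is developed and tested against synthetic cohorts
that reproduce the statistical structure those stages assume:

* correlated rare binary outcomes produced by a latent multivariate-Gaussian
  liability model with quantile thresholding, repaired by minimal label swaps
  so the per-outcome case counts and the "any adverse outcome" union hit the
  configured values exactly;
* psychosocial/stress factors (PSFs) drawn from a block-correlated Gaussian
  and partially discretised to the binary / 8-point ordinal scales of a
  questionnaire, with missing-completely-at-random masking;
* an immune panel of repeated measurements (4 timepoints per patient) where
  a configurable subset of features is genuinely linear in the PSFs, so that
  recovery by the ridge screen can be verified against planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

OUTCOME_NAMES = (
    "hypertension",
    "diabetes",
    "gestational_diabetes",
    "superimposed_pree",
    "severe_pree",
    "preterm",
)

#: Outcomes modelled as prediction tasks: 4 adverse pregnancy outcomes
#: (gestational diabetes, the two preeclampsia variants, gestational age at
#: delivery as the continuous surrogate for preterm birth) and 3
#: pre-pregnancy risk factors (diabetes, hypertension, BMI).
APO_TASKS = ("gestational_diabetes", "superimposed_pree", "severe_pree", "ga_delivery")
RF_TASKS = ("diabetes", "hypertension", "bmi")

DEFAULT_CASE_COUNTS: dict[str, int] = {
    "hypertension": 18,
    "diabetes": 11,
    "gestational_diabetes": 29,
    "superimposed_pree": 6,
    "severe_pree": 13,
    "preterm": 17,
}

# 15 correlated questionnaire blocks totalling 79 retained predictors.
DEFAULT_PSF_BLOCK_SIZES: tuple[int, ...] = (6, 6, 6, 6) + (5,) * 11


class ConstraintError(ValueError):
    """Raised when a cohort specification is infeasible."""


def default_outcome_corr(names: Sequence[str] = OUTCOME_NAMES) -> pd.DataFrame:
    """Latent outcome correlation built from a 3-factor loading structure.

    Factor 1 is a metabolic/vascular axis (hypertension, diabetes,
    gestational diabetes, superimposed preeclampsia), factor 2 a
    preeclampsia axis, factor 3 a prematurity axis.  A loading construction
    ``L L' + diag`` guarantees a positive semi-definite matrix with the
    tightly connected hypertension/diabetes/superimposed-preeclampsia
    cluster seen in first-trimester cohorts.
    """
    base = pd.DataFrame(
        [
            # htn   diab  gdm   sup   sev   pre
            [1.00, 0.80, 0.60, 0.85, 0.45, 0.30],
            [0.80, 1.00, 0.70, 0.78, 0.40, 0.30],
            [0.60, 0.70, 1.00, 0.50, 0.35, 0.40],
            [0.85, 0.78, 0.50, 1.00, 0.65, 0.50],
            [0.45, 0.40, 0.35, 0.65, 1.00, 0.75],
            [0.30, 0.30, 0.40, 0.50, 0.75, 1.00],
        ],
        index=list(OUTCOME_NAMES),
        columns=list(OUTCOME_NAMES),
    )
    sub = base.reindex(index=list(names), columns=list(names))
    fill = 0.35  # outcomes outside the canonical set: moderately related
    sub = sub.fillna(fill)
    np.fill_diagonal(sub.values, 1.0)
    # guard the nearest-PSD requirement after any subsetting/filling
    w, V = np.linalg.eigh(sub.to_numpy())
    if w.min() < 1e-8:
        C = V @ np.diag(np.clip(w, 1e-8, None)) @ V.T
        d = np.sqrt(np.diag(C))
        sub = pd.DataFrame(C / np.outer(d, d), index=sub.index, columns=sub.columns)
    return sub


def default_effect_matrix(
    block_sizes: Sequence[int],
    outcome_names: Sequence[str],
    strength: float = 1.0,
) -> np.ndarray:
    """Planted PSF -> outcome-liability loadings, disjoint blocks per outcome.

    Each outcome draws primary signal from two questionnaire blocks of its
    own (disjoint across outcomes while blocks last); the cohort generator
    then mixes these independent signal components through the Cholesky
    factor of the outcome correlation, so correlated outcomes share
    predictor effects in proportion to their correlation — the regime where
    multitask learning helps.
    """
    n_psf = int(np.sum(block_sizes))
    starts = np.concatenate([[0], np.cumsum(block_sizes)])
    B = np.zeros((n_psf, len(outcome_names)))
    n_blocks = len(block_sizes)
    for j in range(len(outcome_names)):
        for b in ((2 * j) % n_blocks, (2 * j + 1) % n_blocks):
            sl = slice(starts[b], starts[b + 1])
            B[sl, j] = strength / np.sqrt(block_sizes[b])
    return B


@dataclass
class CohortSpec:
    """Configuration of one synthetic cohort.

    ``psf_signal_fraction`` is the share of each outcome's liability
    variance explained by the planted PSF effects (0 = outcomes independent
    of the questionnaire).
    """

    n_patients: int = 200
    outcome_case_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CASE_COUNTS)
    )
    n_any_aporf: int | None = 52
    outcome_latent_corr: pd.DataFrame | None = None
    psf_block_sizes: Sequence[int] = DEFAULT_PSF_BLOCK_SIZES
    psf_block_corr: float = 0.6
    psf_effect_matrix: np.ndarray | None = None
    psf_signal_fraction: float = 0.25
    psf_missing_rate: float = 0.05
    ga_questionnaire_median_weeks: float = 11.0
    ga_questionnaire_log_sd: float = 0.30
    seed: int = 0

    @property
    def outcome_names(self) -> list[str]:
        return list(self.outcome_case_counts)

    @property
    def n_psf(self) -> int:
        return int(np.sum(self.psf_block_sizes))

    def resolved_corr(self) -> pd.DataFrame:
        corr = (
            default_outcome_corr(self.outcome_names)
            if self.outcome_latent_corr is None
            else self.outcome_latent_corr
        )
        return corr.loc[self.outcome_names, self.outcome_names]

    def validate(self) -> None:
        counts = self.outcome_case_counts
        for name, c in counts.items():
            if not 0 <= c <= self.n_patients:
                raise ConstraintError(
                    f"case count for {name!r} is {c}, outside [0, {self.n_patients}]"
                )
        if self.n_any_aporf is not None and counts:
            lo = max(counts.values())
            hi = min(sum(counts.values()), self.n_patients)
            if not lo <= self.n_any_aporf <= hi:
                raise ConstraintError(
                    f"n_any_aporf={self.n_any_aporf} outside achievable "
                    f"range [{lo}, {hi}]"
                )
        corr = self.resolved_corr().to_numpy()
        if not np.allclose(corr, corr.T):
            raise ConstraintError("outcome_latent_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ConstraintError("outcome_latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ConstraintError("outcome_latent_corr must be positive semi-definite")
        if not 0 <= self.psf_block_corr < 1:
            raise ConstraintError("psf_block_corr must be in [0, 1)")


@dataclass
class CohortTable:
    """Patients x (PSFs, outcome labels, metadata), plus planted truth."""

    data: pd.DataFrame  # indexed by patient_id
    psf_cols: list[str]
    outcome_binary_cols: list[str]
    outcome_numeric_cols: list[str]
    meta_cols: list[str]
    psf_blocks: np.ndarray | None = None
    psf_effects: np.ndarray | None = None
    liabilities: pd.DataFrame | None = None

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    def psf_frame(self) -> pd.DataFrame:
        return self.data[self.psf_cols]

    def outcome_frame(self) -> pd.DataFrame:
        return self.data[self.outcome_binary_cols + self.outcome_numeric_cols]

    def column_roles(self) -> dict[str, str]:
        roles: dict[str, str] = {}
        roles.update({c: "psf" for c in self.psf_cols})
        roles.update({c: "outcome_binary" for c in self.outcome_binary_cols})
        roles.update({c: "outcome_numeric" for c in self.outcome_numeric_cols})
        roles.update({c: "meta" for c in self.meta_cols})
        return roles

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(out / "cohort.csv")
        schema = {"index": "patient_id", "columns": self.column_roles()}
        (out / "cohort.schema.json").write_text(json.dumps(schema, indent=1))
        if self.psf_effects is not None:
            truth = {
                "psf_blocks": None
                if self.psf_blocks is None
                else self.psf_blocks.tolist(),
                "psf_effects": self.psf_effects.tolist(),
            }
            (out / "cohort.planted.json").write_text(json.dumps(truth))

    @classmethod
    def read(cls, out_dir: str | Path) -> "CohortTable":
        out = Path(out_dir)
        schema = json.loads((out / "cohort.schema.json").read_text())
        data = pd.read_csv(out / "cohort.csv", index_col=0)
        roles = schema["columns"]
        by_role: dict[str, list[str]] = {"psf": [], "outcome_binary": [],
                                         "outcome_numeric": [], "meta": []}
        for col, role in roles.items():
            by_role[role].append(col)
        return cls(
            data=data,
            psf_cols=by_role["psf"],
            outcome_binary_cols=by_role["outcome_binary"],
            outcome_numeric_cols=by_role["outcome_numeric"],
            meta_cols=by_role["meta"],
        )


def _block_gaussian(
    rng: np.random.Generator, n: int, block_sizes: Sequence[int], rho: float
) -> np.ndarray:
    """Standard-normal columns with within-block correlation rho."""
    cols = []
    for m in block_sizes:
        common = rng.standard_normal((n, 1))
        idio = rng.standard_normal((n, m))
        cols.append(np.sqrt(rho) * common + np.sqrt(1.0 - rho) * idio)
    return np.concatenate(cols, axis=1)


def _discretize_psfs(
    rng: np.random.Generator, latent: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Map latent Gaussian PSFs onto questionnaire scales.

    Column kinds cycle binary / 8-point ordinal / numeric, emulating the
    yes-no, rating-scale and free-numeric items of the instrument.  All
    transforms are monotone so rank correlations survive.
    """
    n, p = latent.shape
    out = np.empty_like(latent)
    kinds: list[str] = []
    for j in range(p):
        kind = ("binary", "ordinal", "numeric")[j % 3]
        kinds.append(kind)
        col = latent[:, j]
        if kind == "binary":
            thresh = rng.uniform(-1.0, 0.8)
            out[:, j] = (col > thresh).astype(float)
        elif kind == "ordinal":
            # 8-point scale via standard-normal octile cuts
            edges = np.quantile(col, np.linspace(0, 1, 9)[1:-1])
            out[:, j] = np.digitize(col, edges) + 1.0
        else:
            out[:, j] = np.round(col * 10.0 + 50.0, 1)
    return out, kinds


def _repair_union(
    labels: np.ndarray, liab: np.ndarray, target: int
) -> np.ndarray:
    """Label moves so the union of positives has exactly ``target`` patients,
    keeping every per-outcome count fixed.

    The affected set is chosen from the thresholded labels: when the natural
    union is too large, the weakest (fewest labels, lowest liability)
    patients are dropped and their labels moved to the highest-liability
    eligible patients that stay affected; when too small, the
    highest-liability unaffected patients each receive one label donated by
    a multiply-labelled patient.  Patients nearest the thresholds therefore
    trade labels first, and the construction terminates for every feasible
    target.
    """
    Y = labels.copy()
    n, m = Y.shape
    rowsum = Y.sum(axis=1)
    affected = np.flatnonzero(rowsum > 0)

    if len(affected) > target:
        # keep the strongest `target` affected patients
        strength = rowsum[affected] + 1e-9 * liab[affected].max(axis=1)
        keep = set(affected[np.argsort(strength)[::-1][:target]])
        for p in affected:
            if p in keep:
                continue
            for o in np.flatnonzero(Y[p] == 1):
                cand = [q for q in keep if Y[q, o] == 0]
                if not cand:
                    raise ConstraintError(
                        "no feasible label move for n_any_aporf target"
                    )
                q = max(cand, key=lambda q: liab[q, o])
                Y[p, o], Y[q, o] = 0, 1
    elif len(affected) < target:
        outside = np.flatnonzero(Y.sum(axis=1) == 0)
        order = outside[np.argsort(liab[outside].max(axis=1))[::-1]]
        for p in order[: target - len(affected)]:
            rowsum = Y.sum(axis=1)
            # outcomes with a donor that stays affected after donating
            opts = [
                o for o in range(m)
                if np.any((Y[:, o] == 1) & (rowsum >= 2))
            ]
            if not opts:
                raise ConstraintError(
                    "no feasible label move for n_any_aporf target"
                )
            o = max(opts, key=lambda o: liab[p, o])
            donors = np.flatnonzero((Y[:, o] == 1) & (rowsum >= 2))
            q = donors[np.argmin(liab[donors, o])]
            Y[q, o], Y[p, o] = 0, 1
    return Y


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw one cohort from the liability-threshold model.

    Binary outcome labels are the top-``count`` liabilities per outcome
    (exact marginal counts by construction), then swap-repaired to the
    configured union size.  Gestational age at delivery and pre-pregnancy
    BMI are continuous columns driven by the corresponding liabilities.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    outcome_names = spec.outcome_names
    m = len(outcome_names)

    ids = pd.Index([f"P{i:04d}" for i in range(n)], name="patient_id")

    # latent PSFs and their discretised questionnaire versions
    latent_psf = _block_gaussian(rng, n, spec.psf_block_sizes, spec.psf_block_corr)
    psf_vals, _ = _discretize_psfs(rng, latent_psf)
    psf_cols = [f"psf_{j:03d}" for j in range(spec.n_psf)]
    blocks = np.concatenate(
        [np.full(b, k) for k, b in enumerate(spec.psf_block_sizes)]
    )

    # outcome liabilities: correlated latent part + PSF signal sharing the
    # same correlation structure (mixed through the Cholesky factor), so
    # the liability correlation equals the configured matrix
    liab = np.zeros((n, m))
    if m:
        corr = spec.resolved_corr().to_numpy()
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(m))
        Z = rng.standard_normal((n, m)) @ chol.T
        B = spec.psf_effect_matrix
        mix = B is None
        if mix:
            B = default_effect_matrix(spec.psf_block_sizes, outcome_names)
        B = np.asarray(B, dtype=float)
        eta = np.sqrt(spec.psf_signal_fraction)
        S = latent_psf @ B
        col_sd = S.std(axis=0)
        keep = col_sd > 0
        S[:, keep] = (S[:, keep] - S[:, keep].mean(axis=0)) / col_sd[keep]
        if mix:
            S = S @ chol.T
            B = (B / np.where(keep, col_sd, 1.0)) @ chol.T
            keep = np.abs(S).std(axis=0) > 0
        liab = np.sqrt(1.0 - eta**2 * keep) * Z + eta * keep * S

    # exact per-outcome counts via top-k thresholding
    Y = np.zeros((n, m), dtype=int)
    for j, name in enumerate(outcome_names):
        k = spec.outcome_case_counts[name]
        if k > 0:
            Y[np.argsort(liab[:, j])[-k:], j] = 1
    if spec.n_any_aporf is not None and m:
        Y = _repair_union(Y, liab, spec.n_any_aporf)

    data = pd.DataFrame(psf_vals, index=ids, columns=psf_cols)
    # MCAR missingness on PSFs
    if spec.psf_missing_rate > 0:
        mask = rng.random(data.shape) < spec.psf_missing_rate
        data = data.mask(mask)
    for j, name in enumerate(outcome_names):
        data[name] = Y[:, j]

    numeric_cols: list[str] = []
    if "preterm" in outcome_names:
        lp = liab[:, outcome_names.index("preterm")]
        if "severe_pree" in outcome_names:
            lp = lp + 0.6 * liab[:, outcome_names.index("severe_pree")]
        lp = (lp - lp.mean()) / lp.std()
        ga = 39.0 - 1.7 * lp + 0.7 * rng.standard_normal(n)
        data["ga_delivery"] = np.clip(ga, 24.0, 42.5).round(1)
        numeric_cols.append("ga_delivery")
    if "hypertension" in outcome_names and "diabetes" in outcome_names:
        lm = (
            liab[:, outcome_names.index("hypertension")]
            + liab[:, outcome_names.index("diabetes")]
        )
        if "gestational_diabetes" in outcome_names:
            lm = lm + 0.4 * liab[:, outcome_names.index("gestational_diabetes")]
        lm = (lm - lm.mean()) / lm.std()
        bmi = 25.0 + 3.6 * lm + 1.5 * rng.standard_normal(n)
        data["bmi"] = np.clip(bmi, 16.5, 48.0).round(1)
        numeric_cols.append("bmi")

    # gestational age when the questionnaire was filled in: lognormal with
    # the configured median, truncated to the enrollment window
    ga_q = np.exp(
        rng.normal(np.log(spec.ga_questionnaire_median_weeks),
                   spec.ga_questionnaire_log_sd, n)
    )
    data["ga_questionnaire"] = np.clip(ga_q, 5.0, 28.0).round(1)
    data["any_aporf"] = (Y.sum(axis=1) > 0).astype(int) if m else 0

    return CohortTable(
        data=data,
        psf_cols=psf_cols,
        outcome_binary_cols=list(outcome_names),
        outcome_numeric_cols=numeric_cols,
        meta_cols=["ga_questionnaire", "any_aporf"],
        psf_blocks=blocks,
        psf_effects=B if m else None,
        liabilities=pd.DataFrame(liab, index=ids, columns=outcome_names),
    )


# ---------------------------------------------------------------------------
# immune panel


@dataclass
class ImmunePanelSpec:
    """Configuration of the repeated-measures immune feature panel."""

    n_immune_patients: int = 14
    n_timepoints: int = 4
    n_immune_features: int = 534
    n_true_signal_features: int = 40
    signal_coefficient_scale: float = 0.6
    noise_sd: float = 0.5
    timepoint_effect: Sequence[float] = (0.0, 0.5, 1.0, 1.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_true_signal_features > self.n_immune_features:
            raise ConstraintError(
                "n_true_signal_features exceeds n_immune_features"
            )
        if self.noise_sd < 0:
            raise ConstraintError("noise_sd must be >= 0")
        if len(self.timepoint_effect) != self.n_timepoints:
            raise ConstraintError("timepoint_effect length must match n_timepoints")


@dataclass
class ImmunePanel:
    """Patient-timepoint x immune-feature table with planted truth.

    ``design`` is the exact PSF design matrix (mean-imputed, unit-variance
    scaled, one row per patient) the planted linear map was applied to, so
    noiseless recovery tests can refit against the same inputs.
    """

    data: pd.DataFrame  # columns: patient_id, timepoint, feature columns
    feature_names: list[str]
    signal_features: list[str]
    planted_coefficients: pd.DataFrame  # psf x signal-feature
    timepoint_effect: np.ndarray
    design: pd.DataFrame  # patient x psf, as used for generation

    @property
    def patient_ids(self) -> list[str]:
        return list(pd.unique(self.data["patient_id"]))

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(out / "immune_panel.csv", index=False)
        truth = {
            "signal_features": self.signal_features,
            "timepoint_effect": list(map(float, self.timepoint_effect)),
        }
        (out / "immune_panel.planted.json").write_text(json.dumps(truth))
        self.planted_coefficients.to_csv(out / "immune_panel.coefficients.csv")


def scaled_psf_design(cohort: CohortTable, ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean-imputed, centred, unit-variance PSF matrix (population stats)."""
    X = cohort.psf_frame()
    X = X.fillna(X.mean())
    sd = X.std(ddof=1).replace(0.0, 1.0)
    X = (X - X.mean()) / sd
    return X if ids is None else X.loc[list(ids)]


def generate_immune_panel(cohort: CohortTable, spec: ImmunePanelSpec) -> ImmunePanel:
    """Repeated-measures immune features for a healthy sub-cohort.

    Patients are drawn from those without any adverse outcome when enough
    exist (the measured sub-cohort in the emulated study was healthy).  For
    signal features, value = scaled-PSF row . planted coefficients +
    timepoint offset + Gaussian noise; the rest are pure noise.
    """
    spec.validate()
    if spec.n_immune_patients > cohort.n_patients:
        raise ConstraintError("n_immune_patients exceeds cohort size")
    rng = np.random.default_rng(spec.seed)

    healthy = cohort.data.index[cohort.data["any_aporf"] == 0] \
        if "any_aporf" in cohort.data else cohort.data.index
    pool = healthy if len(healthy) >= spec.n_immune_patients else cohort.data.index
    chosen = sorted(rng.choice(pool, size=spec.n_immune_patients, replace=False))

    X = scaled_psf_design(cohort, chosen)
    n_psf = X.shape[1]

    feat_names = [f"imm_{j:03d}" for j in range(spec.n_immune_features)]
    sig_idx = sorted(
        rng.choice(spec.n_immune_features, spec.n_true_signal_features, replace=False)
    )
    beta = rng.normal(0.0, spec.signal_coefficient_scale,
                      size=(n_psf, spec.n_true_signal_features))

    tp = np.asarray(spec.timepoint_effect, dtype=float)
    rows = []
    for pid in chosen:
        x = X.loc[pid].to_numpy()
        for t in range(spec.n_timepoints):
            vals = rng.standard_normal(spec.n_immune_features)
            if spec.n_true_signal_features:
                signal = x @ beta + tp[t]
                noise = (
                    rng.normal(0.0, spec.noise_sd, spec.n_true_signal_features)
                    if spec.noise_sd > 0
                    else 0.0
                )
                vals[sig_idx] = signal + noise
            rows.append([pid, t + 1, *vals])

    data = pd.DataFrame(rows, columns=["patient_id", "timepoint", *feat_names])
    data["timepoint"] = data["timepoint"].astype(int)
    signal_features = [feat_names[j] for j in sig_idx]
    planted = pd.DataFrame(beta, index=list(X.columns), columns=signal_features)
    return ImmunePanel(
        data=data,
        feature_names=feat_names,
        signal_features=signal_features,
        planted_coefficients=planted,
        timepoint_effect=tp,
        design=X,
    )


# ---------------------------------------------------------------------------
# raw questionnaire fixture


_BEDTIMES = (
    "9:00 PM", "9:30 PM", "10:00 PM", "10:30 PM", "11:00 PM",
    "11:30 PM", "12:00 AM", "12:30 AM", "1:00 AM",
)


@dataclass
class RawQuestionnaire:
    """A raw questionnaire export: mixed-type columns plus a role schema.

    ``schema`` maps: ``id`` -> id column, ``outcome_cols`` -> outcome status
    columns (not questionnaire items), ``text_parse`` -> {column: parser
    name} for text items convertible to numbers, ``drop_items`` -> named
    items excluded a priori (e.g. an age bracket outside the cohort's range).
    """

    table: pd.DataFrame
    schema: dict

    def item_columns(self) -> list[str]:
        skip = {self.schema.get("id", "patient_id")}
        skip.update(self.schema.get("outcome_cols", []))
        return [c for c in self.table.columns if c not in skip]

    def outcomes(self) -> pd.DataFrame:
        cols = [self.schema.get("id", "patient_id")] + list(
            self.schema.get("outcome_cols", [])
        )
        return self.table[cols].set_index(self.schema.get("id", "patient_id"))


def generate_questionnaire_fixture(
    seed: int = 0,
    n_patients: int = 283,
    n_missing_pree: int = 83,
    n_retained_items: int = 79,
) -> RawQuestionnaire:
    """Raw questionnaire emulating the documented preprocessing hazards.

    Contains, besides ``n_retained_items`` legitimate predictors (one of
    which is a parseable "preferred bedtime" text column): free-text
    columns, a constant column, an all-missing column, and an
    age-inapplicable life-stress item — engineered so the documented filter
    chain retains exactly ``n_retained_items`` predictors.  A block of
    ``n_missing_pree`` patients lacks preeclampsia status entirely.
    """
    rng = np.random.default_rng(seed)
    n = n_patients
    ids = [f"P{i:04d}" for i in range(n)]
    tbl = pd.DataFrame({"patient_id": ids})

    # preeclampsia status: missing for a random subset of patients
    sev = rng.binomial(1, 0.07, n).astype(float)
    sup = rng.binomial(1, 0.03, n).astype(float)
    miss = rng.choice(n, size=n_missing_pree, replace=False)
    sev[miss] = np.nan
    sup[miss] = np.nan
    tbl["severe_pree"] = sev
    tbl["superimposed_pree"] = sup

    # legitimate items: n_retained_items - 1 numeric/ordinal/binary columns
    # plus one text bedtime column that survives via parsing
    n_numeric = n_retained_items - 1
    latent = _block_gaussian(rng, n, _fixture_blocks(n_numeric), 0.5)
    vals, kinds = _discretize_psfs(rng, latent)
    for j in range(n_numeric):
        col = vals[:, j].astype(float)
        holes = rng.random(n) < 0.04
        col[holes] = np.nan
        tbl[f"item_{j:03d}"] = col

    bed = rng.choice(_BEDTIMES, size=n).astype(object)
    bed[rng.random(n) < 0.05] = "whenever"
    tbl["preferred_bedtime"] = bed

    # hazards the filter chain must remove
    tbl["free_text_notes"] = rng.choice(
        ["feeling ok", "tired lately", "n/a", "busy week"], size=n
    )
    tbl["occupation_text"] = rng.choice(
        ["teacher", "engineer", "nurse", "student"], size=n
    )
    tbl["clinic_site"] = 1.0  # constant
    tbl["unused_item"] = np.nan  # never answered
    tbl["life_stress_41_50"] = rng.integers(1, 9, n).astype(float)

    schema = {
        "id": "patient_id",
        "outcome_cols": ["severe_pree", "superimposed_pree"],
        "text_parse": {"preferred_bedtime": "bedtime"},
        "drop_items": ["life_stress_41_50"],
    }
    return RawQuestionnaire(table=tbl, schema=schema)


def _fixture_blocks(n_items: int, block: int = 6) -> list[int]:
    sizes = [block] * (n_items // block)
    if n_items % block:
        sizes.append(n_items % block)
    return sizes
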