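"""In-silico immune feature generation and outcome prediction from it.

The ridge ensemble from the stress-to-immune screen is collapsed into a
single linear generator by taking the unweighted elementwise mean of the
coefficients (and intercepts, and training scaling parameters) over all
repetition x fold fits.  The generator then imputes immune features for
the patients who were never measured — by default at timepoint 1, the
first trimester, when the questionnaire was administered — and those
generated features feed the same multitask / single-task networks used for
the questionnaire-based outcome models.  Measured patients are excluded
from that second model to prevent bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .immune import RidgeEnsemble
from .multitask import KFoldResult, evaluate_repeated_kfold
from .nn import NetworkConfig
from .prep import FeatureMatrix
from .synthetic import CohortTable


@dataclass
class LinearGenerator:
    """Affine map raw-questionnaire-row + timepoint -> immune features."""

    W: np.ndarray  # (n_immune, n_pred), scaled-predictor space
    b: np.ndarray  # (n_immune,)
    scaler_mean: np.ndarray  # (n_pred,)
    scaler_sd: np.ndarray  # (n_pred,)
    predictor_names: list[str]
    immune_feature_names: list[str]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.W, index=self.immune_feature_names, columns=self.predictor_names
        ).to_csv(out / "generator_W.csv")
        meta = {
            "intercepts": self.b.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "predictor_names": self.predictor_names,
        }
        (out / "generator_meta.json").write_text(json.dumps(meta))


def average_ensemble(ens: RidgeEnsemble) -> LinearGenerator:
    """Elementwise mean over all repetition x fold fits.

    Coefficients, intercepts and the training scaling parameters are all
    averaged unweighted; the result is one linear model per immune feature.
    """
    if ens.n_slices < 1:
        raise ValueError("ensemble has no fitted slices")
    return LinearGenerator(
        W=ens.coefs.mean(axis=0).astype(float),
        b=ens.intercepts.mean(axis=0).astype(float),
        scaler_mean=ens.scaler_mean.mean(axis=0).astype(float),
        scaler_sd=ens.scaler_sd.mean(axis=0).astype(float),
        predictor_names=list(ens.predictor_names),
        immune_feature_names=list(ens.immune_feature_names),
    )


def generate_features(
    gen: LinearGenerator,
    fm: FeatureMatrix,
    timepoint: int = 1,
) -> pd.DataFrame:
    """Exact affine generation of immune features — no noise injection.

    ``fm`` holds raw questionnaire predictors (one row per patient); the
    generator's fold-averaged scaling is applied, the timepoint code is
    appended, and the averaged linear model is evaluated.  Returns a
    patients x immune-features frame.
    """
    psf_names = [n for n in gen.predictor_names if n != "timepoint"]
    have = list(fm.values.columns)
    missing = [n for n in psf_names if n not in have]
    extra = [n for n in have if n not in psf_names]
    if missing or extra:
        raise ValueError(
            f"predictor mismatch; missing={missing[:5]} extra={extra[:5]}"
        )
    X = fm.values[psf_names].to_numpy(dtype=float)
    n_psf = len(psf_names)
    Xs = (X - gen.scaler_mean[:n_psf]) / gen.scaler_sd[:n_psf]
    Xs = np.nan_to_num(Xs, nan=0.0)
    Xa = np.column_stack([Xs, np.full(len(Xs), float(timepoint))])
    out = Xa @ gen.W.T + gen.b
    return pd.DataFrame(
        out, index=fm.values.index, columns=gen.immune_feature_names
    )


def predict_aporfs_from_generated(
    gen_matrix: pd.DataFrame,
    outcomes: pd.DataFrame,
    cfg: NetworkConfig,
    measured_patient_ids: Sequence[str] = (),
    k: int = 5,
    n_repetitions: int = 20,
) -> KFoldResult:
    """Multitask vs single-task outcome prediction from generated features.

    ``gen_matrix`` must already exclude the immune-measured patients; any
    overlap with ``measured_patient_ids`` is a hard error, since those
    patients' measured data trained the generator.
    """
    overlap = set(gen_matrix.index) & set(measured_patient_ids)
    if overlap:
        raise ValueError(
            f"immune-measured patients present in generated input: {sorted(overlap)[:5]}"
        )
    common = gen_matrix.index.intersection(outcomes.index)
    if len(common) != len(gen_matrix):
        raise ValueError("generated matrix and outcomes are not patient-aligned")
    Y = outcomes.loc[gen_matrix.index]
    fm = FeatureMatrix(values=gen_matrix)
    return evaluate_repeated_kfold(fm, Y, cfg, k=k, n_repetitions=n_repetitions)


def unmeasured_patients(cohort: CohortTable, measured_ids: Sequence[str]) -> pd.Index:
    return cohort.data.index.difference(pd.Index(measured_ids)).sort_values()
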