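"""Questionnaire-to-feature-matrix preprocessing and cohort exclusions.

The documented chain, in order: remove patients without preeclampsia
information; parse configured text items into numbers (e.g. preferred
bedtime); drop non-numeric columns; drop columns with at most one unique
non-missing value (constants, never-answered items); drop named
age-inapplicable items; finally scale to unit variance with parameters
estimated on the fitting split only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import RawQuestionnaire

log = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Tables cannot be joined on patient id."""


@dataclass
class FeatureMatrix:
    """Patients x numeric predictors, with the scaling used to produce it.

    ``scaling_params`` (set by :func:`scale_features`) holds per-feature
    fit-split mean and sample standard deviation (ddof=1) so held-out rows
    can be transformed identically.
    """

    values: pd.DataFrame  # indexed by patient_id
    scaling_params: pd.DataFrame | None = None
    centered: bool = True
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.index


def exclude_patients(
    raw: RawQuestionnaire, outcomes: pd.DataFrame
) -> tuple[RawQuestionnaire, pd.DataFrame]:
    """Remove patients whose preeclampsia status is entirely missing.

    ``outcomes`` must be indexed by patient id and contain the preeclampsia
    status columns named in the questionnaire schema.  Returns the filtered
    questionnaire and outcome tables, row-aligned.
    """
    id_col = raw.schema.get("id", "patient_id")
    pree_cols = [c for c in raw.schema.get("outcome_cols", []) if c in outcomes]
    if not pree_cols:
        raise AlignmentError("outcomes table lacks the preeclampsia status columns")
    tbl = raw.table.set_index(id_col, drop=False)
    if not tbl.index.isin(outcomes.index).all():
        raise AlignmentError("questionnaire patients missing from outcomes table")
    outcomes = outcomes.loc[tbl.index]

    keep = ~outcomes[pree_cols].isna().all(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("removed %d patients without preeclampsia information", n_removed)
    if keep.sum() == 0:
        log.warning("all patients lack preeclampsia information; cohort is empty")
    kept_tbl = tbl.loc[keep].reset_index(drop=True)
    return RawQuestionnaire(kept_tbl, raw.schema), outcomes.loc[keep]


_TIME_RE = re.compile(r"^\s*(\d{1,2})(?::(\d{2}))?\s*(am|pm)?\s*$", re.IGNORECASE)


def parse_bedtime(text: object) -> float:
    """Clock-time text -> minutes after noon on a 24 h wrap.

    "10:30 PM" -> 630, "noon" -> 0, "midnight" -> 720; unparseable -> NaN.
    """
    if not isinstance(text, str):
        return np.nan
    s = text.strip().lower()
    if s == "noon":
        return 0.0
    if s == "midnight":
        return 720.0
    m = _TIME_RE.match(s)
    if not m:
        return np.nan
    hour = int(m.group(1))
    minute = int(m.group(2) or 0)
    ampm = m.group(3)
    if hour > 23 or minute > 59:
        return np.nan
    if ampm:
        if hour > 12 or hour == 0:
            return np.nan
        hour = hour % 12 + (12 if ampm == "pm" else 0)
    minutes_midnight = 60 * hour + minute
    return float((minutes_midnight - 720) % 1440)


_PARSERS = {"bedtime": parse_bedtime}


def parse_text_features(raw: RawQuestionnaire) -> RawQuestionnaire:
    """Convert configured text columns to numbers; per-cell failures -> NaN."""
    tbl = raw.table.copy()
    for col, parser_name in raw.schema.get("text_parse", {}).items():
        if col not in tbl:
            continue
        parser = _PARSERS[parser_name]
        tbl[col] = tbl[col].map(parser).astype(float)
    return RawQuestionnaire(tbl, raw.schema)


def _is_numeric(col: pd.Series) -> bool:
    if pd.api.types.is_numeric_dtype(col):
        return True
    coerced = pd.to_numeric(col, errors="coerce")
    return bool((coerced.notna() | col.isna()).all())


def filter_features(raw: RawQuestionnaire) -> FeatureMatrix:
    """Apply the documented predictor filters, in their stated order.

    1. drop non-numeric columns;
    2. drop columns with <=1 unique non-missing value (constants and
       fully-missing items);
    3. drop named a-priori-excluded items.
    """
    id_col = raw.schema.get("id", "patient_id")
    items = raw.table[raw.item_columns()]
    dropped: dict[str, list[str]] = {}

    numeric = [c for c in items.columns if _is_numeric(items[c])]
    dropped["non_numeric"] = [c for c in items.columns if c not in numeric]
    items = items[numeric].apply(pd.to_numeric, errors="coerce")

    nunique = items.nunique(dropna=True)
    varying = nunique[nunique > 1].index.tolist()
    dropped["degenerate"] = [c for c in items.columns if c not in varying]
    items = items[varying]

    named = [c for c in raw.schema.get("drop_items", []) if c in items]
    dropped["named"] = named
    items = items.drop(columns=named)

    if items.shape[1] == 0:
        raise ValueError("no predictors retained")
    values = items.copy()
    if id_col in raw.table:
        values.index = pd.Index(raw.table[id_col], name=id_col)
    return FeatureMatrix(values=values, dropped=dropped)


def scale_features(
    fm: FeatureMatrix,
    fit_rows: pd.Index | np.ndarray | None = None,
    center: bool = True,
) -> FeatureMatrix:
    """Scale every column to unit variance; impute missing by fit-split mean.

    Mean and sample sd (ddof=1) are computed on the non-missing entries of
    ``fit_rows`` only (default: all rows) and recorded in
    ``scaling_params``; all rows — including held-out ones — are then
    transformed with those parameters, so no information flows from
    held-out rows into the scaling.  With ``center`` (default) columns are
    also mean-centred, making missing entries 0 after imputation.
    """
    X = fm.values
    fit = X if fit_rows is None else X.loc[fit_rows]
    mean = fit.mean()
    sd = fit.std(ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = sd.index[(sd == 0) | sd.isna()].tolist()
        raise ValueError(f"zero-variance column(s) at transform time: {bad}")
    loc = mean if center else 0.0 * mean
    scaled = (X - loc) / sd
    scaled = scaled.fillna((mean - loc) / sd)  # fit-mean imputation
    params = pd.DataFrame({"mean": mean, "sd": sd, "loc": loc})
    return FeatureMatrix(
        values=scaled, scaling_params=params, centered=center, dropped=fm.dropped
    )


def apply_scaling(fm: FeatureMatrix, params: pd.DataFrame, centered: bool = True) -> pd.DataFrame:
    """Transform held-out rows with previously stored scaling parameters."""
    missing = [c for c in fm.values.columns if c not in params.index]
    if missing:
        raise ValueError(f"no stored scaling for columns: {missing}")
    loc, sd, mean = params["loc"], params["sd"], params["mean"]
    scaled = (fm.values - loc) / sd
    return scaled.fillna((mean - loc) / sd)
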