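"""Correlation-profile clustering of stress factors and APORF associations.

Each questionnaire item (PSF) is represented by its vector of Spearman
correlations against every other item (pairwise-complete).  K-means on the
raw (signed) profiles yields stressor categories; a t-SNE on the absolute
profiles places items in the plane for visualisation.  Item- and
cluster-level associations with outcomes use unadjusted Spearman p < 0.05 —
no multiple-testing correction is applied at this stage, by design (the
FDR correction belongs to the immune screen only).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .network import spearman
from .prep import FeatureMatrix

log = logging.getLogger(__name__)

DEFAULT_K = 15


@dataclass
class ClusterAssignment:
    assignment: pd.Series  # feature -> cluster_id
    k: int
    embedding: pd.DataFrame | None = None  # feature x (x, y)

    @property
    def features(self) -> list[str]:
        return list(self.assignment.index)

    def members(self, cluster_id: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster_id])


@dataclass
class AssociationResult:
    rho: pd.DataFrame  # PSF x outcome
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean, p < alpha
    alpha_assoc: float
    cluster_summary: pd.DataFrame  # per cluster: size, n_assoc_aporfs
    cluster_pct_significant: pd.DataFrame  # cluster x outcome, percentages
    psf_counts: pd.DataFrame  # per PSF: n_assoc_apo, n_assoc_rf
    masked_rho: pd.DataFrame  # rho with non-significant cells set to NaN


def correlation_profiles(fm: FeatureMatrix) -> pd.DataFrame:
    """PSF x PSF Spearman matrix (pairwise-complete), unit diagonal.

    Features with no defined correlation to any other feature are excluded
    with a warning.
    """
    X = fm.values
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    prof = X.corr(method="spearman")  # pandas: pairwise-complete
    np.fill_diagonal(prof.values, 1.0)
    undefined = prof.index[prof.isna().all(axis=1)]
    if len(undefined):
        log.warning("excluding features with undefined profiles: %s",
                    list(undefined))
        prof = prof.drop(index=undefined, columns=undefined)
    return prof.fillna(0.0)


def cluster_psfs(
    profiles: pd.DataFrame, k: int = DEFAULT_K, seed: int = 0
) -> ClusterAssignment:
    """K-means (k-means++, 10 restarts) on the raw signed profiles.

    Deterministic given ``seed``; re-seeds and retries in the unlikely
    event of an empty cluster.
    """
    n = profiles.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of features ({n})")
    X = profiles.to_numpy()
    for attempt in range(10):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) == k:
            break
    else:
        raise RuntimeError("could not produce k non-empty clusters")
    return ClusterAssignment(
        assignment=pd.Series(labels, index=profiles.index, name="cluster_id"),
        k=k,
    )


def embed_psfs(
    profiles: pd.DataFrame, seed: int = 0, perplexity: float = 10.0
) -> pd.DataFrame:
    """2-D t-SNE of the absolute correlation profiles."""
    n = profiles.shape[0]
    if n < 3:
        raise ValueError("need at least 3 features to embed")
    perplexity = min(perplexity, (n - 1) / 3)
    ts = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    xy = ts.fit_transform(np.abs(profiles.to_numpy()))
    return pd.DataFrame(xy, index=profiles.index, columns=["x", "y"])


def associate(
    fm: FeatureMatrix,
    outcomes: pd.DataFrame,
    clusters: ClusterAssignment,
    alpha_assoc: float = 0.05,
    apo_cols: list[str] | None = None,
) -> AssociationResult:
    """Item- and cluster-level PSF-outcome associations.

    Per PSF x outcome: Spearman rho and p (pairwise complete); a cell is
    significant at unadjusted p < ``alpha_assoc``.  A cluster is associated
    with an outcome if *any* member item is (the any-member rule); the
    heatmap percentage is significant members / cluster size.  Per-item
    counts are split into APO vs risk-factor tallies via ``apo_cols``.
    """
    common = fm.values.index.intersection(outcomes.index)
    if len(common) != len(fm.values) or len(common) != len(outcomes):
        raise ValueError("feature matrix and outcomes are not patient-aligned")
    X, O = fm.values.loc[common], outcomes.loc[common]
    feats = [f for f in clusters.features if f in X.columns]

    rho = pd.DataFrame(index=feats, columns=O.columns, dtype=float)
    p = pd.DataFrame(index=feats, columns=O.columns, dtype=float)
    for f in feats:
        for o in O.columns:
            r, pv = spearman(X[f], O[o])
            rho.loc[f, o] = r
            p.loc[f, o] = pv
    significant = p < alpha_assoc  # NaN p compares False

    assign = clusters.assignment.loc[feats]
    cluster_rows, pct_rows = [], []
    for cid in range(clusters.k):
        members = assign.index[assign == cid]
        size = len(members)
        sig_any = significant.loc[members].any(axis=0) if size else (
            pd.Series(False, index=O.columns))
        pct = (
            100.0 * significant.loc[members].sum(axis=0) / size
            if size
            else pd.Series(0.0, index=O.columns)
        )
        cluster_rows.append(
            {"cluster_id": cid, "size": size,
             "n_assoc_aporfs": int(sig_any.sum())}
        )
        pct_rows.append(pct.rename(cid))
    cluster_summary = pd.DataFrame(cluster_rows).set_index("cluster_id")
    cluster_pct = pd.DataFrame(pct_rows)
    cluster_pct.index.name = "cluster_id"

    apo_cols = list(apo_cols or [])
    rf_cols = [c for c in O.columns if c not in apo_cols]
    psf_counts = pd.DataFrame(
        {
            "n_assoc_apo": significant[
                [c for c in apo_cols if c in O.columns]
            ].sum(axis=1),
            "n_assoc_rf": significant[rf_cols].sum(axis=1),
        }
    )
    psf_counts["n_assoc_total"] = psf_counts.sum(axis=1)
    psf_counts["cluster_id"] = assign

    return AssociationResult(
        rho=rho,
        p=p,
        significant=significant,
        alpha_assoc=alpha_assoc,
        cluster_summary=cluster_summary,
        cluster_pct_significant=cluster_pct,
        psf_counts=psf_counts,
        masked_rho=rho.where(significant),
    )


def write_associations(res: AssociationResult, assignment: ClusterAssignment,
                       out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    assignment.assignment.to_csv(out / "psf_clusters.csv")
    res.rho.to_csv(out / "psf_outcome_rho.csv")
    res.p.to_csv(out / "psf_outcome_p.csv")
    res.masked_rho.to_csv(out / "psf_outcome_rho_masked.csv")
    res.psf_counts.to_csv(out / "psf_association_counts.csv")
    summary = {
        "alpha_assoc": res.alpha_assoc,
        "clusters": res.cluster_summary.reset_index().to_dict("records"),
        "pct_significant": res.cluster_pct_significant.round(2)
        .reset_index().to_dict("records"),
    }
    (out / "cluster_summary.json").write_text(json.dumps(summary, indent=1))
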