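"""Pairwise outcome interrelatedness network.

Spearman rank correlations (pairwise-complete) between all modelled
outcomes and risk factors, with each edge categorised as weak, moderate or
strong by |rho|.  The published strength taxonomy names several scales
without fixing cut points; the defaults here (0.3 / 0.6) are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CohortTable

#: |rho| bounds: below first -> weak, between -> moderate, above second -> strong
DEFAULT_STRENGTH_THRESHOLDS = (0.3, 0.6)


@dataclass
class CorrelationMatrix:
    labels: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame


@dataclass
class EdgeCategory:
    pair: tuple[str, str]
    category: str  # weak | moderate | strong | undefined
    rho: float


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p on pairwise-complete observations.

    Ties get average ranks; p uses the t approximation.  Fewer than 3
    complete pairs, or a constant input, yields (nan, nan) rather than an
    exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return float("nan"), float("nan")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return float("nan"), float("nan")
    res = stats.spearmanr(xs, ys)
    return float(res.statistic), float(res.pvalue)


def categorize(rho: float, thresholds=DEFAULT_STRENGTH_THRESHOLDS) -> str:
    if np.isnan(rho):
        return "undefined"
    a = abs(rho)
    if a < thresholds[0]:
        return "weak"
    if a <= thresholds[1]:
        return "moderate"
    return "strong"


def build_network(
    outcomes: pd.DataFrame | CohortTable,
    node_roles: dict[str, str] | None = None,
    thresholds=DEFAULT_STRENGTH_THRESHOLDS,
) -> tuple[CorrelationMatrix, list[EdgeCategory]]:
    """All pairwise outcome correlations plus categorised edges.

    ``outcomes`` is either a numeric DataFrame (patients x outcomes) or a
    cohort table, in which case its binary and numeric outcome columns are
    used and node roles (APO vs risk factor) are attached automatically.
    """
    if isinstance(outcomes, CohortTable):
        from .synthetic import APO_TASKS

        df = outcomes.outcome_frame()
        node_roles = {
            c: ("APO" if c in APO_TASKS or c == "preterm" else "RF")
            for c in df.columns
        }
    else:
        df = outcomes
    labels = list(df.columns)
    if len(labels) < 2:
        raise ValueError("need at least 2 outcomes")

    k = len(labels)
    rho = np.eye(k)
    p = np.zeros((k, k))
    n_pairs = np.zeros((k, k), dtype=int)
    for i in range(k):
        n_pairs[i, i] = int(df[labels[i]].notna().sum())
        for j in range(i + 1, k):
            r, pv = spearman(df[labels[i]], df[labels[j]])
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
            n_pairs[i, j] = n_pairs[j, i] = int(
                (df[labels[i]].notna() & df[labels[j]].notna()).sum()
            )

    cm = CorrelationMatrix(
        labels=labels,
        rho=pd.DataFrame(rho, index=labels, columns=labels),
        p=pd.DataFrame(p, index=labels, columns=labels),
        n_pairs=pd.DataFrame(n_pairs, index=labels, columns=labels),
    )
    edges = [
        EdgeCategory(
            pair=(labels[i], labels[j]),
            category=categorize(rho[i, j], thresholds),
            rho=float(rho[i, j]),
        )
        for i in range(k)
        for j in range(i + 1, k)
    ]
    cm.node_roles = node_roles or {}
    return cm, edges


def write_network(
    cm: CorrelationMatrix, edges: list[EdgeCategory], out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm.rho.to_csv(out / "outcome_rho.csv")
    cm.p.to_csv(out / "outcome_p.csv")
    payload = {
        "nodes": [
            {"name": n, "role": getattr(cm, "node_roles", {}).get(n, "")}
            for n in cm.labels
        ],
        "edges": [
            {"source": e.pair[0], "target": e.pair[1],
             "rho": None if np.isnan(e.rho) else round(e.rho, 4),
             "category": e.category}
            for e in edges
        ],
    }
    (out / "outcome_network.json").write_text(json.dumps(payload, indent=1))


def to_networkx(cm: CorrelationMatrix, edges: list[EdgeCategory]):
    """Edge-categorised graph for layout/plotting."""
    import networkx as nx

    g = nx.Graph()
    for n in cm.labels:
        g.add_node(n, role=getattr(cm, "node_roles", {}).get(n, ""))
    for e in edges:
        if not np.isnan(e.rho):
            g.add_edge(*e.pair, rho=e.rho, category=e.category)
    return g
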