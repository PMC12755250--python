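"""Bootstrap edge stability and edge-set comparison between learned models.

The nonparametric bootstrap re-runs the full learn-and-fit procedure on
resamples of the rows (with replacement, resample size n).  Each edge's
appearance frequency across resamples measures its stability; a 95%
percentile interval (2.5th/97.5th percentiles) of its coefficient is
recorded over the resamples in which the edge was actually learned.  An
effect is called consistent when the coefficient fitted on the full data
falls inside that interval.

Two learned DAGs (e.g. from the full sample and from a subgroup) are
compared as directed edge sets via the Jaccard overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .effects import PathModel, fit_path_model
from .graph import DagStructure, Edge
from .preprocess import StandardizedDataset, VariableTable, standardize
from .search import EdgeConstraintSet, SearchConfig, hill_climb

DEFAULT_REPORTING_THRESHOLD = 0.40


@dataclass(frozen=True)
class BootstrapSummary:
    """Per-edge appearance frequencies and coefficient intervals.

    ``records`` has one row per edge observed at least once, with columns
    parent, child, frequency, ci_low, ci_high, n_present.  ``frequency``
    is n_present / B, counting failed resamples in the denominator.
    """

    B: int
    records: pd.DataFrame = field(compare=False)
    reporting_threshold: float = DEFAULT_REPORTING_THRESHOLD
    failures: int = 0

    def __post_init__(self) -> None:
        if len(self.records):
            freq = self.records["frequency"]
            if (freq < 0).any() or (freq > 1).any():
                raise ValueError("frequencies must lie in [0, 1]")
            if (self.records["ci_low"] > self.records["ci_high"]).any():
                raise ValueError("ci_low must not exceed ci_high")

    def edge_record(self, edge: Edge) -> pd.Series | None:
        mask = (self.records["parent"] == edge[0]) & (self.records["child"] == edge[1])
        hit = self.records[mask]
        return hit.iloc[0] if len(hit) else None


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["parent", "child", "frequency", "ci_low", "ci_high", "n_present"]
    )


def bootstrap_dags(
    data: StandardizedDataset,
    constraints: EdgeConstraintSet | None,
    config: SearchConfig | None,
    B: int,
    seed: int,
) -> BootstrapSummary:
    """Re-learn the DAG and refit coefficients on B row resamples.

    Each resample draws n rows with replacement, re-standardizes them,
    runs the hill climb and fits the path model.  Per-resample random
    streams derive from ``(seed, resample index)``, so results are
    reproducible and independent of execution order.  A resample that
    fails (e.g. a constant column after resampling) is excluded from
    edge statistics and counted in ``failures``.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    n = data.n
    roles = data.roles
    counts: dict[Edge, int] = {}
    coefs: dict[Edge, list[float]] = {}
    failures = 0
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        idx = rng.integers(0, n, size=n)
        frame = data.frame.iloc[idx].reset_index(drop=True)
        try:
            resample = standardize(VariableTable(frame, roles))
            dag, _ = hill_climb(resample, constraints, config)
            model = fit_path_model(dag, resample)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        for parent, child in dag.edges:
            edge = (parent, child)
            counts[edge] = counts.get(edge, 0) + 1
            coefs.setdefault(edge, []).append(model.direct_effect(parent, child))
    rows = []
    for edge in sorted(counts):
        values = np.asarray(coefs[edge])
        lo, hi = np.percentile(values, [2.5, 97.5])
        rows.append(
            {
                "parent": edge[0],
                "child": edge[1],
                "frequency": counts[edge] / B,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_present": counts[edge],
            }
        )
    records = pd.DataFrame(rows) if rows else _empty_records()
    return BootstrapSummary(B, records, failures=failures)


def filter_reported_edges(
    summary: BootstrapSummary, threshold: float = DEFAULT_REPORTING_THRESHOLD
) -> BootstrapSummary:
    """Keep edges whose frequency is at least ``threshold`` (inclusive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("reporting threshold must lie in [0, 1]")
    records = summary.records
    kept = (
        records[records["frequency"] >= threshold].reset_index(drop=True)
        if len(records)
        else records
    )
    return replace(summary, records=kept, reporting_threshold=threshold)


def consistency_check(
    summary: BootstrapSummary, model: PathModel
) -> dict[Edge, bool | None]:
    """Whether each edge's full-data coefficient lies in its bootstrap CI.

    The interval is closed, so a coefficient equal to an endpoint counts
    as consistent.  Edges of the model that never appeared in the
    bootstrap summary are not assessable and map to ``None``.
    """
    result: dict[Edge, bool | None] = {}
    for _, row in summary.records.iterrows():
        edge = (row["parent"], row["child"])
        if edge not in model.dag.edges:
            continue
        coef = model.direct_effect(*edge)
        result[edge] = bool(row["ci_low"] <= coef <= row["ci_high"])
    for edge in model.dag.edges:
        if edge not in result:
            result[edge] = None
    return result


def bootstrap_table(
    summary: BootstrapSummary, model: PathModel | None = None
) -> pd.DataFrame:
    """Bootstrap records, optionally annotated with the consistency flag."""
    table = summary.records.copy()
    if model is not None and len(table):
        flags = consistency_check(summary, model)
        table["consistent"] = [
            flags.get((row["parent"], row["child"])) for _, row in table.iterrows()
        ]
    return table


@dataclass(frozen=True)
class EdgeSetComparison:
    """Directed-edge overlap between two learned DAGs."""

    shared: frozenset[Edge]
    only_a: frozenset[Edge]
    only_b: frozenset[Edge]
    jaccard: float
    pct_a_shared: float
    pct_b_shared: float

    def to_dict(self) -> dict:
        return {
            "shared": sorted(map(list, self.shared)),
            "only_a": sorted(map(list, self.only_a)),
            "only_b": sorted(map(list, self.only_b)),
            "jaccard": self.jaccard,
            "pct_a_shared": self.pct_a_shared,
            "pct_b_shared": self.pct_b_shared,
        }


def compare_edge_sets(a: DagStructure, b: DagStructure) -> EdgeSetComparison:
    """Directed intersection/differences and Jaccard overlap of edge sets.

    Edge identity is direction-sensitive: X -> Y and Y -> X are distinct.
    Two empty edge sets are identical, so their Jaccard is 1.
    """
    ea, eb = set(a.edges), set(b.edges)
    shared = ea & eb
    union = ea | eb
    jaccard = len(shared) / len(union) if union else 1.0
    pct_a = len(shared) / len(ea) if ea else 1.0
    pct_b = len(shared) / len(eb) if eb else 1.0
    return EdgeSetComparison(
        frozenset(shared), frozenset(ea - eb), frozenset(eb - ea),
        jaccard, pct_a, pct_b,
    )
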