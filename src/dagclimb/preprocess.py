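"""Variable tables, z-scoring, correlation clustering and factor aggregation.

The entry point of the pipeline is a rectangular table of continuous
variables (samples x variables).  Highly inter-correlated variables are
merged into single factors before structure search: agglomerative
clustering on the dissimilarity ``1 - |r|`` groups variables whose absolute
Pearson correlation exceeds a cutoff, and each multi-variable group is
replaced by its first principal component.  This controls the
multicollinearity that otherwise destabilizes score-based DAG search.

LMG relative importance (the average over all predictor orderings of the
incremental R-squared) is provided for variable screening.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

ROLES = ("predictor", "outcome", "genetic")


class VariableTable:
    """Samples x variables matrix of continuous values with roles.

    Each variable carries one role: ``predictor`` (default), ``outcome``
    (at most one) or ``genetic``.  Missing values are rejected here;
    complete-case filtering happens at ingest (:meth:`read_table`).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        roles: Mapping[str, str] | None = None,
    ) -> None:
        frame = pd.DataFrame(values).copy()
        frame.columns = [str(c) for c in frame.columns]
        if frame.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        if len(set(frame.columns)) != len(frame.columns):
            raise ValueError("variable names must be unique")
        if any(not c for c in frame.columns):
            raise ValueError("variable names must be non-empty")
        try:
            frame = frame.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric values in table: {exc}") from None
        if frame.isna().any().any():
            bad = [c for c in frame.columns if frame[c].isna().any()]
            raise ValueError(
                f"missing values in column(s) {bad}; apply complete-case "
                "filtering before constructing a VariableTable"
            )
        self._frame = frame
        role_map = {name: "predictor" for name in frame.columns}
        if roles:
            for name, role in roles.items():
                if name not in role_map:
                    raise ValueError(f"role assigned to unknown variable {name!r}")
                if role not in ROLES:
                    raise ValueError(f"unknown role {role!r} for {name!r}")
                role_map[name] = role
        if sum(1 for r in role_map.values() if r == "outcome") > 1:
            raise ValueError("at most one variable may have role 'outcome'")
        self._roles = role_map

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def names(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def roles(self) -> dict[str, str]:
        return dict(self._roles)

    @property
    def n(self) -> int:
        return self._frame.shape[0]

    @property
    def p(self) -> int:
        return self._frame.shape[1]

    @property
    def outcome(self) -> str | None:
        for name, role in self._roles.items():
            if role == "outcome":
                return name
        return None

    @property
    def genetic(self) -> str | None:
        for name, role in self._roles.items():
            if role == "genetic":
                return name
        return None

    def column(self, name: str) -> np.ndarray:
        return self._frame[name].to_numpy()

    @classmethod
    def read_table(
        cls,
        path: str | Path,
        *,
        outcome: str | None = None,
        genetic: str | None = None,
        sep: str | None = None,
    ) -> "VariableTable":
        """Read a CSV/TSV with a header row, dropping incomplete rows.

        The delimiter is inferred from the file extension (``.tsv`` ->
        tab, otherwise comma) unless given explicitly.
        """
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        frame = pd.read_csv(path, sep=sep)
        frame = frame.dropna(axis=0, how="any").reset_index(drop=True)
        roles: dict[str, str] = {}
        if outcome is not None:
            if outcome not in frame.columns:
                raise ValueError(f"outcome variable {outcome!r} not in header")
            roles[outcome] = "outcome"
        if genetic is not None:
            if genetic not in frame.columns:
                raise ValueError(f"genetic variable {genetic!r} not in header")
            roles[genetic] = "genetic"
        return cls(frame, roles)

    def write_table(self, path: str | Path, *, sep: str = ",") -> None:
        self._frame.to_csv(path, sep=sep, index=False)


class StandardizedDataset(VariableTable):
    """A VariableTable whose columns are z-scores (mean 0, sample sd 1)."""

    _TOL = 1e-6

    def __init__(
        self, values: pd.DataFrame, roles: Mapping[str, str] | None = None
    ) -> None:
        super().__init__(values, roles)
        arr = self._frame.to_numpy()
        means = arr.mean(axis=0)
        sds = arr.std(axis=0, ddof=1)
        if np.any(np.abs(means) > self._TOL) or np.any(np.abs(sds - 1.0) > self._TOL):
            raise ValueError(
                "columns are not standardized; use standardize() to construct"
            )


def standardize(table: VariableTable) -> StandardizedDataset:
    """Z-score every column using the sample (n-1) standard deviation.

    Raises
    ------
    ValueError
        If any column has zero variance (constant column).
    """
    arr = table.frame.to_numpy()
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=1)
    for name, sd in zip(table.names, sds):
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"zero variance in column {name!r}")
    z = (arr - means) / sds
    frame = pd.DataFrame(z, columns=table.names)
    return StandardizedDataset(frame, table.roles)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlation matrix with the variable order preserved."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(arr), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have a unit diagonal")
        if np.any(arr < -1 - 1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values.loc[a, b])


def correlation_matrix(data: StandardizedDataset) -> CorrelationMatrix:
    """Pairwise Pearson correlations of all variables."""
    corr = data.frame.corr(method="pearson")
    # Clip float fuzz so downstream distance computations stay in range.
    arr = np.clip(corr.to_numpy(), -1.0, 1.0)
    np.fill_diagonal(arr, 1.0)
    return CorrelationMatrix(pd.DataFrame(arr, index=corr.index, columns=corr.columns))


@dataclass(frozen=True)
class ClusterAssignment:
    """Disjoint groups of variable names produced at an |r| cutoff."""

    clusters: tuple[tuple[str, ...], ...]
    threshold: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.clusters:
            if not group:
                raise ValueError("empty cluster")
            for name in group:
                if name in seen:
                    raise ValueError(f"variable {name!r} appears in two clusters")
                seen.add(name)

    @property
    def names(self) -> list[str]:
        return [name for group in self.clusters for name in group]


def cluster_variables(
    corr: CorrelationMatrix, threshold: float
) -> ClusterAssignment:
    """Group variables by average-linkage clustering on ``1 - |r|``.

    The dendrogram is cut so that merges happen only while the linkage
    distance stays at or below ``1 - threshold``; a variable with no
    neighbor at ``|r| >= threshold`` therefore remains a singleton.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    names = corr.names
    if len(names) == 1:
        return ClusterAssignment(((names[0],),), threshold)
    dist = 1.0 - np.abs(corr.values.to_numpy())
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    labels = hierarchy.fcluster(linkage, t=1.0 - threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    order: list[int] = []
    for name, label in zip(names, labels):
        if label not in groups:
            groups[label] = []
            order.append(label)
        groups[label].append(name)
    clusters = tuple(tuple(groups[label]) for label in order)
    return ClusterAssignment(clusters, threshold)


@dataclass(frozen=True)
class AggregatedFactorSet:
    """First-PC factor scores per cluster, with loadings and variance shares."""

    factors: pd.DataFrame
    loadings: dict[str, dict[str, float]] = field(compare=False)
    variance_explained: dict[str, float] = field(compare=False)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors.columns)

    def loadings_frame(self) -> pd.DataFrame:
        rows = []
        for factor, load in self.loadings.items():
            for variable, value in load.items():
                rows.append(
                    {
                        "factor": factor,
                        "variable": variable,
                        "loading": value,
                        "variance_explained": self.variance_explained[factor],
                    }
                )
        return pd.DataFrame(rows)


def pca_aggregate(
    data: StandardizedDataset, clusters: ClusterAssignment
) -> AggregatedFactorSet:
    """Collapse each cluster to its first principal component.

    Singleton clusters pass through unchanged (variance_explained = 1).
    For a multi-variable cluster the factor is the PC1 score of its
    z-scored columns; ``variance_explained`` is the leading eigenvalue of
    the cluster correlation matrix divided by the cluster size.  The PC
    sign is fixed so the loading sum is positive (first loading's sign
    breaks exact ties), making the output deterministic across platforms.
    """
    known = set(data.names)
    for group in clusters.clusters:
        missing = [v for v in group if v not in known]
        if missing:
            raise ValueError(f"cluster references unknown variable(s) {missing}")
    columns: dict[str, np.ndarray] = {}
    loadings: dict[str, dict[str, float]] = {}
    variance: dict[str, float] = {}
    for idx, group in enumerate(clusters.clusters):
        if len(group) == 1:
            name = group[0]
            columns[name] = data.column(name)
            loadings[name] = {name: 1.0}
            variance[name] = 1.0
            continue
        name = f"F{idx + 1}"
        X = data.frame[list(group)].to_numpy()
        R = (X.T @ X) / (data.n - 1)
        eigvals, eigvecs = np.linalg.eigh(R)
        lead = int(np.argmax(eigvals))
        w = eigvecs[:, lead]
        s = w.sum()
        if s < 0 or (s == 0 and w[0] < 0):
            w = -w
        columns[name] = X @ w
        loadings[name] = {v: float(c) for v, c in zip(group, w)}
        variance[name] = float(eigvals[lead] / len(group))
    factors = pd.DataFrame(columns)
    return AggregatedFactorSet(factors, loadings, variance)


def lmg_importance(
    data: StandardizedDataset,
    outcome: str,
    predictors: Sequence[str],
) -> dict[str, float]:
    """LMG relative importance of each predictor for the outcome.

    The LMG share of predictor j averages, over every ordering of the
    predictors, the increase in R-squared when j enters after its
    predecessors.  Shares sum to the full-model R-squared.  Exact
    enumeration is feasible only for small predictor sets; the subset
    reformulation used here is O(2^p) rather than O(p!).
    """
    predictors = list(predictors)
    p = len(predictors)
    if not 1 <= p <= 12:
        raise ValueError(
            "lmg_importance enumerates orderings exactly and supports at most "
            "12 predictors; subsample orderings externally for larger sets"
        )
    if outcome in predictors:
        raise ValueError("outcome must not be among the predictors")
    for name in [outcome, *predictors]:
        if name not in set(data.names):
            raise ValueError(f"unknown variable {name!r}")

    y = data.column(outcome)
    X = data.frame[predictors].to_numpy()
    n = data.n
    # Standardized columns: correlations double as covariances.
    r_xy = (X.T @ y) / (n - 1)
    R_xx = (X.T @ X) / (n - 1)

    def r_squared(subset: tuple[int, ...]) -> float:
        if not subset:
            return 0.0
        idx = list(subset)
        beta = np.linalg.lstsq(R_xx[np.ix_(idx, idx)], r_xy[idx], rcond=None)[0]
        return float(r_xy[idx] @ beta)

    r2 = {
        subset: r_squared(subset)
        for size in range(p + 1)
        for subset in itertools.combinations(range(p), size)
    }
    shares: dict[str, float] = {}
    fact = math.factorial
    for j, name in enumerate(predictors):
        others = [i for i in range(p) if i != j]
        total = 0.0
        for size in range(p):
            weight = fact(size) * fact(p - size - 1) / fact(p)
            for subset in itertools.combinations(others, size):
                with_j = tuple(sorted(subset + (j,)))
                total += weight * (r2[with_j] - r2[subset])
        shares[name] = total
    return shares
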