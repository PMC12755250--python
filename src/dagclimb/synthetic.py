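"""Seeded linear-Gaussian SEM generators for testing and benchmarking.

Three generators are provided: :func:`simulate_sem` draws from an
arbitrary user-specified recursive linear model; :func:`make_study_like`
emulates a cohort-study-like system of eight standardized factors (three
inter-correlated parental substance-use factors feeding two parental
problem factors and a somatic-complaints factor, a child polygenic score,
and a child externalizing-behavior outcome); and
:func:`make_correlated_blocks` draws block-equicorrelated Gaussian tables
for exercising the clustering/aggregation steps.

All generators are deterministic given their seed, and noise variances
for the fixtures are solved so that every variable has unit marginal
variance — coefficients then read directly as standardized effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import DagStructure, Edge
from .preprocess import VariableTable


@dataclass(frozen=True)
class SemSpecification:
    """A recursive linear-Gaussian structural model plus sampling plan."""

    dag: DagStructure
    coefficients: dict[Edge, float]
    noise_sd: dict[str, float]
    n: int
    seed: int

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.dag.edges):
            raise ValueError("coefficient keys must exactly match the DAG edges")
        for edge, beta in self.coefficients.items():
            if not np.isfinite(beta):
                raise ValueError(f"non-finite coefficient on edge {edge}")
        if set(self.noise_sd) != set(self.dag.nodes):
            raise ValueError("noise_sd must cover every node exactly")
        for node, sd in self.noise_sd.items():
            if not (np.isfinite(sd) and sd > 0):
                raise ValueError(f"noise sd for {node!r} must be positive")
        if self.n < 1:
            raise ValueError("n must be positive")


def implied_covariance(
    dag: DagStructure, coefficients: dict[Edge, float], noise_sd: dict[str, float]
) -> pd.DataFrame:
    """Population covariance (I - B)^-1 D (I - B)^-T of the model."""
    names = list(dag.nodes)
    p = len(names)
    idx = {n: i for i, n in enumerate(names)}
    B = np.zeros((p, p))
    for (u, v), beta in coefficients.items():
        B[idx[v], idx[u]] = beta
    D = np.diag([noise_sd[n] ** 2 for n in names])
    M = np.linalg.inv(np.eye(p) - B)
    return pd.DataFrame(M @ D @ M.T, index=names, columns=names)


def unit_variance_noise(
    dag: DagStructure, coefficients: dict[Edge, float]
) -> dict[str, float]:
    """Solve noise SDs so each node has unit marginal variance.

    Walks the DAG in topological order, tracking the implied covariance;
    raises if any node's parental signal variance reaches 1 (no positive
    noise variance could bring the marginal back to unity).
    """
    names = list(dag.nodes)
    idx = {n: i for i, n in enumerate(names)}
    Sigma = np.zeros((len(names), len(names)))
    noise: dict[str, float] = {}
    for node in dag.topological_order():
        i = idx[node]
        parents = sorted(dag.parents(node))
        if parents:
            b = np.array([coefficients[(p, node)] for p in parents])
            pj = [idx[p] for p in parents]
            signal = float(b @ Sigma[np.ix_(pj, pj)] @ b)
            for other in names:
                Sigma[i, idx[other]] = Sigma[idx[other], i] = float(
                    b @ Sigma[pj, idx[other]]
                )
        else:
            signal = 0.0
        if signal >= 1.0:
            raise ValueError(
                f"node {node!r} has parental signal variance {signal:.3f} >= 1; "
                "cannot standardize to unit marginal variance"
            )
        noise[node] = float(np.sqrt(1.0 - signal))
        Sigma[i, i] = 1.0
    return noise


def simulate_sem(
    spec: SemSpecification,
    *,
    roles: dict[str, str] | None = None,
) -> VariableTable:
    """Draw n samples from the structural model, in topological order.

    Each node equals the coefficient-weighted sum of its parents plus
    independent Gaussian noise.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    values: dict[str, np.ndarray] = {}
    for node in spec.dag.topological_order():
        col = spec.noise_sd[node] * rng.standard_normal(spec.n)
        for parent in sorted(spec.dag.parents(node)):
            col = col + spec.coefficients[(parent, node)] * values[parent]
        values[node] = col
    frame = pd.DataFrame({name: values[name] for name in spec.dag.nodes})
    return VariableTable(frame, roles)


# --- study-like fixture ----------------------------------------------------

STUDY_NODES = (
    "Tobacco", "Drug", "Alcohol", "EmoIssues", "Behavioral", "Somatic",
    "PRS", "External",
)

#: Standardized path coefficients of the study-like generating model.
#: The outcome's direct effects (Alcohol 0.33, EmoIssues 0.20, Behavioral
#: 0.10, PRS 0.07) are the quantities the recovery tests target; the
#: remaining edges wire the substance-use factors together and into the
#: parental problem factors at plausible strengths.  The weak
#: Tobacco -> PRS edge induces the near-zero (|r| ~ 0.05) correlation
#: between the polygenic score and the parental factors that passive
#: gene-environment correlation would produce.
STUDY_COEFFICIENTS: dict[Edge, float] = {
    ("Tobacco", "Drug"): 0.45,
    ("Tobacco", "Alcohol"): 0.25,
    ("Drug", "Alcohol"): 0.45,
    ("Alcohol", "EmoIssues"): 0.55,
    ("Alcohol", "Behavioral"): 0.25,
    ("EmoIssues", "Behavioral"): 0.30,
    ("EmoIssues", "Somatic"): 0.45,
    ("Tobacco", "PRS"): 0.05,
    ("Alcohol", "External"): 0.33,
    ("EmoIssues", "External"): 0.20,
    ("Behavioral", "External"): 0.10,
    ("PRS", "External"): 0.07,
}

STUDY_ROLES = {"External": "outcome", "PRS": "genetic"}


def study_like_spec(n: int, seed: int) -> SemSpecification:
    """The generating model behind :func:`make_study_like` (ground truth)."""
    if n < 500:
        raise ValueError("study-like fixture needs n >= 500")
    dag = DagStructure(STUDY_NODES, STUDY_COEFFICIENTS.keys())
    noise = unit_variance_noise(dag, STUDY_COEFFICIENTS)
    return SemSpecification(dag, dict(STUDY_COEFFICIENTS), noise, n, seed)


def make_study_like(n: int, seed: int) -> VariableTable:
    """Eight-factor study-like table with roles assigned.

    Outcome = ``External`` (child externalizing behavior), genetic =
    ``PRS``; every variable has unit population variance.
    """
    return simulate_sem(study_like_spec(n, seed), roles=dict(STUDY_ROLES))


def make_correlated_blocks(
    block_sizes: tuple[int, ...] | list[int],
    within_r: float,
    between_r: float,
    n: int,
    seed: int,
) -> VariableTable:
    """Gaussian table with block-equicorrelation structure, standardized.

    Variables are named ``B{i}V{j}``.  Correlation is ``within_r`` inside
    a block and ``between_r`` across blocks; the implied matrix must be
    positive definite.
    """
    sizes = [int(s) for s in block_sizes]
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError("block sizes must be positive")
    p = sum(sizes)
    R = np.full((p, p), float(between_r))
    start = 0
    names: list[str] = []
    for bi, size in enumerate(sizes):
        R[start : start + size, start : start + size] = float(within_r)
        names.extend(f"B{bi + 1}V{j + 1}" for j in range(size))
        start += size
    np.fill_diagonal(R, 1.0)
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise ValueError(
            "requested block correlation matrix is not positive definite"
        ) from None
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p)) @ L.T
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    return VariableTable(pd.DataFrame(Z, columns=names))


def write_dataset(
    table: VariableTable,
    csv_path: str | Path,
    spec: SemSpecification | None = None,
    truth_path: str | Path | None = None,
) -> None:
    """Write a generated table as CSV plus an optional ground-truth sidecar."""
    table.write_table(csv_path)
    if spec is not None and truth_path is not None:
        truth = {
            "nodes": list(spec.dag.nodes),
            "edges": sorted(map(list, spec.dag.edges)),
            "coefficients": {
                f"{u}->{v}": beta for (u, v), beta in sorted(spec.coefficients.items())
            },
            "noise_sd": {k: spec.noise_sd[k] for k in spec.dag.nodes},
            "n": spec.n,
            "seed": spec.seed,
            "roles": table.roles,
        }
        Path(truth_path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
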