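"""Quantification of a learned DAG as a recursive linear path model.

Every node with parents is regressed on exactly its DAG parents; because
the model is recursive (acyclic) with independent errors and no latent
variables, these equation-wise OLS estimates are the maximum-likelihood
path coefficients.  Inputs are z-scored, so coefficients are standardized
effects.  Direct effects sit on single edges; the total effect of a
source on a target sums, over every directed path, the product of edge
coefficients along the path — equivalently, the (target, source) entry of
(I - B)^-1 - I for the coefficient matrix B.  Both routes are computed
and must agree, which guards the path enumeration against bookkeeping
bugs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .graph import DagStructure
from .preprocess import StandardizedDataset

_AGREEMENT_TOL = 1e-10


@dataclass(frozen=True)
class EquationFit:
    """One structural equation: a node regressed on its DAG parents."""

    node: str
    parents: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float] = field(compare=False)
    std_errors: dict[str, float] = field(compare=False)
    p_values: dict[str, float] = field(compare=False)
    rss: float = 0.0
    n: int = 0


@dataclass(frozen=True)
class PathModel:
    """Per-node linear equations plus the direct-effect matrix B.

    ``coefficient_matrix`` is a square DataFrame with
    ``B.loc[child, parent]`` holding the direct effect on each edge and
    zero elsewhere; its sparsity pattern matches the DAG edge set.
    """

    dag: DagStructure
    equations: dict[str, EquationFit] = field(compare=False)
    coefficient_matrix: pd.DataFrame = field(compare=False)

    def direct_effect(self, source: str, target: str) -> float:
        return float(self.coefficient_matrix.loc[target, source])


def fit_path_model(dag: DagStructure, data: StandardizedDataset) -> PathModel:
    """OLS fit of every node with >= 1 parent on its parents.

    Standard errors come from the classical OLS covariance and p-values
    from the t distribution with n - k - 1 degrees of freedom.
    """
    known = set(data.names)
    unknown = [n for n in dag.nodes if n not in known]
    if unknown:
        raise ValueError(f"DAG nodes {unknown} not present in the data")
    equations: dict[str, EquationFit] = {}
    B = pd.DataFrame(
        np.zeros((len(dag.nodes), len(dag.nodes))),
        index=list(dag.nodes),
        columns=list(dag.nodes),
    )
    for node in dag.nodes:
        parents = tuple(sorted(dag.parents(node)))
        if not parents:
            continue
        y = data.column(node)
        X = sm.add_constant(data.frame[list(parents)].to_numpy())
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"rank-deficient design for node {node!r}: parents {parents} "
                "are collinear"
            )
        res = sm.OLS(y, X).fit()
        coefs = dict(zip(parents, map(float, res.params[1:])))
        ses = dict(zip(parents, map(float, res.bse[1:])))
        pvals = dict(zip(parents, map(float, res.pvalues[1:])))
        equations[node] = EquationFit(
            node,
            parents,
            float(res.params[0]),
            coefs,
            ses,
            pvals,
            float(res.ssr),
            data.n,
        )
        for parent, beta in coefs.items():
            B.loc[node, parent] = beta
    return PathModel(dag, equations, B)


def enumerate_paths(
    dag: DagStructure, target: str
) -> dict[str, list[list[str]]]:
    """All simple directed paths from each node into ``target``.

    Discovered breadth-first, so shorter paths are listed before longer
    ones; within a length, children are expanded in lexicographic order.
    Nodes with no path (including the target itself) map to an empty
    list.
    """
    if target not in dag.nodes:
        raise ValueError(f"target {target!r} not in DAG")
    result: dict[str, list[list[str]]] = {}
    for source in dag.nodes:
        paths: list[list[str]] = []
        if source != target:
            queue: deque[list[str]] = deque([[source]])
            while queue:
                path = queue.popleft()
                tail = path[-1]
                if tail == target:
                    paths.append(path)
                    continue
                for child in sorted(dag.children(tail)):
                    if child not in path:
                        queue.append(path + [child])
        result[source] = paths
    return result


@dataclass(frozen=True)
class EffectTable:
    """Direct/indirect/total effects of every source on one target."""

    target: str
    table: pd.DataFrame = field(compare=False)
    paths: dict[str, list[list[str]]] = field(compare=False)

    def path_frame(self, model: PathModel) -> pd.DataFrame:
        rows = []
        B = model.coefficient_matrix
        for source, paths in self.paths.items():
            for path in paths:
                product = 1.0
                for parent, child in zip(path, path[1:]):
                    product *= float(B.loc[child, parent])
                rows.append(
                    {
                        "source": source,
                        "path": " -> ".join(path),
                        "path_product": product,
                    }
                )
        return pd.DataFrame(rows, columns=["source", "path", "path_product"])


def total_effects(model: PathModel, target: str) -> EffectTable:
    """Direct, indirect and total standardized effects on ``target``.

    Total effects are computed twice — as path-products summed over the
    BFS path enumeration, and as entries of (I - B)^-1 - I — and the two
    must agree to 1e-10.  B is nilpotent for a DAG, so I - B is always
    invertible.
    """
    dag = model.dag
    B = model.coefficient_matrix.to_numpy()
    p = B.shape[0]
    try:
        T = np.linalg.inv(np.eye(p) - B) - np.eye(p)
    except np.linalg.LinAlgError:  # pragma: no cover - impossible for a DAG
        raise AssertionError("I - B is singular, coefficient matrix is not nilpotent")
    names = list(dag.nodes)
    t_idx = names.index(target)
    paths = enumerate_paths(dag, target)
    rows = []
    for source in names:
        if source == target:
            continue
        total_paths = 0.0
        for path in paths[source]:
            product = 1.0
            for parent, child in zip(path, path[1:]):
                product *= B[names.index(child), names.index(parent)]
            total_paths += product
        total_matrix = float(T[t_idx, names.index(source)])
        if abs(total_paths - total_matrix) > _AGREEMENT_TOL:
            raise AssertionError(
                f"path-sum total effect {total_paths!r} disagrees with matrix "
                f"route {total_matrix!r} for {source} -> {target}"
            )
        direct = model.direct_effect(source, target)
        eq = model.equations.get(target)
        se = p_value = float("nan")
        if eq is not None and source in eq.std_errors:
            se = eq.std_errors[source]
            p_value = eq.p_values[source]
        rows.append(
            {
                "source": source,
                "target": target,
                "direct": direct,
                "se": se,
                "p_value": p_value,
                "indirect": total_paths - direct,
                "total": total_paths,
            }
        )
    table = pd.DataFrame(
        rows, columns=["source", "target", "direct", "se", "p_value", "indirect", "total"]
    )
    return EffectTable(target, table, paths)


def equations_text(model: PathModel) -> str:
    """Structural equations in `child ~ parent1 + parent2` notation."""
    lines = []
    for node in model.dag.nodes:
        parents = sorted(model.dag.parents(node))
        if parents:
            lines.append(f"{node} ~ " + " + ".join(parents))
    return "\n".join(lines) + ("\n" if lines else "")
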