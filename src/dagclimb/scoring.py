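"""Decomposable linear-Gaussian BIC scoring of DAG structures.

Each node is modeled as a linear regression on its DAG parents with
Gaussian noise, X_i = b0 + sum_j b_j X_j + e, e ~ N(0, sigma^2).  The
local score is the maximized Gaussian log-likelihood minus a BIC penalty
counting k slopes, the intercept and the residual variance:

    BIC(X_i | Pa) = -(n/2) * [ln(2*pi) + 1 + ln(RSS/n)] - ((k+2)/2) * ln(n)

Larger (less negative) is better; the graph score is the sum of local
scores, so single-edge moves re-score only the touched node(s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Iterable

import numpy as np

if TYPE_CHECKING:
    from .graph import DagStructure
    from .preprocess import StandardizedDataset

VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class LocalFit:
    """OLS fit of one node on its parent set."""

    node: str
    parents: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float] = field(compare=False)
    rss: float = 0.0
    n: int = 0

    @property
    def k(self) -> int:
        return len(self.parents)

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be nonnegative")
        if self.n <= self.k + 1:
            raise ValueError("need n > k + 1 observations")


def fit_local_regression(
    data: "StandardizedDataset", node: str, parents: Iterable[str]
) -> LocalFit:
    """Least-squares fit of ``node`` on ``parents`` (with intercept).

    Uses an orthogonal-decomposition solver rather than the normal
    equations: aggregated factors can be nearly collinear and the
    normal equations square the condition number.
    """
    parents = tuple(parents)
    if node in parents:
        raise ValueError(f"node {node!r} cannot be its own parent")
    y = data.column(node)
    n = y.shape[0]
    k = len(parents)
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k}) for node {node!r}")
    if k == 0:
        mean = float(y.mean())
        rss = float(((y - mean) ** 2).sum())
        return LocalFit(node, (), mean, {}, rss, n)
    X = np.column_stack([np.ones(n)] + [data.column(p) for p in parents])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k + 1:
        raise ValueError(
            f"rank-deficient design for node {node!r}: parents {parents} "
            "are collinear"
        )
    resid = y - X @ beta
    rss = float(resid @ resid)
    coefs = {p: float(b) for p, b in zip(parents, beta[1:])}
    return LocalFit(node, parents, float(beta[0]), coefs, rss, n)


def local_bic_score(
    fit: LocalFit, *, variance_floor: float = VARIANCE_FLOOR, clamp: bool = False
) -> float:
    """Evaluate the local BIC of a fitted node; larger is better.

    A residual variance below ``variance_floor`` signals perfect
    collinearity; by default this is an error, because silently clamping
    would fabricate an effectively unbounded score.  Pass ``clamp=True``
    to floor the variance instead for exploratory runs.
    """
    s2 = fit.rss / fit.n
    if s2 < variance_floor:
        if not clamp:
            raise ValueError(
                f"degenerate fit for node {fit.node!r}: rss/n = {s2:.3e} "
                f"below variance floor {variance_floor:.1e}"
            )
        s2 = variance_floor
    n, k = fit.n, fit.k
    loglik = -(n / 2.0) * (math.log(2.0 * math.pi) + 1.0 + math.log(s2))
    penalty = ((k + 2) / 2.0) * math.log(n)
    return loglik - penalty


class ScoreCache:
    """Memo of local scores keyed by (node, frozen parent set).

    Parent sets are canonicalized to frozensets, so the cache is
    insensitive to parent ordering.  Results with and without the cache
    are bit-identical because the cached value is exactly the value the
    scorer returned.
    """

    def __init__(self) -> None:
        self.entries: dict[tuple[str, frozenset[str]], float] = {}
        self.hits = 0
        self.misses = 0

    def get_or_compute(
        self, node: str, parents: Iterable[str], compute: Callable[[], float]
    ) -> float:
        key = (node, frozenset(parents))
        if key in self.entries:
            self.hits += 1
            return self.entries[key]
        self.misses += 1
        value = compute()
        self.entries[key] = value
        return value

    def __len__(self) -> int:
        return len(self.entries)


def local_score(
    data: "StandardizedDataset",
    node: str,
    parents: Iterable[str],
    cache: ScoreCache | None = None,
    *,
    clamp: bool = False,
) -> float:
    """Local BIC of ``node`` given ``parents``, via the cache if given."""
    parents = tuple(sorted(parents))

    def compute() -> float:
        return local_bic_score(fit_local_regression(data, node, parents), clamp=clamp)

    if cache is None:
        return compute()
    return cache.get_or_compute(node, parents, compute)


def total_bic_score(
    dag: "DagStructure",
    data: "StandardizedDataset",
    cache: ScoreCache | None = None,
) -> float:
    """Sum of local BIC scores over all nodes of the DAG."""
    known = set(data.names)
    unknown = [n for n in dag.nodes if n not in known]
    if unknown:
        raise ValueError(f"DAG nodes {unknown} not present in the data")
    return sum(local_score(data, node, dag.parents(node), cache) for node in dag.nodes)
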