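"""Hill-climb structure search over DAGs under blacklist constraints.

Starting from an empty graph, the search repeatedly evaluates every legal
single-edge modification (addition, removal, reversal), applies the one
with the largest score improvement, and stops at a local optimum.  The
scoring function is decomposable, so a move's delta touches only the
local score(s) of the affected child node(s).

Expert knowledge enters as a blacklist of forbidden directed edges; by
default the outcome variable may not point anywhere (it is a sink) and
the genetic score may not point at the aggregated parental factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .graph import DagStructure, Edge
from .preprocess import StandardizedDataset
from .scoring import ScoreCache, local_score

__all__ = [
    "DagStructure",
    "EdgeConstraintSet",
    "SearchConfig",
    "SearchTrace",
    "Move",
    "default_constraints",
    "candidate_moves",
    "hill_climb",
]


class Move(NamedTuple):
    kind: str  # "add" | "remove" | "reverse"
    u: str
    v: str


@dataclass(frozen=True)
class EdgeConstraintSet:
    """Set of forbidden directed edges."""

    forbidden: frozenset[Edge] = frozenset()

    def allows(self, u: str, v: str) -> bool:
        return (u, v) not in self.forbidden

    def validate(self, nodes: Iterable[str]) -> None:
        known = set(nodes)
        for u, v in self.forbidden:
            if u not in known or v not in known:
                raise ValueError(f"constraint ({u!r}, {v!r}) references unknown node")


def default_constraints(
    nodes: Sequence[str],
    outcome: str,
    genetic: str | None = None,
    parental_factors: Sequence[str] = (),
) -> EdgeConstraintSet:
    """Blacklist: no edge out of the outcome; genetic -/-> parental factors.

    Nothing else is forbidden — in particular genetic -> outcome and
    parental -> genetic edges remain available to the search.
    """
    known = set(nodes)
    for name in [outcome, *( [genetic] if genetic else [] ), *parental_factors]:
        if name not in known:
            raise ValueError(f"unknown node {name!r} in constraint specification")
    forbidden: set[Edge] = {(outcome, n) for n in nodes if n != outcome}
    if genetic is not None:
        forbidden |= {(genetic, f) for f in parental_factors if f != genetic}
    return EdgeConstraintSet(frozenset(forbidden))


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the greedy search.

    epsilon is the minimal score improvement for accepting a move; it
    guards against float-noise oscillation.  max_iterations defaults to
    10 * p**2 (each move changes one edge, so this is generous).
    """

    epsilon: float = 1e-9
    max_iterations: int | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iterations is not None and self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")

    def iteration_budget(self, p: int) -> int:
        return self.max_iterations if self.max_iterations is not None else 10 * p * p


@dataclass
class TraceRecord:
    iteration: int
    move: Move
    delta: float
    total_score: float


@dataclass
class SearchTrace:
    """Per-iteration record of accepted moves and the score path."""

    initial_score: float = 0.0
    records: list[TraceRecord] = field(default_factory=list)
    hit_max_iterations: bool = False

    @property
    def final_score(self) -> float:
        return self.records[-1].total_score if self.records else self.initial_score

    def to_jsonl(self) -> str:
        lines = [
            json.dumps(
                {
                    "iteration": r.iteration,
                    "move": list(r.move),
                    "delta": r.delta,
                    "total_score": r.total_score,
                },
                sort_keys=True,
            )
            for r in self.records
        ]
        return "\n".join(lines) + ("\n" if lines else "")


def candidate_moves(
    dag: DagStructure, constraints: EdgeConstraintSet | None = None
) -> list[Move]:
    """All legal single-edge modifications, in deterministic order.

    Additions first, then removals, then reversals; lexicographic within
    each class.  An addition must not be present, forbidden or
    cycle-creating.  A reversal requires the reversed edge not to be
    forbidden and the result to stay acyclic.
    """
    constraints = constraints or EdgeConstraintSet()
    moves: list[Move] = []
    nodes = sorted(dag.nodes)
    for u in nodes:
        for v in nodes:
            if u == v or dag.has_edge(u, v):
                continue
            if not constraints.allows(u, v):
                continue
            if dag.has_directed_path(v, u):
                continue  # would create a cycle
            moves.append(Move("add", u, v))
    for u, v in sorted(dag.edges):
        moves.append(Move("remove", u, v))
    for u, v in sorted(dag.edges):
        if not constraints.allows(v, u):
            continue
        if dag.has_directed_path(u, v, ignore_edge=(u, v)):
            continue  # reversal would create a cycle
        moves.append(Move("reverse", u, v))
    return moves


def _move_delta(
    move: Move,
    dag: DagStructure,
    data: StandardizedDataset,
    local: dict[str, float],
    cache: ScoreCache,
) -> float:
    kind, u, v = move
    if kind == "add":
        return local_score(data, v, dag.parents(v) | {u}, cache) - local[v]
    if kind == "remove":
        return local_score(data, v, dag.parents(v) - {u}, cache) - local[v]
    if kind == "reverse":
        d_child = local_score(data, v, dag.parents(v) - {u}, cache) - local[v]
        d_parent = local_score(data, u, dag.parents(u) | {v}, cache) - local[u]
        return d_child + d_parent
    raise ValueError(f"unknown move kind {kind!r}")


def _apply(move: Move, dag: DagStructure) -> DagStructure:
    kind, u, v = move
    if kind == "add":
        return dag.add_edge(u, v)
    if kind == "remove":
        return dag.remove_edge(u, v)
    return dag.reverse_edge(u, v)


def hill_climb(
    data: StandardizedDataset,
    constraints: EdgeConstraintSet | None = None,
    config: SearchConfig | None = None,
    *,
    initial: DagStructure | None = None,
    cache: ScoreCache | None = None,
) -> tuple[DagStructure, SearchTrace]:
    """Steepest-ascent hill climb from the empty graph.

    Each iteration scores every legal move and applies the single move
    with the largest positive delta (ties broken by the deterministic
    move ordering of :func:`candidate_moves`).  Stops when no move
    improves the score by more than ``config.epsilon``, or when the
    iteration budget is exhausted (flagged in the trace).
    """
    if data.p < 2:
        raise ValueError("structure search needs at least 2 variables")
    if data.n <= data.p + 1:
        raise ValueError("structure search needs n > p + 1 samples")
    constraints = constraints or EdgeConstraintSet()
    constraints.validate(data.names)
    config = config or SearchConfig()
    cache = cache or ScoreCache()
    dag = initial if initial is not None else DagStructure(data.names)

    local = {node: local_score(data, node, dag.parents(node), cache) for node in dag.nodes}
    trace = SearchTrace(initial_score=sum(local.values()))
    total = trace.initial_score
    budget = config.iteration_budget(data.p)

    def best_neighbor_delta(candidate: DagStructure) -> float:
        cand_local = {
            node: local_score(data, node, candidate.parents(node), cache)
            for node in candidate.nodes
        }
        return max(
            (
                _move_delta(m, candidate, data, cand_local, cache)
                for m in candidate_moves(candidate, constraints)
            ),
            default=0.0,
        )

    for iteration in range(budget):
        scored = [
            (move, _move_delta(move, dag, data, local, cache))
            for move in candidate_moves(dag, constraints)
        ]
        top = max((d for _, d in scored), default=0.0)
        if top <= config.epsilon:
            break  # local optimum
        # Deltas within epsilon of the maximum count as exact ties (score
        # equivalence makes e.g. X->Y vs Y->X mathematically equal, and
        # float noise from row order must not decide).  Ties are resolved
        # by a one-move lookahead: equally scoring orientations can lead
        # to different equivalence classes one move later (a collider is
        # reachable only through the right orientation), so the tied move
        # whose successor graph has the best follow-up delta wins;
        # remaining ties fall back to the deterministic move ordering.
        tied = [(m, d) for m, d in scored if d >= top - config.epsilon]
        if len(tied) == 1:
            best_move, best_delta = tied[0]
        else:
            ahead = [
                (best_neighbor_delta(_apply(m, dag)), m, d) for m, d in tied
            ]
            top_ahead = max(a for a, _, _ in ahead)
            best_move, best_delta = next(
                (m, d) for a, m, d in ahead if a >= top_ahead - config.epsilon
            )
        dag = _apply(best_move, dag)
        touched = {best_move.v}
        if best_move.kind == "reverse":
            touched.add(best_move.u)
        for node in touched:
            local[node] = local_score(data, node, dag.parents(node), cache)
        total = sum(local.values())
        trace.records.append(TraceRecord(iteration, best_move, best_delta, total))
    else:
        trace.hit_max_iterations = True

    return dag, trace
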