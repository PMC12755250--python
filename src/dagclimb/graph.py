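"""Immutable directed-acyclic-graph container used throughout the pipeline.

The search loop mutates structures thousands of times per run, so edits are
expressed as cheap copy-on-write operations (:meth:`DagStructure.add_edge`
and friends) that re-validate acyclicity on construction.  Validation is
O(nodes + edges) via Kahn's algorithm, negligible at the graph sizes this
package targets (tens of variables).
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

Edge = tuple[str, str]


class CycleError(ValueError):
    """Raised when a requested edge set contains a directed cycle."""


class DagStructure:
    """A directed acyclic graph over named variables.

    Parameters
    ----------
    nodes:
        Ordered, unique variable names.  The order is remembered and used
        for deterministic tie-breaking downstream.
    edges:
        Iterable of ``(parent, child)`` pairs.  Self-loops, unknown names
        and cycles are rejected.
    """

    __slots__ = ("_nodes", "_edges", "_parents", "_children", "_hash")

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge] = ()) -> None:
        self._nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self._nodes)) != len(self._nodes):
            raise ValueError("node names must be unique")
        if any(not isinstance(n, str) or not n for n in self._nodes):
            raise ValueError("node names must be non-empty strings")
        known = set(self._nodes)
        edge_set = frozenset((str(u), str(v)) for u, v in edges)
        for u, v in edge_set:
            if u not in known or v not in known:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            if u == v:
                raise ValueError(f"self-loop on {u!r} is not allowed")
        self._edges: frozenset[Edge] = edge_set
        parents: dict[str, set[str]] = {n: set() for n in self._nodes}
        children: dict[str, set[str]] = {n: set() for n in self._nodes}
        for u, v in edge_set:
            parents[v].add(u)
            children[u].add(v)
        self._parents = {n: frozenset(s) for n, s in parents.items()}
        self._children = {n: frozenset(s) for n, s in children.items()}
        self._hash: int | None = None
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        indeg = {n: len(self._parents[n]) for n in self._nodes}
        queue = deque(n for n in self._nodes if indeg[n] == 0)
        seen = 0
        while queue:
            n = queue.popleft()
            seen += 1
            for c in self._children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self._nodes):
            raise CycleError("edge set contains a directed cycle")

    # -- basic queries -----------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> frozenset[Edge]:
        return self._edges

    def parents(self, node: str) -> frozenset[str]:
        return self._parents[node]

    def children(self, node: str) -> frozenset[str]:
        return self._children[node]

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self._edges

    def has_directed_path(
        self, src: str, dst: str, *, ignore_edge: Edge | None = None
    ) -> bool:
        """True if a directed path src -> ... -> dst exists (length >= 1)."""
        stack = [src]
        visited: set[str] = set()
        while stack:
            n = stack.pop()
            for c in self._children[n]:
                if ignore_edge is not None and (n, c) == ignore_edge:
                    continue
                if c == dst:
                    return True
                if c not in visited:
                    visited.add(c)
                    stack.append(c)
        return False

    def topological_order(self) -> tuple[str, ...]:
        """Kahn's algorithm; ties broken by the declared node order."""
        index = {n: i for i, n in enumerate(self._nodes)}
        indeg = {n: len(self._parents[n]) for n in self._nodes}
        ready = sorted((n for n in self._nodes if indeg[n] == 0), key=index.get)
        order: list[str] = []
        while ready:
            n = ready.pop(0)
            order.append(n)
            changed = False
            for c in self._children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
                    changed = True
            if changed:
                ready.sort(key=index.get)
        return tuple(order)

    # -- copy-on-write edits ----------------------------------------------

    def add_edge(self, u: str, v: str) -> "DagStructure":
        return DagStructure(self._nodes, self._edges | {(u, v)})

    def remove_edge(self, u: str, v: str) -> "DagStructure":
        if (u, v) not in self._edges:
            raise ValueError(f"edge ({u!r}, {v!r}) not present")
        return DagStructure(self._nodes, self._edges - {(u, v)})

    def reverse_edge(self, u: str, v: str) -> "DagStructure":
        if (u, v) not in self._edges:
            raise ValueError(f"edge ({u!r}, {v!r}) not present")
        return DagStructure(self._nodes, (self._edges - {(u, v)}) | {(v, u)})

    # -- dunder plumbing ---------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DagStructure):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self._nodes, self._edges))
        return self._hash

    def __iter__(self) -> Iterator[str]:
        return iter(self._nodes)

    def __repr__(self) -> str:
        return (
            f"DagStructure(nodes={len(self._nodes)}, "
            f"edges={sorted(self._edges)})"
        )

    # -- interchange -------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(sorted(self._edges))
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self._edges), columns=["parent", "child"])

    def to_dot(self) -> str:
        lines = ["digraph dag {"]
        for n in self._nodes:
            lines.append(f'  "{n}";')
        for u, v in sorted(self._edges):
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)
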