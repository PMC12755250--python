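"""Shared fixtures: small deterministic tables and graph helpers."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dagclimb import DagStructure, StandardizedDataset, VariableTable, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_table():
    """4-sample, 3-variable table with hand-checkable correlations."""
    frame = pd.DataFrame(
        {
            "A": [1.0, 2.0, 3.0, 4.0],
            "B": [2.0, 1.0, 4.0, 3.0],
            "C": [-1.0, -2.0, -3.0, -4.0],
        }
    )
    return VariableTable(frame)


@pytest.fixture
def gaussian_data(rng):
    """200 x 4 independent standard-normal standardized dataset."""
    frame = pd.DataFrame(
        rng.standard_normal((200, 4)), columns=["W", "X", "Y", "Z"]
    )
    return standardize(VariableTable(frame))


def all_dags(nodes):
    """Enumerate every DAG over the given nodes (oracle-grade brute force)."""
    pairs = [
        (u, v) for u, v in itertools.permutations(nodes, 2)
    ]
    dags = []
    for mask in itertools.product([False, True], repeat=len(pairs)):
        edges = [p for p, keep in zip(pairs, mask) if keep]
        if any((v, u) in edges for u, v in edges):
            continue
        try:
            dags.append(DagStructure(nodes, edges))
        except ValueError:
            continue
    return dags


def markov_class(dag):
    """Skeleton + v-structures, the invariants of Markov equivalence."""
    skeleton = frozenset(frozenset(e) for e in dag.edges)
    v_structs = set()
    for node in dag.nodes:
        for a, b in itertools.combinations(sorted(dag.parents(node)), 2):
            if not dag.has_edge(a, b) and not dag.has_edge(b, a):
                v_structs.add((a, node, b))
    return skeleton, frozenset(v_structs)


@pytest.fixture
def three_node_dags():
    return all_dags(("A", "B", "C"))


def standardized_from_array(arr, names, roles=None) -> StandardizedDataset:
    return standardize(VariableTable(pd.DataFrame(arr, columns=names), roles))
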