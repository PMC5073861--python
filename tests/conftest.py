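"""Shared fixtures: toy graphs, random-graph builders, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from degraph.deg_core import ADVERSE, DEG, DEGEdge


def make_deg(drugs, effects, edges, label=ADVERSE):
    """Convenience DEG builder from id lists and (drug, effect) pairs."""
    deg = DEG()
    for d in drugs:
        deg.add_drug(d)
    for e in effects:
        deg.add_effect(e)
    for d, e in edges:
        deg.add_edge(DEGEdge(d, e, label=label))
    return deg


@pytest.fixture
def toy_t1():
    """Two drugs, three effects, a path-like topology used throughout."""
    return make_deg(
        ["d1", "d2"],
        ["e1", "e2", "e3"],
        [("d1", "e1"), ("d1", "e2"), ("d2", "e2"), ("d2", "e3")],
    )


def random_bipartite_deg(rng: np.random.Generator, max_nodes: int = 30) -> DEG:
    """A random small bipartite graph (possibly with isolated nodes)."""
    n_drugs = int(rng.integers(1, max_nodes // 2 + 1))
    n_effects = int(rng.integers(1, max_nodes - n_drugs + 1))
    drugs = [f"d{i}" for i in range(n_drugs)]
    effects = [f"e{j}" for j in range(n_effects)]
    p = rng.uniform(0.05, 0.5)
    edges = [
        (d, e) for d in drugs for e in effects if rng.random() < p
    ]
    return make_deg(drugs, effects, edges)


def oracle_gamma(deg: DEG, node: tuple[str, str]) -> set[tuple[str, str]]:
    """Independent Γ oracle: breadth-first search capped at depth 2 over an
    explicit adjacency list, excluding the start node."""
    adjacency: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for (d, e) in deg.edges:
        adjacency.setdefault(("drug", d), set()).add(("effect", e))
        adjacency.setdefault(("effect", e), set()).add(("drug", d))
    frontier = {node}
    seen = {node}
    for _ in range(2):
        frontier = {
            nbr for x in frontier for nbr in adjacency.get(x, set())
        } - seen
        seen |= frontier
    return seen - {node}
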