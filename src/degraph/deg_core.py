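"""Bipartite drug-effect graph (DEG) data model and construction.

A DEG has drug nodes and effect nodes in disjoint partite sets; every edge
joins a drug to an effect.  Edges carry a class label (``adverse`` when the
pair is recorded in a SIDER-style database, ``pseudo_non_adverse`` when it
is treated as a negative example without asserting true absence) and two
optional weights: the mean day gap between the mentions that produced the
edge, and the number of per-user graphs that contributed it.

The *pharmacological neighborhood* Γ(x) of a node is the set of nodes
reachable within two hops of x, excluding x itself: two drugs are
neighbors when they share an effect, and vice versa, so Γ of a drug mixes
effects (one hop) and drugs (two hops).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ADVERSE = "adverse"
PSEUDO_NON_ADVERSE = "pseudo_non_adverse"
UNLABELED = "unlabeled"
_LABELS = frozenset({ADVERSE, PSEUDO_NON_ADVERSE, UNLABELED})


@dataclass(frozen=True)
class DrugNode:
    """A drug vertex: opaque canonical compound id plus display name."""

    id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("drug node id must be non-empty")


@dataclass(frozen=True)
class EffectNode:
    """An effect vertex: UMLS-CUI-style concept id plus display name."""

    id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("effect node id must be non-empty")


@dataclass
class DEGEdge:
    """One drug-effect edge with label and optional dual weights."""

    drug_id: str
    effect_id: str
    label: str = UNLABELED
    temporal_weight: float | None = None
    frequency_weight: int | None = None

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"unknown edge label {self.label!r}")
        if self.temporal_weight is not None:
            if not math.isfinite(self.temporal_weight) or self.temporal_weight < 0:
                raise ValueError(
                    f"temporal_weight must be finite and >= 0, got {self.temporal_weight}"
                )
        if self.frequency_weight is not None and self.frequency_weight < 1:
            raise ValueError(
                f"frequency_weight must be >= 1, got {self.frequency_weight}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_id, self.effect_id)


class DEG:
    """Bipartite drug-effect graph.

    Drugs and effects live in disjoint id namespaces: the same string may
    appear as both a drug id and an effect id without the partite sets
    colliding.  At most one edge exists per (drug_id, effect_id) pair.
    """

    def __init__(self) -> None:
        self._drugs: dict[str, DrugNode] = {}
        self._effects: dict[str, EffectNode] = {}
        self._edges: dict[tuple[str, str], DEGEdge] = {}
        # adjacency: drug id -> set of effect ids, and the reverse
        self._adj_d: dict[str, set[str]] = {}
        self._adj_e: dict[str, set[str]] = {}

    # -- construction ----------------------------------------------------

    def add_drug(self, node: DrugNode | str, name: str = "") -> DrugNode:
        if isinstance(node, str):
            node = DrugNode(node, name)
        existing = self._drugs.get(node.id)
        if existing is None:
            self._drugs[node.id] = node
            self._adj_d[node.id] = set()
        elif not existing.name and node.name:
            self._drugs[node.id] = node
        return self._drugs[node.id]

    def add_effect(self, node: EffectNode | str, name: str = "") -> EffectNode:
        if isinstance(node, str):
            node = EffectNode(node, name)
        existing = self._effects.get(node.id)
        if existing is None:
            self._effects[node.id] = node
            self._adj_e[node.id] = set()
        elif not existing.name and node.name:
            self._effects[node.id] = node
        return self._effects[node.id]

    def add_edge(self, edge: DEGEdge) -> DEGEdge:
        """Insert an edge; endpoints must already exist. Replaces any
        previous edge on the same pair."""
        if edge.drug_id not in self._drugs:
            raise KeyError(f"unknown drug node {edge.drug_id!r}")
        if edge.effect_id not in self._effects:
            raise KeyError(f"unknown effect node {edge.effect_id!r}")
        self._edges[edge.pair] = edge
        self._adj_d[edge.drug_id].add(edge.effect_id)
        self._adj_e[edge.effect_id].add(edge.drug_id)
        return edge

    def remove_edge(self, drug_id: str, effect_id: str) -> DEGEdge:
        edge = self._edges.pop((drug_id, effect_id))
        self._adj_d[drug_id].discard(effect_id)
        self._adj_e[effect_id].discard(drug_id)
        return edge

    # -- views -----------------------------------------------------------

    @property
    def drugs(self) -> Mapping[str, DrugNode]:
        return self._drugs

    @property
    def effects(self) -> Mapping[str, EffectNode]:
        return self._effects

    @property
    def edges(self) -> Mapping[tuple[str, str], DEGEdge]:
        return self._edges

    def n_drugs(self) -> int:
        return len(self._drugs)

    def n_effects(self) -> int:
        return len(self._effects)

    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, drug_id: str, effect_id: str) -> bool:
        return (drug_id, effect_id) in self._edges

    def adverse_pairs(self) -> set[tuple[str, str]]:
        return {p for p, e in self._edges.items() if e.label == ADVERSE}

    def effects_of(self, drug_id: str) -> frozenset[str]:
        """Effect ids adjacent (one hop) to a drug."""
        if drug_id not in self._adj_d:
            raise KeyError(f"unknown drug node {drug_id!r}")
        return frozenset(self._adj_d[drug_id])

    def drugs_of(self, effect_id: str) -> frozenset[str]:
        """Drug ids adjacent (one hop) to an effect."""
        if effect_id not in self._adj_e:
            raise KeyError(f"unknown effect node {effect_id!r}")
        return frozenset(self._adj_e[effect_id])

    def degree(self, node_id: str, partite: str) -> int:
        """Incident-edge count (one hop), distinct from |Γ|."""
        if partite == "drug":
            return len(self._adj_d[node_id])
        if partite == "effect":
            return len(self._adj_e[node_id])
        raise ValueError(f"partite must be 'drug' or 'effect', got {partite!r}")

    def copy(self) -> "DEG":
        out = DEG()
        out._drugs = dict(self._drugs)
        out._effects = dict(self._effects)
        out._edges = {
            p: DEGEdge(e.drug_id, e.effect_id, e.label, e.temporal_weight, e.frequency_weight)
            for p, e in self._edges.items()
        }
        out._adj_d = {k: set(v) for k, v in self._adj_d.items()}
        out._adj_e = {k: set(v) for k, v in self._adj_e.items()}
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DEG):
            return NotImplemented
        return (
            self._drugs == other._drugs
            and self._effects == other._effects
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        return (
            f"DEG(drugs={len(self._drugs)}, effects={len(self._effects)}, "
            f"edges={len(self._edges)})"
        )


# -- neighborhood ---------------------------------------------------------


def neighborhood(deg: DEG, node_id: str, partite: str | None = None) -> set[tuple[str, str]]:
    """Pharmacological neighborhood Γ(x): all nodes within two hops of x.

    Returns a set of ``(partite_class, node_id)`` tuples so that drug and
    effect ids cannot collide.  x itself is excluded.  For a drug node the
    result holds its adjacent effects (distance 1) and the drugs sharing
    those effects (distance 2); symmetrically for an effect node.

    ``partite`` ('drug' or 'effect') disambiguates when the same id string
    exists in both partite sets; when omitted the id must be unambiguous.
    """
    is_drug = node_id in deg.drugs
    is_effect = node_id in deg.effects
    if partite == "drug":
        is_effect = False
    elif partite == "effect":
        is_drug = False
    if is_drug and is_effect:
        raise KeyError(
            f"node id {node_id!r} exists in both partite sets; pass partite="
        )
    if is_drug:
        one_hop = deg.effects_of(node_id)
        two_hop: set[str] = set()
        for eff in one_hop:
            two_hop |= deg.drugs_of(eff)
        two_hop.discard(node_id)
        return {("effect", e) for e in one_hop} | {("drug", d) for d in two_hop}
    if is_effect:
        one_hop = deg.drugs_of(node_id)
        two_hop = set()
        for drug in one_hop:
            two_hop |= deg.effects_of(drug)
        two_hop.discard(node_id)
        return {("drug", d) for d in one_hop} | {("effect", e) for e in two_hop}
    raise KeyError(f"unknown node id {node_id!r}")


# -- SIDER ingestion ------------------------------------------------------


def load_sider(rows: Iterable[Sequence[str]]) -> DEG:
    """Build a DEG from SIDER-style relationship rows.

    Each row carries ``(drug_id, drug_name, effect_id, effect_name)``.
    One node is created per distinct id, one edge labeled adverse per
    distinct (drug_id, effect_id) pair; duplicate rows collapse (logged).
    A row with a missing or empty id is rejected with its row number.
    """
    deg = DEG()
    duplicates = 0
    for i, row in enumerate(rows, start=1):
        if len(row) < 4:
            raise ValueError(f"row {i}: expected 4 columns, got {len(row)}")
        drug_id, drug_name, effect_id, effect_name = row[0], row[1], row[2], row[3]
        if not drug_id or not effect_id:
            raise ValueError(f"row {i}: empty drug or effect id")
        deg.add_drug(drug_id, drug_name)
        deg.add_effect(effect_id, effect_name)
        if deg.has_edge(drug_id, effect_id):
            duplicates += 1
            continue
        deg.add_edge(DEGEdge(drug_id, effect_id, label=ADVERSE))
    if duplicates:
        logger.info("load_sider: collapsed %d duplicate rows", duplicates)
    return deg


def load_sider_tsv(path: str | Path) -> DEG:
    """Read the 4-column, headered, UTF-8 SIDER-style TSV."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            return DEG()
        rows = (line.rstrip("\n").split("\t") for line in fh if line.strip())
        return load_sider(rows)


# -- pseudo-negative sampling --------------------------------------------


def sample_pseudo_negatives(deg: DEG, n: int, seed: int) -> set[tuple[str, str]]:
    """Draw n distinct (drug_id, effect_id) pairs uniformly, without
    replacement, from the pairs *not* labeled adverse in ``deg``.

    Sampling is rejection-free: ranks are drawn over the complement's size
    and mapped past the sorted adverse pair indices.  Fully reproducible
    from ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return set()
    drug_ids = sorted(deg.drugs)
    effect_ids = sorted(deg.effects)
    m = len(effect_ids)
    total = len(drug_ids) * m
    eff_index = {e: j for j, e in enumerate(effect_ids)}
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    adverse = np.fromiter(
        (
            drug_index[d] * m + eff_index[e]
            for (d, e) in deg.adverse_pairs()
        ),
        dtype=np.int64,
    )
    adverse.sort()
    available = total - len(adverse)
    if n > available:
        raise ValueError(
            f"requested {n} pseudo-negative pairs but only {available} "
            f"non-adverse pairs exist"
        )
    rng = np.random.default_rng(seed)
    ranks = rng.choice(available, size=n, replace=False).astype(np.int64)
    # map complement ranks to absolute pair indices by skipping adverse ones
    idx = ranks.copy()
    while True:
        shifted = ranks + np.searchsorted(adverse, idx, side="right")
        if np.array_equal(shifted, idx):
            break
        idx = shifted
    return {(drug_ids[int(i) // m], effect_ids[int(i) % m]) for i in idx}


# -- merging --------------------------------------------------------------


def merge_degs(user_degs: Sequence[DEG]) -> DEG:
    """Merge per-user DEGs into one graph.

    Nodes and edges are unioned.  For an edge present in c member graphs
    the merged temporal_weight is the arithmetic mean of the member
    weights and frequency_weight = c.  Every member edge must carry a
    temporal weight.
    """
    merged = DEG()
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    labels: dict[tuple[str, str], str] = {}
    for g in user_degs:
        for node in g.drugs.values():
            merged.add_drug(node)
        for node in g.effects.values():
            merged.add_effect(node)
        for pair, edge in g.edges.items():
            if edge.temporal_weight is None:
                raise ValueError(
                    f"member edge {pair} lacks a temporal weight; cannot average"
                )
            sums[pair] = sums.get(pair, 0.0) + edge.temporal_weight
            counts[pair] = counts.get(pair, 0) + 1
            labels[pair] = edge.label
    for pair, c in counts.items():
        merged.add_edge(
            DEGEdge(
                pair[0],
                pair[1],
                label=labels[pair],
                temporal_weight=sums[pair] / c,
                frequency_weight=c,
            )
        )
    return merged


# -- serialization --------------------------------------------------------

_EDGE_HEADER = "drug_id\teffect_id\tlabel\ttemporal_weight\tfrequency_weight"


def write_deg(deg: DEG, path: str | Path) -> None:
    """Write a DEG as an edge-list TSV.

    Node declarations (including isolated nodes and display names) go in
    ``#drug``/``#effect`` comment lines before the header so that
    ``read_deg(write_deg(g)) == g`` exactly; missing weights serialize as
    empty fields.  Float weights are written with ``repr`` so they
    round-trip at full precision.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for node in sorted(deg.drugs.values(), key=lambda d: d.id):
            fh.write(f"#drug\t{node.id}\t{node.name}\n")
        for node in sorted(deg.effects.values(), key=lambda e: e.id):
            fh.write(f"#effect\t{node.id}\t{node.name}\n")
        fh.write(_EDGE_HEADER + "\n")
        for pair in sorted(deg.edges):
            e = deg.edges[pair]
            tw = "" if e.temporal_weight is None else repr(float(e.temporal_weight))
            fw = "" if e.frequency_weight is None else str(int(e.frequency_weight))
            fh.write(f"{e.drug_id}\t{e.effect_id}\t{e.label}\t{tw}\t{fw}\n")


def read_deg(path: str | Path) -> DEG:
    """Read an edge-list TSV written by :func:`write_deg`."""
    deg = DEG()
    with open(path, encoding="utf-8") as fh:
        lineno = 0
        header_seen = False
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#drug\t") or line.startswith("#effect\t"):
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"line {lineno}: malformed node declaration")
                kind, node_id, name = parts[0][1:], parts[1], parts[2]
                if kind == "drug":
                    deg.add_drug(node_id, name)
                else:
                    deg.add_effect(node_id, name)
                continue
            if not header_seen:
                if line != _EDGE_HEADER:
                    raise ValueError(f"line {lineno}: unexpected header {line!r}")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"line {lineno}: expected 5 fields, got {len(parts)}")
            drug_id, effect_id, label, tw, fw = parts
            try:
                deg.add_edge(
                    DEGEdge(
                        drug_id,
                        effect_id,
                        label=label,
                        temporal_weight=float(tw) if tw else None,
                        frequency_weight=int(fw) if fw else None,
                    )
                )
            except (KeyError, ValueError) as err:
                raise ValueError(f"line {lineno}: {err}") from err
    return deg
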