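"""Topological edge features over a drug-effect graph.

For a drug d and effect e the features are computed from the two-hop
pharmacological neighborhoods Γ(d) and Γ(e):

* common neighbors        N(d,e)  = |Γ(d) ∩ Γ(e)|
* Jaccard coefficient     S(d,e)  = |Γ(d) ∩ Γ(e)| / |Γ(d) ∪ Γ(e)|
* Adamic-Adar index       A(d,e)  = Σ_{z ∈ Γ(d) ∩ Γ(e)} 1 / ln|Γ(z)|
* preferential attachment PA(d,e) = |Γ(d)| · |Γ(e)|

plus the plain one-hop degrees of both endpoints.  The Adamic-Adar sum
skips any common neighbor with |Γ(z)| ≤ 1 (ln 1 = 0 would blow up the
term); Jaccard of two empty neighborhoods is 0 by convention.  The query
pair need not be an edge of the graph, and the graph is featurized as
given — an existing edge is not removed first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from degraph.deg_core import DEG, neighborhood


@dataclass(frozen=True)
class TopoFeatureVector:
    """The six topological statistics for one (drug, effect) pair."""

    degree_d: int
    degree_e: int
    common_neighbors: int
    jaccard: float
    adamic_adar: float
    pref_attach: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.degree_d,
                self.degree_e,
                self.common_neighbors,
                self.jaccard,
                self.adamic_adar,
                self.pref_attach,
            ],
            dtype=float,
        )


TOPO_COLUMNS: tuple[str, ...] = tuple(f.name for f in fields(TopoFeatureVector))


def _gammas(deg: DEG, d: str, e: str):
    gd = neighborhood(deg, d, partite="drug")
    ge = neighborhood(deg, e, partite="effect")
    return gd, ge


def common_neighbors(deg: DEG, d: str, e: str) -> int:
    """N(d,e): size of the intersection of the two-hop neighborhoods."""
    gd, ge = _gammas(deg, d, e)
    return len(gd & ge)


def jaccard(deg: DEG, d: str, e: str) -> float:
    """S(d,e): common-neighborhood fraction of the combined neighborhood."""
    gd, ge = _gammas(deg, d, e)
    union = gd | ge
    if not union:
        return 0.0
    return len(gd & ge) / len(union)


def adamic_adar(deg: DEG, d: str, e: str) -> float:
    """A(d,e): common neighbors down-weighted by their own connectedness."""
    gd, ge = _gammas(deg, d, e)
    total = 0.0
    for klass, z in gd & ge:
        size = len(neighborhood(deg, z, partite=klass))
        if size > 1:
            total += 1.0 / math.log(size)
    return total


def preferential_attachment(deg: DEG, d: str, e: str) -> int:
    """PA(d,e): product of the two-hop neighborhood sizes."""
    gd, ge = _gammas(deg, d, e)
    return len(gd) * len(ge)


def featurize_edge(deg: DEG, d: str, e: str) -> TopoFeatureVector:
    """All six topological features from one neighborhood computation."""
    gd, ge = _gammas(deg, d, e)
    inter = gd & ge
    union = gd | ge
    aa = 0.0
    for klass, z in inter:
        size = len(neighborhood(deg, z, partite=klass))
        if size > 1:
            aa += 1.0 / math.log(size)
    return TopoFeatureVector(
        degree_d=deg.degree(d, "drug"),
        degree_e=deg.degree(e, "effect"),
        common_neighbors=len(inter),
        jaccard=(len(inter) / len(union)) if union else 0.0,
        adamic_adar=aa,
        pref_attach=len(gd) * len(ge),
    )


def neighborhood_map(deg: DEG) -> dict[tuple[str, str], frozenset]:
    """Γ for every node at once, keyed by (partite_class, id).

    Bulk featurization over many pairs reuses this instead of recomputing
    two-hop sets per query.
    """
    gammas: dict[tuple[str, str], frozenset] = {}
    for d in deg.drugs:
        gammas[("drug", d)] = frozenset(neighborhood(deg, d, partite="drug"))
    for e in deg.effects:
        gammas[("effect", e)] = frozenset(neighborhood(deg, e, partite="effect"))
    return gammas


def feature_frame(
    deg: DEG,
    pairs: Iterable[tuple[str, str]],
    labels: Sequence[str] | None = None,
    insert_query: bool = False,
) -> pd.DataFrame:
    """Topological feature matrix for a collection of (drug, effect) pairs.

    Returns a DataFrame with columns drug_id, effect_id, label (empty
    string when no labels given) and the six feature columns in fixed
    order.  Neighborhoods are computed once per node, not once per pair.

    With ``insert_query=True`` every queried pair is featurized as if its
    edge were present in the graph (pairs that already are edges are
    unaffected).  This is the uniform convention for classification:
    hypothetical candidates are scored after insertion, so training
    negatives must be featurized the same way — otherwise the classifier
    learns mere edge presence instead of neighborhood structure.  The
    insertion is applied through an incremental neighborhood update; the
    graph itself is never mutated.
    """
    pairs = list(pairs)
    if labels is not None and len(labels) != len(pairs):
        raise ValueError("labels length must match pairs")
    gammas = neighborhood_map(deg)
    log_sizes = {
        key: (math.log(len(g)) if len(g) > 1 else None) for key, g in gammas.items()
    }
    rows = []
    for i, (d, e) in enumerate(pairs):
        key_d, key_e = ("drug", d), ("effect", e)
        inserted = insert_query and not deg.has_edge(d, e)
        if inserted:
            # adding edge (d,e) extends Γ(d) by e and e's drugs, Γ(e) by d
            # and d's effects; other nodes gain at most the new endpoint
            gd = gammas[key_d] | {key_e} | {("drug", x) for x in deg.drugs_of(e)}
            ge = gammas[key_e] | {key_d} | {("effect", y) for y in deg.effects_of(d)}
            degree_d = deg.degree(d, "drug") + 1
            degree_e = deg.degree(e, "effect") + 1
        else:
            gd, ge = gammas[key_d], gammas[key_e]
            degree_d = deg.degree(d, "drug")
            degree_e = deg.degree(e, "effect")
        inter = gd & ge
        union_size = len(gd) + len(ge) - len(inter)
        if inserted:
            drugs_of_e = deg.drugs_of(e)
            effects_of_d = deg.effects_of(d)
            aa = 0.0
            for z in inter:
                size = len(gammas[z])
                if z[0] == "drug" and z[1] in drugs_of_e and key_d not in gammas[z]:
                    size += 1
                elif z[0] == "effect" and z[1] in effects_of_d and key_e not in gammas[z]:
                    size += 1
                if size > 1:
                    aa += 1.0 / math.log(size)
        else:
            aa = sum(1.0 / log_sizes[z] for z in inter if log_sizes[z] is not None)
        rows.append(
            (
                d,
                e,
                labels[i] if labels is not None else "",
                float(degree_d),
                float(degree_e),
                float(len(inter)),
                (len(inter) / union_size) if union_size else 0.0,
                aa,
                float(len(gd) * len(ge)),
            )
        )
    return pd.DataFrame(
        rows, columns=["drug_id", "effect_id", "label", *TOPO_COLUMNS]
    )


def write_feature_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    """CSV writer: header row (drug_id, effect_id, label, features...)."""
    frame.to_csv(path, index=False)
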