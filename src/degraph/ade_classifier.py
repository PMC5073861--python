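"""Edge classification: feature assembly, the 10-tree forest, evaluation.

Four feature configurations are supported, each a superset of the last:

* ``topo``            — Twitter-side topological features plus the two
                        edge weights (mean day gap, contributing users)
* ``topo_sent``       — adds the edge sentiment pair (s_drug, s_effect)
* ``topo_sent_topic`` — adds the 2k topic context (drug context ++ effect
                        context)
* ``enriched``        — adds the SIDER-side topological features for the
                        same pair; when either endpoint is absent from the
                        SIDER graph the block is all-zero and an indicator
                        flag is set

Classification uses a 10-tree random forest; evaluation reports
precision, recall and F1 with a 50/50 train/test split and stratified
10-fold cross-validation on the training half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from degraph.deg_core import ADVERSE, DEG
from degraph.semantic_context import EdgeSentimentContext
from degraph.topo_features import TOPO_COLUMNS, featurize_edge

FEATURE_SETS = ("topo", "topo_sent", "topo_sent_topic", "enriched")


@dataclass
class EdgeContexts:
    """Per-edge sentiment and per-entity topic contexts for a DEG."""

    sentiment: Mapping[tuple[str, str], EdgeSentimentContext] = field(
        default_factory=dict
    )
    topic: Mapping[str, np.ndarray] = field(default_factory=dict)
    k: int = 0


def feature_columns(selector: str, k: int = 0) -> list[str]:
    """Ordered column names for a feature configuration."""
    if selector not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {selector!r}")
    cols = [f"tw_{c}" for c in TOPO_COLUMNS] + ["temporal_weight", "frequency_weight"]
    if selector in ("topo_sent", "topo_sent_topic", "enriched"):
        cols += ["s_drug", "s_effect"]
    if selector in ("topo_sent_topic", "enriched"):
        cols += [f"topic_d_{i}" for i in range(k)]
        cols += [f"topic_e_{i}" for i in range(k)]
    if selector == "enriched":
        cols += [f"sider_{c}" for c in TOPO_COLUMNS] + ["missing_sider_flag"]
    return cols


def featurize(
    pair: tuple[str, str],
    deg_twitter: DEG,
    deg_sider: DEG | None,
    contexts: EdgeContexts | None,
    selector: str = "topo",
) -> np.ndarray:
    """Assemble one edge's feature vector for the chosen configuration."""
    if selector not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {selector!r}")
    d, e = pair
    edge = deg_twitter.edges.get(pair)
    if edge is None:
        raise KeyError(f"pair {pair} is not an edge of the Twitter DEG")
    blocks = [featurize_edge(deg_twitter, d, e).as_array()]
    blocks.append(
        np.array(
            [
                edge.temporal_weight if edge.temporal_weight is not None else 0.0,
                edge.frequency_weight if edge.frequency_weight is not None else 0.0,
            ]
        )
    )
    if selector in ("topo_sent", "topo_sent_topic", "enriched"):
        if contexts is None or pair not in contexts.sentiment:
            raise ValueError(f"sentiment context missing for edge {pair}")
        sc = contexts.sentiment[pair]
        blocks.append(np.array([sc.s_drug, sc.s_effect]))
    if selector in ("topo_sent_topic", "enriched"):
        if contexts is None or d not in contexts.topic or e not in contexts.topic:
            raise ValueError(f"topic context missing for an endpoint of {pair}")
        blocks.append(np.asarray(contexts.topic[d], dtype=float))
        blocks.append(np.asarray(contexts.topic[e], dtype=float))
    if selector == "enriched":
        if deg_sider is None:
            raise ValueError("enriched features need the SIDER DEG")
        if d in deg_sider.drugs and e in deg_sider.effects:
            blocks.append(featurize_edge(deg_sider, d, e).as_array())
            blocks.append(np.array([0.0]))
        else:
            blocks.append(np.zeros(len(TOPO_COLUMNS)))
            blocks.append(np.array([1.0]))
    return np.concatenate(blocks)


def build_feature_frame(
    deg_twitter: DEG,
    deg_sider: DEG | None = None,
    contexts: EdgeContexts | None = None,
    selector: str = "topo",
) -> pd.DataFrame:
    """Feature matrix over every edge of the Twitter DEG.

    Indexed by (drug_id, effect_id) with a binary ``label`` column
    (1 = adverse) followed by the selector's feature columns.
    """
    k = contexts.k if contexts is not None else 0
    cols = feature_columns(selector, k)
    pairs = sorted(deg_twitter.edges)
    rows = [featurize(p, deg_twitter, deg_sider, contexts, selector) for p in pairs]
    frame = pd.DataFrame(
        rows, columns=cols, index=pd.MultiIndex.from_tuples(pairs, names=["drug_id", "effect_id"])
    )
    frame.insert(
        0,
        "label",
        [int(deg_twitter.edges[p].label == ADVERSE) for p in pairs],
    )
    return frame


# -- training and evaluation ----------------------------------------------


def train_edge_classifier(
    feature_matrix: np.ndarray | pd.DataFrame,
    labels: Sequence[int],
    seed: int = 0,
    n_trees: int = 10,
) -> RandomForestClassifier:
    """Fit the 10-tree random forest; reproducible from ``seed``."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(np.asarray(feature_matrix, dtype=float), y)
    return model


def evaluate(
    model: RandomForestClassifier,
    feature_matrix: np.ndarray | pd.DataFrame,
    labels: Sequence[int],
) -> tuple[float, float, float]:
    """(precision, recall, F1) on the positive class.

    Precision is 0 when no positive predictions are made; F1 is 0 when
    both precision and recall are 0.
    """
    y = np.asarray(labels, dtype=int)
    pred = model.predict(np.asarray(feature_matrix, dtype=float))
    return _prf(y, pred)


def _prf(y: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum((y == 1) & (pred == 1)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def cross_validate(
    feature_matrix: np.ndarray | pd.DataFrame,
    labels: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    n_trees: int = 10,
) -> dict[str, dict[str, float]]:
    """Stratified k-fold cross-validation of the 10-tree forest.

    Returns mean and standard deviation of precision, recall and F1 over
    folds; a fold whose validation slice collapses to one class scores 0
    on its undefined metrics (warned).
    """
    import warnings

    X = np.asarray(feature_matrix, dtype=float)
    y = np.asarray(labels, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = {"precision": [], "recall": [], "f1": []}
    for fit_idx, val_idx in skf.split(X, y):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(X[fit_idx], y[fit_idx])
        if len(np.unique(y[val_idx])) < 2:
            warnings.warn("cross_validate: single-class validation fold")
        p, r, f = _prf(y[val_idx], clf.predict(X[val_idx]))
        per_fold["precision"].append(p)
        per_fold["recall"].append(r)
        per_fold["f1"].append(f)
    return {
        metric: {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
        for metric, vals in per_fold.items()
    }


def split_train_test(
    edges: Sequence, fraction: float = 0.5, seed: int = 0
) -> tuple[list, list]:
    """Disjoint, exhaustive, seed-reproducible random split.

    ``fraction`` is the training share; with 0.5 the two sides differ in
    size by at most one element.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    edges = list(edges)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    n_train = int(round(fraction * len(edges)))
    train = [edges[i] for i in order[:n_train]]
    test = [edges[i] for i in order[n_train:]]
    return train, test
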