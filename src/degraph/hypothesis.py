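"""Hypothetical adverse-effect edge enumeration and insert-and-classify.

The recorded graph covers only known drug-effect relationships; every
absent (drug, effect) pair is a hypothetical edge.  Each candidate is
inserted into the graph, featurized with the topological features (so its
own presence shapes the neighborhoods, matching how training edges are
featurized), scored by a trained edge classifier, and removed again,
leaving the graph bit-identical.  An offline evidence search scans a
tweet corpus for users who mention both endpoints of a candidate within
the time window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from degraph.deg_core import DEG, DEGEdge
from degraph.topo_features import featurize_edge
from degraph.tweet_pipeline import Lexicon, Tweet
from degraph.twitter_deg_builder import histories_from_tweets


@dataclass(frozen=True)
class CandidateEdge:
    drug_id: str
    effect_id: str
    predicted_label: str
    score: float  # positive-class vote fraction


def enumerate_hypothetical_edges(deg: DEG) -> Iterator[tuple[str, str]]:
    """All (drug, effect) pairs of the full bipartite product that are not
    adverse edges of the graph; exactly |D|*|S| - |E_s| pairs."""
    adverse = deg.adverse_pairs()
    for d in sorted(deg.drugs):
        for e in sorted(deg.effects):
            if (d, e) not in adverse:
                yield (d, e)


def classify_hypothetical(
    candidate: tuple[str, str],
    deg: DEG,
    model: RandomForestClassifier,
    threshold: float = 0.5,
) -> CandidateEdge:
    """Insert one candidate edge, featurize, score, remove.

    The graph is observably unchanged afterwards; repeated calls return
    identical scores.  Endpoints must already exist in the graph.
    """
    d, e = candidate
    if d not in deg.drugs:
        raise KeyError(f"unknown drug node {d!r}")
    if e not in deg.effects:
        raise KeyError(f"unknown effect node {e!r}")
    pre_existing = deg.edges.get(candidate)
    if pre_existing is None:
        deg.add_edge(DEGEdge(d, e))
    try:
        features = featurize_edge(deg, d, e).as_array().reshape(1, -1)
        score = float(model.predict_proba(features)[0, list(model.classes_).index(1)])
    finally:
        if pre_existing is None:
            deg.remove_edge(d, e)
        else:
            deg.add_edge(pre_existing)
    return CandidateEdge(
        drug_id=d,
        effect_id=e,
        predicted_label="adverse" if score >= threshold else "pseudo_non_adverse",
        score=score,
    )


def rank_candidates(
    deg: DEG,
    model: RandomForestClassifier,
    candidates: Iterable[tuple[str, str]] | None = None,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Score candidates (all hypothetical edges by default) and return a
    table sorted descending by score."""
    if candidates is None:
        candidates = enumerate_hypothetical_edges(deg)
    records = [classify_hypothetical(c, deg, model) for c in candidates]
    frame = pd.DataFrame(
        [(r.drug_id, r.effect_id, r.score, r.predicted_label) for r in records],
        columns=["drug_id", "effect_id", "score", "predicted_label"],
    )
    frame = frame.sort_values(
        ["score", "drug_id", "effect_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    if top_n is not None:
        frame = frame.head(top_n)
    return frame


def find_corpus_evidence(
    candidates: Sequence[tuple[str, str]],
    tweet_corpus: Sequence[Tweet],
    lexicon: Lexicon,
    t_window: int = 20,
) -> pd.DataFrame:
    """Users whose histories mention both endpoints of a candidate within
    the time window.

    Returns one row per (candidate, user, drug tweet, effect tweet)
    combination with the day gap; an empty frame when no evidence exists.
    """
    histories = histories_from_tweets(tweet_corpus, lexicon)
    wanted = set(candidates)
    rows = []
    for history in histories:
        drugs = [(m, d) for m, d in history.mentions if m.entity_class == "drug"]
        effects = [(m, d) for m, d in history.mentions if m.entity_class == "effect"]
        for dm, dday in drugs:
            for em, eday in effects:
                pair = (dm.canonical_id, em.canonical_id)
                if pair not in wanted:
                    continue
                gap = abs((dday - eday).days)
                if gap <= t_window:
                    rows.append(
                        (
                            pair[0],
                            pair[1],
                            history.user_id,
                            dm.tweet_id,
                            em.tweet_id,
                            gap,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "drug_id",
            "effect_id",
            "user_id",
            "drug_tweet_id",
            "effect_tweet_id",
            "day_gap",
        ],
    )
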