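"""Build per-user drug-effect graphs from mention timelines and merge them.

For each user, an edge is drawn between a drug mention and an effect
mention whenever their calendar-day gap is at most ``t_window`` days
(default 20; direction-agnostic, same-tweet co-mentions count with gap
0).  The edge's temporal weight is the mean absolute day gap over *all*
qualifying mention pairs of that (drug, effect) in the user's history.
User graphs are then merged: temporal weights average across users and a
frequency weight counts the contributing users.  Edges are labeled
adverse or pseudo-non-adverse by membership in a SIDER-derived DEG.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from degraph.deg_core import (
    ADVERSE,
    DEG,
    DEGEdge,
    PSEUDO_NON_ADVERSE,
    merge_degs,
)
from degraph.tweet_pipeline import EntityMention, Lexicon, Tweet, extract_entities


@dataclass
class BuilderConfig:
    """t_window: maximum day gap for a drug-effect mention pair to draw an
    edge."""

    t_window: int = 20

    def __post_init__(self) -> None:
        if self.t_window < 1:
            raise ValueError("t_window must be >= 1 day")


@dataclass
class UserHistory:
    """Chronologically ordered (mention, date) pairs for one user."""

    user_id: str
    mentions: list[tuple[EntityMention, date]]

    def __post_init__(self) -> None:
        days = [d for _, d in self.mentions]
        if any(b < a for a, b in zip(days, days[1:])):
            raise ValueError("mention dates must be non-decreasing")


def histories_from_tweets(
    tweets: Iterable[Tweet], lexicon: Lexicon
) -> list[UserHistory]:
    """Group tweets by user, extract entities, and order mentions by day."""
    per_user: dict[str, list[tuple[EntityMention, date]]] = defaultdict(list)
    for tweet in sorted(tweets, key=lambda t: (t.user_id, t.timestamp)):
        for mention in extract_entities(tweet, lexicon):
            per_user[tweet.user_id].append((mention, tweet.day))
    return [
        UserHistory(user_id=u, mentions=ms) for u, ms in sorted(per_user.items())
    ]


def build_user_deg(history: UserHistory, config: BuilderConfig | None = None) -> DEG:
    """One user's DEG under the t-day window rule.

    Nodes appear only when they participate in at least one edge; every
    edge's temporal weight is the mean absolute day gap over all
    qualifying (drug mention, effect mention) pairs.
    """
    config = config or BuilderConfig()
    drugs = [(m, d) for m, d in history.mentions if m.entity_class == "drug"]
    effects = [(m, d) for m, d in history.mentions if m.entity_class == "effect"]
    gaps: dict[tuple[str, str], list[int]] = defaultdict(list)
    for dm, dday in drugs:
        for em, eday in effects:
            gap = abs((dday - eday).days)
            if gap <= config.t_window:
                gaps[(dm.canonical_id, em.canonical_id)].append(gap)
    deg = DEG()
    for (drug_id, effect_id), day_gaps in gaps.items():
        deg.add_drug(drug_id)
        deg.add_effect(effect_id)
        deg.add_edge(
            DEGEdge(
                drug_id,
                effect_id,
                temporal_weight=sum(day_gaps) / len(day_gaps),
            )
        )
    return deg


def label_edges(deg: DEG, sider_deg: DEG) -> DEG:
    """Label every edge adverse iff its pair is an adverse edge of the
    SIDER DEG, else pseudo-non-adverse.  Returns the same graph."""
    sider_pairs = sider_deg.adverse_pairs()
    for pair, edge in deg.edges.items():
        edge.label = ADVERSE if pair in sider_pairs else PSEUDO_NON_ADVERSE
    return deg


def build_twitter_deg(
    user_histories: Sequence[UserHistory],
    config: BuilderConfig | None = None,
    sider_deg: DEG | None = None,
) -> DEG:
    """Merge per-user DEGs into the stream-wide graph and label against
    SIDER when given."""
    config = config or BuilderConfig()
    user_degs = [build_user_deg(h, config) for h in user_histories]
    user_degs = [g for g in user_degs if g.n_edges() > 0]
    merged = merge_degs(user_degs)
    if sider_deg is not None:
        label_edges(merged, sider_deg)
    return merged


def window_sweep(
    user_histories: Sequence[UserHistory],
    sider_deg: DEG,
    t_values: Sequence[int],
) -> pd.DataFrame:
    """Edge counts of the merged DEG as the time window grows.

    One row per t with total edges, adverse edges, and the adverse
    fraction (0 when the graph is empty).  Total edges are non-decreasing
    in t because a larger window only adds qualifying pairs.
    """
    rows = []
    for t in t_values:
        if t < 1:
            raise ValueError("t values must be positive integers")
        merged = build_twitter_deg(user_histories, BuilderConfig(t_window=t), sider_deg)
        total = merged.n_edges()
        adverse = sum(1 for e in merged.edges.values() if e.label == ADVERSE)
        rows.append((t, total, adverse, adverse / total if total else 0.0))
    return pd.DataFrame(rows, columns=["t", "total_edges", "adverse_edges", "pct_adverse"])
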