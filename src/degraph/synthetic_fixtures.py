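"""Seeded generators for testing the whole pipeline.

Real side-effect databases and tweet collections are large, licensed, or
ephemeral, so the package ships generators that emulate their relevant
structure:

* :func:`generate_planted_sider` draws a SIDER-like bipartite graph with
  planted block structure — drugs and effects are grouped into blocks and
  adverse edges are much denser inside blocks (``p_in``) than across
  (``p_out``) — so that adverse edges are topologically distinguishable
  from randomly drawn pseudo-non-adverse pairs, mimicking the class-
  separable feature distributions real data exhibits.
* :func:`generate_tweet_stream` scripts per-user timelines in which
  planted (drug, effect) pairs are co-mentioned at controlled day
  offsets, plus far-apart spurious pairs and entity-free spam, with
  sentiment words and topic-segregated filler vocabulary injected so
  every text feature is exercised.  A ledger records every intended edge
  with its true offset, giving downstream tests an exact oracle.
* :func:`case_study_fixture` encodes the 18-tweet / 9-user worked example: one
  user mentions a benzodiazepine two days before three effects (a
  four-node, three-edge graph with weights 2), and the merged stream
  graph has exactly 3 drugs, 9 effects and frequency 1 on every edge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from degraph.deg_core import ADVERSE, DEG, DEGEdge
from degraph.tweet_pipeline import Lexicon, Tweet

# -- planted SIDER-like graph ---------------------------------------------


@dataclass
class PlantedDEGParams:
    n_drugs: int = 50
    n_effects: int = 100
    n_blocks: int = 5
    p_in: float = 0.6
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


def _block_of(index: int, n_items: int, n_blocks: int) -> int:
    # contiguous chunks; remainder spread over the leading blocks
    base, extra = divmod(n_items, n_blocks)
    bound = 0
    for b in range(n_blocks):
        bound += base + (1 if b < extra else 0)
        if index < bound:
            return b
    return n_blocks - 1


def generate_planted_sider(
    params: PlantedDEGParams | None = None,
) -> tuple[DEG, dict[tuple[str, str], int]]:
    """Planted-block bipartite graph plus its ground-truth block map.

    Every drug-effect pair gets an adverse edge with probability ``p_in``
    when the two nodes share a block, else ``p_out``.  The block map is
    keyed by ("drug"|"effect", node_id).  Reproducible from the seed.
    """
    params = params or PlantedDEGParams()
    rng = np.random.default_rng(params.seed)
    deg = DEG()
    drug_ids = [f"CID{i:05d}" for i in range(params.n_drugs)]
    effect_ids = [f"C{i:07d}" for i in range(params.n_effects)]
    blocks: dict[tuple[str, str], int] = {}
    for i, d in enumerate(drug_ids):
        deg.add_drug(d, f"drug{i}")
        blocks[("drug", d)] = _block_of(i, params.n_drugs, params.n_blocks)
    for j, e in enumerate(effect_ids):
        deg.add_effect(e, f"effect{j}")
        blocks[("effect", e)] = _block_of(j, params.n_effects, params.n_blocks)
    draws = rng.random((params.n_drugs, params.n_effects))
    for i, d in enumerate(drug_ids):
        bd = blocks[("drug", d)]
        for j, e in enumerate(effect_ids):
            p = params.p_in if bd == blocks[("effect", e)] else params.p_out
            if draws[i, j] < p:
                deg.add_edge(DEGEdge(d, e, label=ADVERSE))
    return deg, blocks


def generate_random_sider(
    n_drugs: int, n_effects: int, n_edges: int, seed: int = 0
) -> DEG:
    """Uniform random bipartite graph with exactly n_edges adverse edges.

    Used for scale checks where only cardinalities matter.
    """
    total = n_drugs * n_effects
    if n_edges > total:
        raise ValueError("more edges requested than pairs exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=n_edges, replace=False)
    deg = DEG()
    drug_ids = [f"CID{i:05d}" for i in range(n_drugs)]
    effect_ids = [f"C{i:07d}" for i in range(n_effects)]
    for d in drug_ids:
        deg.add_drug(d)
    for e in effect_ids:
        deg.add_effect(e)
    for idx in chosen:
        deg.add_edge(
            DEGEdge(drug_ids[int(idx) // n_effects], effect_ids[int(idx) % n_effects], label=ADVERSE)
        )
    return deg


# -- synthetic tweet streams ----------------------------------------------

_TOPIC_POOLS = (
    ("clinic", "doctor", "dose", "pharmacy", "prescription", "symptom",
     "treatment", "recovery", "hospital", "nurse"),
    ("concert", "movie", "playlist", "weekend", "football", "episode",
     "album", "camping", "recipe", "holiday"),
)
_POSITIVE_WORDS = ("love", "great", "relief", "better")
_NEGATIVE_WORDS = ("hate", "awful", "worse", "terrible")


@dataclass
class StreamParams:
    n_users: int = 40
    planted_pairs_per_user: int = 2
    planted_offset_range: tuple[int, int] = (0, 10)   # days, inclusive
    spurious_pairs_per_user: int = 1
    spurious_offset_range: tuple[int, int] = (30, 60)  # beyond default window
    spam_tweets_per_user: int = 2
    positive_rate: float = 0.3
    negative_rate: float = 0.3
    episode_spacing: int = 100  # days between a user's episodes
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.positive_rate, self.negative_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.planted_offset_range[0] < 0 or self.spurious_offset_range[0] < 0:
            raise ValueError("offsets must be >= 0")


def stream_lexicon(deg: DEG) -> Lexicon:
    """Synthetic surface forms for every node of a generated graph, with
    one extra brand-name synonym per drug and the classic "pic" stop
    entry."""
    drug_synonyms: dict[str, str] = {}
    effect_terms: dict[str, str] = {}
    for i, d in enumerate(sorted(deg.drugs)):
        drug_synonyms[f"drugine{i}"] = d
        drug_synonyms[f"brandol{i}"] = d
    for j, e in enumerate(sorted(deg.effects)):
        effect_terms[f"effectosis{j}"] = e
    return Lexicon(drug_synonyms, effect_terms, stop_list=["pic"])


def generate_tweet_stream(
    deg: DEG, params: StreamParams | None = None
) -> tuple[list[Tweet], list[int], Lexicon, pd.DataFrame]:
    """Scripted per-user timelines plus the ground-truth edge ledger.

    Returns ``(tweets, labels, lexicon, ledger)``.  Labels are 1 for
    experiential tweets and 0 for spam.  The ledger has one row per
    intended (user, drug, effect) co-mention with its exact day offset
    and kind: ``planted`` pairs are adverse edges of ``deg`` emitted
    within the planted offset range; ``spurious`` pairs are non-adverse
    pairs emitted far apart, so they only form edges once the window
    crosses their offset.  Episodes of one user are spaced
    ``episode_spacing`` days apart so they never cross-pair.
    """
    params = params or StreamParams()
    rng = np.random.default_rng(params.seed)
    lexicon = stream_lexicon(deg)
    drug_ids = sorted(deg.drugs)
    effect_ids = sorted(deg.effects)
    drug_surface = {d: f"drugine{i}" for i, d in enumerate(drug_ids)}
    effect_surface = {e: f"effectosis{j}" for j, e in enumerate(effect_ids)}
    adverse = sorted(deg.adverse_pairs())
    non_adverse = [
        (d, e)
        for d in drug_ids
        for e in effect_ids
        if not deg.has_edge(d, e)
    ]
    base = datetime(2016, 1, 1)
    tweets: list[Tweet] = []
    labels: list[int] = []
    ledger_rows = []
    counter = itertools.count(1)

    def filler(topic: int, k: int = 3) -> str:
        pool = _TOPIC_POOLS[topic]
        return " ".join(rng.choice(pool, size=k, replace=True))

    def sentiment_word() -> str:
        u = rng.random()
        if u < params.positive_rate:
            return rng.choice(_POSITIVE_WORDS)
        if u < params.positive_rate + params.negative_rate:
            return rng.choice(_NEGATIVE_WORDS)
        return ""

    for u in range(params.n_users):
        user_id = f"user{u:03d}"
        topic = int(rng.integers(len(_TOPIC_POOLS)))
        episodes: list[tuple[tuple[str, str], int, str]] = []
        if adverse:
            picks = rng.choice(
                len(adverse),
                size=min(params.planted_pairs_per_user, len(adverse)),
                replace=False,
            )
            lo, hi = params.planted_offset_range
            for p in picks:
                episodes.append(
                    (adverse[int(p)], int(rng.integers(lo, hi + 1)), "planted")
                )
        if non_adverse and params.spurious_pairs_per_user:
            picks = rng.choice(
                len(non_adverse),
                size=min(params.spurious_pairs_per_user, len(non_adverse)),
                replace=False,
            )
            lo, hi = params.spurious_offset_range
            for p in picks:
                episodes.append(
                    (non_adverse[int(p)], int(rng.integers(lo, hi + 1)), "spurious")
                )
        for ep_index, ((d, e), offset, kind) in enumerate(episodes):
            day0 = base + timedelta(days=ep_index * params.episode_spacing)
            drug_text = (
                f"i took my {drug_surface[d]} today {sentiment_word()} "
                f"{filler(topic)}"
            )
            effect_text = (
                f"my {effect_surface[e]} again {sentiment_word()} {filler(topic)}"
            )
            tweets.append(
                Tweet(f"t{next(counter)}", user_id, day0, " ".join(drug_text.split()))
            )
            labels.append(1)
            tweets.append(
                Tweet(
                    f"t{next(counter)}",
                    user_id,
                    day0 + timedelta(days=offset),
                    " ".join(effect_text.split()),
                )
            )
            labels.append(1)
            ledger_rows.append((user_id, d, e, offset, kind))
        for s in range(params.spam_tweets_per_user):
            spam_day = base + timedelta(days=int(rng.integers(0, 14)))
            tweets.append(
                Tweet(
                    f"t{next(counter)}",
                    user_id,
                    spam_day,
                    f"check this out #win #free #deal http://spam.example/{u}{s} "
                    f"{filler(1 - topic if len(_TOPIC_POOLS) > 1 else topic)}",
                )
            )
            labels.append(0)
    ledger = pd.DataFrame(
        ledger_rows, columns=["user_id", "drug_id", "effect_id", "offset_days", "kind"]
    )
    return tweets, labels, lexicon, ledger


def expected_merged_edges(ledger: pd.DataFrame, t_window: int = 20) -> pd.DataFrame:
    """The edges the builder should reconstruct from a generated stream at
    a given window: per (drug, effect), the mean offset over qualifying
    (user, pair) episodes and the count of contributing users."""
    visible = ledger[ledger["offset_days"] <= t_window]
    grouped = visible.groupby(["drug_id", "effect_id"]).agg(
        temporal_weight=("offset_days", "mean"),
        frequency_weight=("user_id", "nunique"),
    )
    return grouped.reset_index()


# -- the worked 18-tweet / 9-user example ---------------------------------

_CASE_STUDY_DRUGS = {
    "clonazepam": "CID2802",
    "prednisone": "CID5865",
    "xanax": "CID2118",
    "alprazolam": "CID2118",
}
_CASE_STUDY_EFFECTS = {
    "depression": "C0011570",
    "pain": "C0030193",
    "confusional state": "C0009676",
    "confusion": "C0009676",
    "anxiety": "C0003467",
    "exhaustion": "C0015672",
    "malnutrition": "C0162429",
    "nightmares": "C0028084",
    "hunger": "C0020175",
    "tremors": "C0040822",
}

# (tweet_id, user, date, text); entity surfaces resolve via case_study_lexicon()
_CASE_STUDY_TWEETS = (
    ("t01", "User1", "2016-02-09", "Took my clonazepam before bed again"),
    ("t02", "User1", "2016-02-11", "My depression and pain are unbearable today"),
    ("t03", "User1", "2016-02-11", "Feeling so much confusion lately, hate it"),
    ("t04", "User2", "2016-02-01",
     "Prednisone did kill most of my gut microbes & worsened my malnutrition though"),
    ("t05", "User2", "2016-02-02", "I hope I can sleep better tonight"),
    ("t06", "User3", "2016-01-29", "Just picked up my xanax refill"),
    ("t07", "User3", "2016-02-02", "My anxiety is through the roof tonight"),
    ("t08", "User4", "2016-02-05", "Taking clonazepam again, wish me luck"),
    ("t09", "User4", "2016-02-10", "The exhaustion never ends, I am wiped out"),
    ("t10", "User5", "2016-02-06",
     "Prednisone has me feeling constant hunger, I cannot stop eating"),
    ("t11", "User6", "2016-01-30", "Been on xanax for a week now"),
    ("t12", "User6", "2016-02-08", "Keep waking up from nightmares, it is awful"),
    ("t13", "User7", "2016-02-02", "My doctor upped my prednisone dose"),
    ("t14", "User7", "2016-02-07", "These tremors in my hands will not stop"),
    ("t15", "User8", "2016-02-04", "Xanax helps me get through the day"),
    ("t16", "User8", "2016-02-09", "Fighting my depression every single day"),
    ("t17", "User9", "2016-02-01", "Prednisone round two starts today"),
    ("t18", "User9", "2016-02-06", "This back pain is killing me"),
)

# (drug_id, effect_id, temporal_weight) of the merged case-study graph
_CASE_STUDY_EDGES = (
    ("CID2802", "C0011570", 2.0),  # User1: drug two days before depression
    ("CID2802", "C0030193", 2.0),  # User1: ... pain
    ("CID2802", "C0009676", 2.0),  # User1: ... confusional state
    ("CID5865", "C0162429", 0.0),  # User2: same-tweet co-mention
    ("CID2118", "C0003467", 4.0),  # User3
    ("CID2802", "C0015672", 5.0),  # User4
    ("CID5865", "C0020175", 0.0),  # User5: single tweet
    ("CID2118", "C0028084", 9.0),  # User6
    ("CID5865", "C0040822", 5.0),  # User7
    ("CID2118", "C0011570", 5.0),  # User8
    ("CID5865", "C0030193", 5.0),  # User9
)


def case_study_lexicon() -> Lexicon:
    """Lexicon resolving the case-study surfaces, including the synonym
    mappings (confusion → confusional state, xanax → alprazolam's
    compound id)."""
    return Lexicon(_CASE_STUDY_DRUGS, _CASE_STUDY_EFFECTS, stop_list=["pic"])


def case_study_fixture() -> tuple[list[Tweet], DEG]:
    """The 18-tweet, 9-user worked example and its expected merged DEG.

    User1 posts 3 tweets, User5 one, the remaining users 2 each; one
    drug is mentioned by User1 two days before three effects, so User1's
    graph alone has 4 nodes and 3 edges of weight 2.  Across all users
    the merged graph has 3 drug nodes, 9 effect nodes, and frequency
    weight 1 on every edge (no pair recurs across users).
    """
    tweets = [
        Tweet(tid, user, datetime.fromisoformat(day), text)
        for tid, user, day, text in _CASE_STUDY_TWEETS
    ]
    expected = DEG()
    for drug_id in sorted({v for v in _CASE_STUDY_DRUGS.values()}):
        expected.add_drug(drug_id)
    for effect_id in sorted({v for v in _CASE_STUDY_EFFECTS.values()}):
        expected.add_effect(effect_id)
    for drug_id, effect_id, weight in _CASE_STUDY_EDGES:
        expected.add_edge(
            DEGEdge(drug_id, effect_id, temporal_weight=weight, frequency_weight=1)
        )
    return tweets, expected
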