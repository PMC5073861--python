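"""Semantic context of drug/effect mentions: sentiment and topic features.

Sentiment uses a five-level polarity codomain {2, 1, 0, -1, -2} (very
positive .. very negative).  Any scorer honoring that codomain can be
plugged in; the shipped default counts positive- and negative-lexicon
tokens and clamps their difference to [-2, 2].  The sentiment context of
an edge is the pair of mean scores over the contributing tweets that
mention the drug and the effect respectively.

Topic context comes from latent Dirichlet allocation fitted with the
online variational Bayes algorithm over all tweets containing at least
one drug or effect mention (default k = 20 topics, symmetric document-
topic prior 1/k, topic-word prior 0.01).  A tweet's topic vector lies on
the k-simplex; an entity's topic context is the mean topic vector over
the tweets containing that entity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import CountVectorizer

from degraph.tweet_pipeline import Tweet, tokenize

SENTIMENT_CODOMAIN = frozenset({2, 1, 0, -1, -2})

DEFAULT_POSITIVE = frozenset(
    "love loved loves great good better best amazing awesome happy relief "
    "relieved helps helped helping works worked wonderful fantastic glad "
    "thankful grateful improved improving perfect nice".split()
)
DEFAULT_NEGATIVE = frozenset(
    "hate hated hates bad worse worst awful terrible horrible sad sick "
    "pain painful hurt hurts hurting tired exhausted miserable ugh sucks "
    "worsened killed kill cry crying scared depressed anxious".split()
)


@dataclass
class LexiconSentimentScorer:
    """Default scorer: (#positive tokens - #negative tokens), clamped to
    the five-level codomain."""

    positive: frozenset[str] = DEFAULT_POSITIVE
    negative: frozenset[str] = DEFAULT_NEGATIVE

    def __call__(self, tweet: Tweet) -> int:
        tokens = tokenize(tweet.text)
        raw = sum(t in self.positive for t in tokens) - sum(
            t in self.negative for t in tokens
        )
        return int(max(-2, min(2, raw)))


def score_sentiment(tweet: Tweet, scorer: Callable[[Tweet], int] | None = None) -> int:
    """Score one tweet; validates the scorer's output lies in the
    codomain."""
    scorer = scorer or LexiconSentimentScorer()
    value = scorer(tweet)
    if value not in SENTIMENT_CODOMAIN:
        raise ValueError(
            f"sentiment scorer returned {value!r}, outside {{2,1,0,-1,-2}}"
        )
    return value


@dataclass(frozen=True)
class EdgeSentimentContext:
    """Mean sentiment of the contributing tweets mentioning each
    endpoint."""

    s_drug: float
    s_effect: float


def edge_sentiment(
    contributing_tweets: Sequence[tuple[Tweet, frozenset[str] | set[str]]],
    scorer: Callable[[Tweet], int] | None = None,
) -> EdgeSentimentContext:
    """Sentiment context of an edge.

    ``contributing_tweets`` holds (tweet, endpoints) pairs where endpoints
    is a subset of {"drug", "effect"} saying which of the edge's endpoints
    the tweet mentions; a tweet mentioning both contributes to both means.
    An endpoint with no contributing tweet gets component 0 (logged).
    """
    import logging

    drug_scores: list[int] = []
    effect_scores: list[int] = []
    for tweet, endpoints in contributing_tweets:
        value = score_sentiment(tweet, scorer)
        if "drug" in endpoints:
            drug_scores.append(value)
        if "effect" in endpoints:
            effect_scores.append(value)
    if not drug_scores or not effect_scores:
        logging.getLogger(__name__).warning(
            "edge_sentiment: endpoint with no contributing tweets; component set to 0"
        )
    return EdgeSentimentContext(
        s_drug=float(np.mean(drug_scores)) if drug_scores else 0.0,
        s_effect=float(np.mean(effect_scores)) if effect_scores else 0.0,
    )


# -- topic model ----------------------------------------------------------


@dataclass
class TopicModel:
    """Fitted LDA: vectorizer + estimator + normalized topic-word rows."""

    k: int
    vectorizer: CountVectorizer
    lda: LatentDirichletAllocation

    @property
    def topic_word(self) -> np.ndarray:
        components = self.lda.components_
        return components / components.sum(axis=1, keepdims=True)


def fit_topic_model(
    corpus: Sequence[Tweet | str], k: int = 20, seed: int = 0
) -> TopicModel:
    """Fit k-topic LDA by online variational Bayes over the mention-bearing
    tweet corpus.  Reproducible from ``seed``."""
    if not corpus:
        raise ValueError("cannot fit a topic model on an empty corpus")
    if k < 1:
        raise ValueError("k must be >= 1")
    texts = [t.text if isinstance(t, Tweet) else t for t in corpus]
    vectorizer = CountVectorizer(analyzer=tokenize)
    try:
        X = vectorizer.fit_transform(texts)
    except ValueError as err:
        raise ValueError("corpus contains no tokens") from err
    lda = LatentDirichletAllocation(
        n_components=k,
        learning_method="online",
        doc_topic_prior=1.0 / k,
        topic_word_prior=0.01,
        random_state=seed,
        max_iter=25,
    )
    lda.fit(X)
    return TopicModel(k=k, vectorizer=vectorizer, lda=lda)


def tweet_topic_vector(model: TopicModel, tweet: Tweet | str) -> np.ndarray:
    """θ_tweet: non-negative k-vector summing to 1.

    A tweet whose tokens are all out of vocabulary gets the uniform
    vector.
    """
    text = tweet.text if isinstance(tweet, Tweet) else tweet
    X = model.vectorizer.transform([text])
    if X.nnz == 0:
        return np.full(model.k, 1.0 / model.k)
    theta = model.lda.transform(X)[0]
    return theta / theta.sum()


def entity_topic_context(
    tweets_containing_entity: Sequence[Tweet | str], model: TopicModel
) -> np.ndarray:
    """c(e): component-wise mean of the topic vectors of the tweets
    containing the entity."""
    if not tweets_containing_entity:
        raise ValueError("entity has no containing tweets")
    thetas = np.stack(
        [tweet_topic_vector(model, t) for t in tweets_containing_entity]
    )
    return thetas.mean(axis=0)
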