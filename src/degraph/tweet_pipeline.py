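"""Tweet ingestion, entity extraction, and the experiential-tweet filter.

Short social-media posts mix personal drug-experience reports with
advertisements, news and spam.  This module (a) parses JSON-lines tweet
records, (b) extracts drug and effect mentions by dictionary lookup with
synonym canonicalization and a stop list (longest case-insensitive match
over token n-grams, n ≤ 5), and (c) trains a 10-tree random-forest filter
that keeps only *experiential* tweets — those relating the author's own
experience — using hashtag/negation/URL/pronoun/entity counts plus a
bag-of-words representation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.model_selection import StratifiedKFold

DEFAULT_NEGATIONS = frozenset({"no", "not", "never", "n't", "without", "cannot"})
DEFAULT_PRONOUNS = frozenset(
    {"i", "me", "my", "mine", "we", "us", "our", "you", "your",
     "he", "she", "him", "her", "they", "them"}
)

_URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)", re.IGNORECASE)
_HANDLE_RE = re.compile(r"@\w+")
_HASHTAG_RE = re.compile(r"#(\w+)")
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_NT_RE = re.compile(r"n't", re.IGNORECASE)


@dataclass(frozen=True)
class Tweet:
    tweet_id: str
    user_id: str
    timestamp: datetime
    text: str

    def __post_init__(self) -> None:
        if not self.tweet_id or not self.user_id:
            raise ValueError("tweet_id and user_id must be non-empty")

    @property
    def day(self) -> date:
        return self.timestamp.date()


@dataclass(frozen=True)
class EntityMention:
    """A canonicalized drug or effect mention inside one tweet."""

    tweet_id: str
    canonical_id: str
    entity_class: str  # "drug" | "effect"
    surface: str
    span: tuple[int, int]  # half-open character interval


def _normalize_surface(surface: str) -> str:
    return " ".join(t.lower() for t in _TOKEN_RE.findall(surface))


class Lexicon:
    """Surface-form dictionaries for drugs and effects plus a stop list.

    Lookups are case-insensitive and whitespace/punctuation-normalized;
    stop-listed surfaces never yield mentions even when they also appear
    in a synonym table (they model ambiguous abbreviations like "pic").
    """

    def __init__(
        self,
        drug_synonyms: Mapping[str, str],
        effect_terms: Mapping[str, str],
        stop_list: Iterable[str] = (),
    ) -> None:
        self.drug_synonyms = {
            _normalize_surface(k): v for k, v in drug_synonyms.items()
        }
        self.effect_terms = {
            _normalize_surface(k): v for k, v in effect_terms.items()
        }
        self.stop_list = {_normalize_surface(s) for s in stop_list}
        self._max_ngram = 1
        for key in (*self.drug_synonyms, *self.effect_terms):
            self._max_ngram = max(self._max_ngram, key.count(" ") + 1)
        self._max_ngram = min(self._max_ngram, 5)

    def lookup(self, surface: str) -> tuple[str, str] | None:
        """Resolve a normalized surface to (entity_class, canonical_id)."""
        key = _normalize_surface(surface)
        if key in self.stop_list:
            return None
        if key in self.drug_synonyms:
            return ("drug", self.drug_synonyms[key])
        if key in self.effect_terms:
            return ("effect", self.effect_terms[key])
        return None

    @classmethod
    def from_files(
        cls,
        drug_path: str | Path,
        effect_path: str | Path,
        stop_path: str | Path | None = None,
    ) -> "Lexicon":
        """TSV (surface, canonical_id) per entity class; stop list one term
        per line."""

        def read_tsv(path: str | Path) -> dict[str, str]:
            table: dict[str, str] = {}
            with open(path, encoding="utf-8") as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line:
                        continue
                    surface, canonical = line.split("\t")[:2]
                    table[surface] = canonical
            return table

        stops: list[str] = []
        if stop_path is not None:
            with open(stop_path, encoding="utf-8") as fh:
                stops = [line.strip() for line in fh if line.strip()]
        return cls(read_tsv(drug_path), read_tsv(effect_path), stops)


# -- tokenization ---------------------------------------------------------


@dataclass(frozen=True)
class TokenScan:
    tokens: tuple[str, ...]
    spans: tuple[tuple[int, int], ...]  # char spans in the original text
    n_urls: int
    n_hashtags: int
    n_negations: int


def _scan(text: str, negations: frozenset[str] = DEFAULT_NEGATIONS) -> TokenScan:
    n_urls = len(_URL_RE.findall(text))
    n_hashtags = len(_HASHTAG_RE.findall(text))
    # "n't" disappears when splitting on non-alphanumerics, so count it on
    # the raw text when the configured negation list asks for it
    n_negations = len(_NT_RE.findall(text)) if "n't" in negations else 0
    masked = _URL_RE.sub(lambda m: " " * len(m.group()), text)
    masked = _HANDLE_RE.sub(lambda m: " " * len(m.group()), masked)
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for m in _TOKEN_RE.finditer(masked):
        tok = m.group().lower()
        tokens.append(tok)
        spans.append((m.start(), m.end()))
        if tok in negations and tok != "n't":
            n_negations += 1
    return TokenScan(tuple(tokens), tuple(spans), n_urls, n_hashtags, n_negations)


def tokenize(text: str) -> list[str]:
    """Lowercased tokens split on non-alphanumeric boundaries.

    URLs and @-handles are removed (after being counted elsewhere);
    hashtags keep their word part.
    """
    return list(_scan(text).tokens)


# -- entity extraction ----------------------------------------------------


def extract_entities(tweet: Tweet, lexicon: Lexicon) -> list[EntityMention]:
    """Dictionary extraction: longest-match scan over token n-grams.

    Greedy left-to-right; a match consumes its tokens.  Stop-listed
    surfaces are suppressed, surviving matches canonicalized, and repeated
    mentions of the same canonical id collapse to one per tweet (the first
    occurrence wins).
    """
    scan = _scan(tweet.text)
    tokens, spans = scan.tokens, scan.spans
    max_n = lexicon._max_ngram
    mentions: list[EntityMention] = []
    seen: set[str] = set()
    i = 0
    while i < len(tokens):
        hit = None
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            key = " ".join(tokens[i : i + n])
            if key in lexicon.stop_list:
                hit = ("stop", None, n)
                break
            resolved = lexicon.lookup(key)
            if resolved is not None:
                hit = (resolved[0], resolved[1], n)
                break
        if hit is None:
            i += 1
            continue
        klass, canonical, n = hit
        if klass == "stop":
            i += n
            continue
        span = (spans[i][0], spans[i + n - 1][1])
        if canonical not in seen:
            seen.add(canonical)
            mentions.append(
                EntityMention(
                    tweet_id=tweet.tweet_id,
                    canonical_id=canonical,
                    entity_class=klass,
                    surface=tweet.text[span[0] : span[1]],
                    span=span,
                )
            )
        i += n
    return mentions


# -- filter features ------------------------------------------------------


@dataclass
class TweetFeatureVector:
    """Scalar text statistics plus bag-of-words for the tweet filter."""

    n_hashtags: int
    n_negations: int
    n_urls: int
    n_pronouns: int
    n_drug_entities: int
    n_effect_entities: int
    bag_of_words: sp.csr_matrix  # 1 x |vocabulary|


SCALAR_FEATURES = (
    "n_hashtags",
    "n_negations",
    "n_urls",
    "n_pronouns",
    "n_drug_entities",
    "n_effect_entities",
)


def fit_vocabulary(texts: Sequence[str], min_df: int = 2) -> CountVectorizer:
    """Bag-of-words vocabulary: training tokens with document frequency
    >= min_df, raw term-frequency values."""
    vectorizer = CountVectorizer(analyzer=tokenize, min_df=min_df)
    try:
        vectorizer.fit(texts)
    except ValueError:
        # no token survives the df cutoff: degenerate single-slot vocabulary
        vectorizer = CountVectorizer(analyzer=tokenize, vocabulary={"__empty__": 0})
        vectorizer._validate_vocabulary()
    return vectorizer


def tweet_filter_features(
    tweet: Tweet,
    lexicon: Lexicon,
    vocabulary: CountVectorizer,
    negations: frozenset[str] = DEFAULT_NEGATIONS,
    pronouns: frozenset[str] = DEFAULT_PRONOUNS,
) -> TweetFeatureVector:
    scan = _scan(tweet.text, negations)
    mentions = extract_entities(tweet, lexicon)
    return TweetFeatureVector(
        n_hashtags=scan.n_hashtags,
        n_negations=scan.n_negations,
        n_urls=scan.n_urls,
        n_pronouns=sum(1 for t in scan.tokens if t in pronouns),
        n_drug_entities=sum(1 for m in mentions if m.entity_class == "drug"),
        n_effect_entities=sum(1 for m in mentions if m.entity_class == "effect"),
        bag_of_words=vocabulary.transform([tweet.text]).tocsr(),
    )


def filter_feature_matrix(
    tweets: Sequence[Tweet],
    lexicon: Lexicon,
    vocabulary: CountVectorizer,
    negations: frozenset[str] = DEFAULT_NEGATIONS,
    pronouns: frozenset[str] = DEFAULT_PRONOUNS,
) -> sp.csr_matrix:
    scalars = np.zeros((len(tweets), len(SCALAR_FEATURES)))
    for i, tw in enumerate(tweets):
        scan = _scan(tw.text, negations)
        mentions = extract_entities(tw, lexicon)
        scalars[i] = (
            scan.n_hashtags,
            scan.n_negations,
            scan.n_urls,
            sum(1 for t in scan.tokens if t in pronouns),
            sum(1 for m in mentions if m.entity_class == "drug"),
            sum(1 for m in mentions if m.entity_class == "effect"),
        )
    bow = vocabulary.transform([tw.text for tw in tweets])
    return sp.hstack([sp.csr_matrix(scalars), bow], format="csr")


# -- experiential filter --------------------------------------------------


@dataclass
class ExperientialFilter:
    """A fitted tweet filter: vocabulary + 10-tree random forest."""

    vocabulary: CountVectorizer
    classifier: RandomForestClassifier
    lexicon: Lexicon
    n_features: int

    def predict(self, tweets: Sequence[Tweet]) -> np.ndarray:
        X = filter_feature_matrix(tweets, self.lexicon, self.vocabulary)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature-matrix width {X.shape[1]} does not match the "
                f"model's vocabulary ({self.n_features} columns)"
            )
        return self.classifier.predict(X)


def _prf(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def train_experiential_filter(
    labeled_tweets: Sequence[tuple[Tweet, int]],
    lexicon: Lexicon,
    split_fraction: float = 0.6,
    seed: int = 0,
    n_trees: int = 10,
    cv_folds: int = 10,
) -> tuple[ExperientialFilter, dict]:
    """Train the experiential/non-experiential tweet filter.

    The corpus is split into a training fraction (default 60 %) and a
    held-out test set; the vocabulary is fitted on the training split
    only.  Returns the fitted filter and a metrics dict with 10-fold
    cross-validated precision/recall/F1 on the training split (mean and
    sd) plus held-out metrics.  Reproducible from ``seed``.
    """
    labels = np.array([lab for _, lab in labeled_tweets], dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to train the filter")
    tweets = [tw for tw, _ in labeled_tweets]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tweets))
    n_train = int(round(split_fraction * len(tweets)))
    train_idx, test_idx = order[:n_train], order[n_train:]
    train_tweets = [tweets[i] for i in train_idx]
    y_train, y_test = labels[train_idx], labels[test_idx]

    vocabulary = fit_vocabulary([tw.text for tw in train_tweets])
    X_train = filter_feature_matrix(train_tweets, lexicon, vocabulary)
    X_test = filter_feature_matrix([tweets[i] for i in test_idx], lexicon, vocabulary)

    cv_metrics = {"precision": [], "recall": [], "f1": []}
    folds = min(cv_folds, int(np.min(np.bincount(y_train))))
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for fit_idx, val_idx in skf.split(X_train, y_train):
            clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
            clf.fit(X_train[fit_idx], y_train[fit_idx])
            p, r, f = _prf(y_train[val_idx], clf.predict(X_train[val_idx]))
            cv_metrics["precision"].append(p)
            cv_metrics["recall"].append(r)
            cv_metrics["f1"].append(f)

    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(X_train, y_train)
    p, r, f = _prf(y_test, clf.predict(X_test)) if len(test_idx) else (0.0, 0.0, 0.0)
    metrics = {
        "cv": {
            k: {"mean": float(np.mean(v)) if v else 0.0,
                "sd": float(np.std(v)) if v else 0.0}
            for k, v in cv_metrics.items()
        },
        "test": {"precision": p, "recall": r, "f1": f},
        "n_train": int(n_train),
        "n_test": int(len(test_idx)),
    }
    model = ExperientialFilter(
        vocabulary=vocabulary,
        classifier=clf,
        lexicon=lexicon,
        n_features=X_train.shape[1],
    )
    return model, metrics


def apply_filter(model: ExperientialFilter, tweets: Sequence[Tweet]) -> list[Tweet]:
    """Tweets predicted experiential, order preserved."""
    if not tweets:
        return []
    keep = model.predict(tweets)
    return [tw for tw, k in zip(tweets, keep) if k == 1]


# -- JSON-lines IO --------------------------------------------------------


def parse_tweet(record: Mapping) -> Tweet:
    return Tweet(
        tweet_id=str(record["id"]),
        user_id=str(record["user_id"]),
        timestamp=datetime.fromisoformat(str(record["created_at"])),
        text=str(record["text"]),
    )


def read_tweets_jsonl(path: str | Path) -> list[Tweet]:
    """Read tweets from JSON-lines: {"id","user_id","created_at","text"}."""
    tweets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                tweets.append(parse_tweet(json.loads(line)))
            except (KeyError, ValueError) as err:
                raise ValueError(f"line {lineno}: malformed tweet record ({err})")
    return tweets


def read_labeled_tweets_jsonl(path: str | Path) -> list[tuple[Tweet, int]]:
    """Labeled corpus: tweet records with an integer "label" field
    (1 = experiential)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            record = json.loads(line)
            out.append((parse_tweet(record), int(record["label"])))
    return out


def write_tweets_jsonl(
    tweets: Iterable[Tweet], path: str | Path, labels: Sequence[int] | None = None
) -> None:
    tweets = list(tweets)
    with open(path, "w", encoding="utf-8") as fh:
        for i, tw in enumerate(tweets):
            record = {
                "id": tw.tweet_id,
                "user_id": tw.user_id,
                "created_at": tw.timestamp.isoformat(),
                "text": tw.text,
            }
            if labels is not None:
                record["label"] = int(labels[i])
            fh.write(json.dumps(record) + "\n")
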