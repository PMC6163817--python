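"""Collocation mining over comment text for word-cloud frequency tables.

Frequent multiword expressions (up to 4-grams) are detected by
pointwise-mutual-information (PMI) scoring: an n-gram is kept when its
count reaches a floor and some split into two adjacent units — words or
already-accepted shorter collocations — has PMI above a threshold, so
longer phrases grow out of shorter ones.  Emitted frequencies are raw
within-document
n-gram counts (never cross-document spans), so an n-gram can never be
more frequent than any of its constituent (n-1)-grams.  Public and
government comments are mined separately.  Stop-words are kept: the
target phrases are fixed expressions like "to prevent" or "NEA has"
whose function words carry the signal.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CommentCorpus",
    "CollocationTerm",
    "WordCloudSpec",
    "tokenize_comments",
    "extract_collocations",
    "build_word_cloud_data",
]

_TOKEN_RE = re.compile(r"[\w][\w'’\-]*", re.UNICODE)


@dataclass(frozen=True)
class CommentCorpus:
    """Comment documents from a single author kind (public or government)."""

    author_kind: str
    documents: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.author_kind not in ("public", "government"):
            raise ValueError(f"unknown author_kind {self.author_kind!r}")


@dataclass(frozen=True, order=True)
class CollocationTerm:
    expression: str
    frequency: int
    n: int

    def __post_init__(self) -> None:
        if not 1 <= self.n <= 4:
            raise ValueError("collocation length must be 1..4")
        if self.frequency < 1:
            raise ValueError("frequency must be positive")


@dataclass(frozen=True)
class WordCloudSpec:
    terms: dict[str, int] = field(default_factory=dict)
    min_frequency: int = 0


def tokenize_comments(corpus: CommentCorpus | Iterable[str]) -> list[list[str]]:
    """Lowercase word tokenization, one token list per document.

    No stop-word removal and no stemming; empty documents drop out.
    """
    docs = corpus.documents if isinstance(corpus, CommentCorpus) else corpus
    out = []
    for doc in docs:
        toks = [m.group(0).lower().replace("’", "'") for m in _TOKEN_RE.finditer(doc)]
        if toks:
            out.append(toks)
    return out


def _ngram_counts(docs: Sequence[Sequence[str]], max_n: int) -> Counter:
    counts: Counter = Counter()
    for toks in docs:
        for n in range(1, max_n + 1):
            for i in range(len(toks) - n + 1):
                counts[" ".join(toks[i : i + n])] += 1
    return counts


def extract_collocations(
    docs: Sequence[Sequence[str]],
    max_n: int = 4,
    min_count: int = 2,
    merge_score_threshold: float = 0.0,
) -> list[CollocationTerm]:
    """Rank collocations of 1..max_n tokens by frequency.

    An n-gram is accepted as a collocation when it occurs at least
    ``min_count`` times and it can be split into two adjacent units —
    each a single word or an already-accepted shorter collocation —
    whose pointwise mutual information
    PMI(a, b) = log[p(ab) / (p(a) p(b))] exceeds
    ``merge_score_threshold``.  Working upward from pairs to ``max_n``
    lets longer phrases grow out of accepted shorter ones.  Reported
    frequencies are raw contiguous within-document n-gram counts.
    Ranking: frequency descending, then longer phrases first, then
    lexicographic.
    """
    if not 1 <= max_n <= 4:
        raise ValueError(f"max_n must be in 1..4, got {max_n}")
    docs = [list(t) for t in docs if t]
    counts = _ngram_counts(docs, max_n)
    totals = Counter()  # n -> number of n-gram positions
    for gram, c in counts.items():
        totals[len(gram.split())] += c

    def prob(gram: str) -> float:
        n = len(gram.split())
        return counts[gram] / totals[n]

    accepted: set[str] = set()
    for n in range(2, max_n + 1):
        for gram, c in counts.items():
            words = gram.split()
            if len(words) != n or c < min_count:
                continue
            for k in range(1, n):
                left, right = " ".join(words[:k]), " ".join(words[k:])
                if k > 1 and left not in accepted:
                    continue
                if n - k > 1 and right not in accepted:
                    continue
                pmi = math.log(prob(gram)) - math.log(prob(left)) - math.log(prob(right))
                if pmi > merge_score_threshold:
                    accepted.add(gram)
                    break

    terms: list[CollocationTerm] = []
    for gram, c in counts.items():
        n = len(gram.split())
        if c >= min_count and (n == 1 or gram in accepted):
            terms.append(CollocationTerm(expression=gram, frequency=c, n=n))
    terms.sort(key=lambda t: (-t.frequency, -t.n, t.expression))
    return terms


def build_word_cloud_data(
    terms: Sequence[CollocationTerm], min_frequency: int
) -> WordCloudSpec:
    """Strict frequency filter for word-cloud export.

    Only expressions with frequency strictly greater than
    ``min_frequency`` are kept ("higher than" semantics).
    """
    kept = {t.expression: t.frequency for t in terms if t.frequency > min_frequency}
    return WordCloudSpec(terms=kept, min_frequency=min_frequency)
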