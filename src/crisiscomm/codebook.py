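"""Codebook-driven thematic classification of social-media posts.

The classification layer of the pipeline: a hierarchical codebook
(themes → subcategories → keyword patterns) is applied to post text by
deterministic keyword matching.  A post receives a (theme, subcategory)
label iff at least one keyword of that subcategory matches; theme-level
membership is the union over the theme's subcategories, and a post counts
once per theme however many keywords fire.

Pattern dialect (as used in the built-in CERC Zika codebook):

* ``word`` — exact token match after normalisation.
* ``word*`` — token-prefix match ("includes the derivatives"):
  ``measure*`` matches measure, measures, measurement, ...
* ``*word*`` — token-substring match: ``*pain*`` matches pain, painful,
  backpain.
* ``a b`` — contiguous token phrase (whitespace-flexible, punctuation
  between tokens breaks the phrase).
* ``a…b`` (or ``a...b``) — ordered gap pattern: part ``a`` must occur
  somewhere before part ``b`` in the same document (``prevent…by``).
* ``x/y z`` — alternation, expanded at load time into ``x z`` and ``y z``
  (``has/have been``).
* ``http`` and ``www.`` — web keywords, matched as token prefixes so they
  fire on URL tokens.

Hashtags are camel-case split during normalisation, so ``#MozzieWipeout``
yields the contiguous tokens ``mozzie wipeout`` in addition to the fused
form — the Efficacy keyword ``mozzie wipeout`` depends on this.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "KeywordPattern",
    "SubcategoryDefinition",
    "ThemeDefinition",
    "Codebook",
    "Comment",
    "Post",
    "Token",
    "NormalizedDoc",
    "ThemeAssignment",
    "CorpusReport",
    "CodebookError",
    "normalize_text",
    "match_keyword",
    "classify_post",
    "classify_corpus",
    "load_codebook",
    "dump_codebook",
    "default_codebook",
]

AGENCIES = ("NEA", "MOH", "HPB")

#: single-token keywords matched as token prefixes (they fire on URL tokens)
WEB_PREFIX_KEYWORDS = frozenset({"http", "www."})

_GAP = "…"


class CodebookError(ValueError):
    """Raised when a codebook file or pattern is malformed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KeywordPattern:
    """One keyword as printed in the codebook, e.g. ``symptom*`` or ``we can``."""

    raw: str
    expand_derivatives: bool = field(init=False)
    token_count: int = field(init=False)

    def __post_init__(self) -> None:
        raw = self.raw.strip()
        if not raw:
            raise CodebookError("empty keyword pattern")
        canonical = raw.lower().replace("...", _GAP).replace("’", "'")
        object.__setattr__(self, "raw", canonical)
        star = canonical.endswith("*") and not canonical.startswith("*")
        if canonical.strip("*") == "":
            raise CodebookError(f"keyword pattern {raw!r} is empty after star removal")
        object.__setattr__(self, "expand_derivatives", star)
        object.__setattr__(self, "token_count", len(canonical.split()))
        if star and self.token_count != 1:
            raise CodebookError(f"derivative wildcard only allowed on single tokens: {raw!r}")


@dataclass(frozen=True)
class SubcategoryDefinition:
    name: str
    definition: str
    keywords: tuple[KeywordPattern, ...]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise CodebookError(f"subcategory {self.name!r} has no keywords")


@dataclass(frozen=True)
class ThemeDefinition:
    name: str
    subcategories: tuple[SubcategoryDefinition, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.subcategories]
        if len(set(names)) != len(names):
            raise CodebookError(f"duplicate subcategory names in theme {self.name!r}")


@dataclass(frozen=True)
class Codebook:
    themes: tuple[ThemeDefinition, ...]
    version: str = "table2-v1"

    def __post_init__(self) -> None:
        names = [t.name for t in self.themes]
        if len(set(names)) != len(names):
            raise CodebookError("duplicate theme names")

    @property
    def theme_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.themes)

    def subcategory_index(self) -> tuple[tuple[str, str], ...]:
        return tuple((t.name, s.name) for t in self.themes for s in t.subcategories)

    def __iter__(self) -> Iterator[ThemeDefinition]:
        return iter(self.themes)


@dataclass(frozen=True)
class Comment:
    author_kind: str  # "public" | "government"
    text: str


@dataclass
class Post:
    """One social-media post with its platform engagement metadata."""

    post_id: str
    agency: str
    timestamp: datetime
    text: str
    likes: int = 0
    shares: int = 0
    comment_count: int = 0
    comments: list[Comment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.likes, self.shares, self.comment_count) < 0:
            raise ValueError(f"negative engagement count on post {self.post_id!r}")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int  # half-open character offsets into the original text


@dataclass(frozen=True)
class NormalizedDoc:
    original: str
    tokens: tuple[Token, ...]

    @property
    def token_texts(self) -> tuple[str, ...]:
        return tuple(t.text for t in self.tokens)


@dataclass(frozen=True)
class ThemeAssignment:
    post_id: str
    labels: frozenset[tuple[str, str]]
    matches: Mapping[tuple[str, str], frozenset[tuple[int, int]]]

    @property
    def themes(self) -> frozenset[str]:
        return frozenset(theme for theme, _ in self.labels)

    def to_record(self) -> dict:
        return {
            "post_id": self.post_id,
            "labels": sorted([list(l) for l in self.labels]),
            "matches": {
                f"{theme}|{sub}": sorted([list(s) for s in spans])
                for (theme, sub), spans in sorted(self.matches.items())
            },
        }


@dataclass(frozen=True)
class CorpusReport:
    """Prevalence bookkeeping for a classified corpus."""

    n_posts: int
    theme_counts: Mapping[str, int]
    subcategory_counts: Mapping[tuple[str, str], int]

    @property
    def empty(self) -> bool:
        return self.n_posts == 0

    def theme_percentage(self, theme: str, decimals: int = 1) -> float:
        """Share of posts carrying the theme, as a percentage (one decimal)."""
        if self.empty:
            raise ValueError("empty corpus has no prevalence percentages")
        return round(100.0 * self.theme_counts.get(theme, 0) / self.n_posts, decimals)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_HASHTAG_RE = re.compile(r"#([A-Za-z][\w]*)")
_WORD_RE = re.compile(r"[\w][\w'’.\-]*[\w]|[\w]", re.UNICODE)
_CAMEL_RE = re.compile(r"[A-Z]+(?=[A-Z][a-z])|[A-Z]?[a-z0-9]+|[A-Z]+|\d+")


def normalize_text(text: str) -> NormalizedDoc:
    """Lowercase and tokenize, retaining character offsets.

    URLs survive as single tokens; hashtags contribute both the fused
    lowercase form and their camel-case parts as adjacent tokens.
    """
    tokens: list[Token] = []
    taken: list[tuple[int, int]] = []

    for m in _URL_RE.finditer(text):
        tokens.append(Token(m.group(0).lower().rstrip(".,;:!?)"), m.start(), m.end()))
        taken.append((m.start(), m.end()))

    def free(a: int, b: int) -> bool:
        return all(b <= s or a >= e for s, e in taken)

    for m in _HASHTAG_RE.finditer(text):
        if not free(m.start(), m.end()):
            continue
        word = m.group(1)
        tokens.append(Token(word.lower(), m.start(1), m.end(1)))
        parts = _CAMEL_RE.findall(word)
        if len(parts) > 1:
            tokens.extend(Token(p.lower(), m.start(1), m.end(1)) for p in parts)
        taken.append((m.start(), m.end()))

    for m in _WORD_RE.finditer(text):
        if free(m.start(), m.end()):
            tokens.append(Token(m.group(0).lower().replace("’", "'").rstrip("."), m.start(), m.end()))

    tokens.sort(key=lambda t: (t.start, t.end))
    return NormalizedDoc(original=text, tokens=tuple(tokens))


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def _match_token(pattern: str, token: str) -> bool:
    if pattern in WEB_PREFIX_KEYWORDS:
        return token.startswith(pattern) or token.startswith(pattern.rstrip("."))
    if pattern.startswith("*") and pattern.endswith("*"):
        return pattern.strip("*") in token
    if pattern.endswith("*"):
        return token.startswith(pattern[:-1])
    if pattern.startswith("*"):
        return token.endswith(pattern[1:])
    return token == pattern


def _match_phrase(words: Sequence[str], doc: NormalizedDoc, start_at: int = 0):
    """Yield (first_index, span) for each contiguous occurrence of the phrase."""
    toks = doc.tokens
    n = len(words)
    for i in range(start_at, len(toks) - n + 1):
        if all(_match_token(words[j], toks[i + j].text) for j in range(n)):
            yield i, (toks[i].start, toks[i + n - 1].end)


def match_keyword(pattern: KeywordPattern, doc: NormalizedDoc) -> tuple[bool, frozenset[tuple[int, int]]]:
    """Test one keyword against a normalised document.

    Returns whether it matched and the set of matched character spans
    (half-open offsets into the original text).  Gap patterns report the
    span from the first part's start to the last part's end.
    """
    spans: set[tuple[int, int]] = set()
    if _GAP in pattern.raw:
        parts = [p.split() for p in pattern.raw.split(_GAP) if p.strip()]
        pos = 0
        first_start = None
        for k, part in enumerate(parts):
            hit = next(iter(_match_phrase(part, doc, start_at=pos)), None)
            if hit is None:
                return False, frozenset()
            idx, (s, e) = hit
            if k == 0:
                first_start = s
            pos = idx + len(part)
        spans.add((first_start, e))
        return True, frozenset(spans)

    words = pattern.raw.split()
    for _, span in _match_phrase(words, doc):
        spans.add(span)
    return bool(spans), frozenset(spans)


def classify_post(post: Post | str, codebook: Codebook) -> ThemeAssignment:
    """Assign all matching (theme, subcategory) labels to one post.

    Multi-label and deterministic: every subcategory with at least one
    keyword match is labelled.
    """
    if isinstance(post, Post):
        post_id, text = post.post_id, post.text
    else:
        post_id, text = "", post
    doc = normalize_text(text)
    labels: set[tuple[str, str]] = set()
    matches: dict[tuple[str, str], frozenset[tuple[int, int]]] = {}
    for theme in codebook.themes:
        for sub in theme.subcategories:
            spans: set[tuple[int, int]] = set()
            for kw in sub.keywords:
                ok, kw_spans = match_keyword(kw, doc)
                if ok:
                    spans.update(kw_spans)
            if spans:
                key = (theme.name, sub.name)
                labels.add(key)
                matches[key] = frozenset(spans)
    return ThemeAssignment(post_id=post_id, labels=frozenset(labels), matches=matches)


def classify_corpus(
    posts: Sequence[Post], codebook: Codebook
) -> tuple[list[ThemeAssignment], CorpusReport]:
    """Classify a corpus and tally post-level prevalence per theme/subcategory.

    A post counts once per theme (and once per subcategory) regardless of
    how many keywords matched.  An empty corpus yields an explicit empty
    report rather than an error.
    """
    assignments = [classify_post(p, codebook) for p in posts]
    theme_counts = {t.name: 0 for t in codebook.themes}
    sub_counts = {key: 0 for key in codebook.subcategory_index()}
    for a in assignments:
        for theme in a.themes:
            if theme in theme_counts:
                theme_counts[theme] += 1
        for key in a.labels:
            if key in sub_counts:
                sub_counts[key] += 1
    report = CorpusReport(
        n_posts=len(posts), theme_counts=theme_counts, subcategory_counts=sub_counts
    )
    return assignments, report


# ---------------------------------------------------------------------------
# codebook I/O  (UTF-8 TSV: theme, subcategory, definition, keywords)
# ---------------------------------------------------------------------------


def _expand_alternation(raw: str) -> list[str]:
    # "has/have been" -> ["has been", "have been"]
    words = raw.split()
    for i, w in enumerate(words):
        if "/" in w and w not in WEB_PREFIX_KEYWORDS and not _URL_RE.match(w):
            return [
                " ".join(words[:i] + [alt] + words[i + 1 :])
                for alt in w.split("/")
                if alt
            ]
    return [raw]


def _parse_rows(rows: Iterable[Sequence[str]], source: str) -> Codebook:
    themes: dict[str, list[SubcategoryDefinition]] = {}
    seen_subs: set[tuple[str, str]] = set()
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 4:
            raise CodebookError(f"{source}: row {lineno}: expected 4 columns, got {len(row)}")
        theme, sub, definition, kw_cell = (c.strip() for c in row[:4])
        if (theme, sub) in seen_subs:
            raise CodebookError(f"{source}: row {lineno}: duplicate subcategory {sub!r} in theme {theme!r}")
        seen_subs.add((theme, sub))
        if not kw_cell:
            raise CodebookError(f"{source}: row {lineno}: empty keyword cell for {theme!r}/{sub!r}")
        patterns: list[KeywordPattern] = []
        for raw in kw_cell.split(","):
            raw = raw.strip()
            if not raw:
                raise CodebookError(f"{source}: row {lineno}: blank keyword in {theme!r}/{sub!r}")
            for alt in _expand_alternation(raw):
                patterns.append(KeywordPattern(alt))
        themes.setdefault(theme, []).append(
            SubcategoryDefinition(name=sub, definition=definition, keywords=tuple(patterns))
        )
    if not themes:
        raise CodebookError(f"{source}: no codebook rows found")
    return Codebook(
        themes=tuple(
            ThemeDefinition(name=name, subcategories=tuple(subs))
            for name, subs in themes.items()
        )
    )


def load_codebook(source) -> Codebook:
    """Load a codebook from a TSV path or file object.

    Columns: theme, subcategory, definition, keywords (comma-separated).
    Malformed rows (duplicates, empty keyword cells) fail with the
    offending row identified.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
        name = str(source)
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    header = next(reader, None)
    if header is None:
        raise CodebookError(f"{name}: empty codebook file")
    return _parse_rows(reader, name)


def dump_codebook(codebook: Codebook, path) -> None:
    """Write a codebook back to TSV; round-trips with :func:`load_codebook`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["theme", "subcategory", "definition", "keywords"])
        for theme in codebook.themes:
            for sub in theme.subcategories:
                writer.writerow(
                    [theme.name, sub.name, sub.definition, ", ".join(k.raw for k in sub.keywords)]
                )


def default_codebook() -> Codebook:
    """The built-in CERC Zika codebook: 7 themes, 16 subcategories."""
    ref = resources.files("crisiscomm.data").joinpath("default_codebook.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return load_codebook(fh)
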