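"""Synthetic outbreak-communication corpora with known ground truth.

The generator emulates the statistical structure of the 2016 Singapore
Zika Facebook corpus so every pipeline stage is testable without any
platform data:

* 72 posts split 11 / 54 / 7 across pre-outbreak / outbreak /
  post-outbreak (scalable), timestamps uniform within each phase,
  agencies sampled to mirror the 33 / 37 / 2 NEA / MOH / HPB split;
* per-phase theme prevalences defaulting to the published
  cross-tabulation proportions, realised by splicing a theme-unique
  keyword into keyword-free filler text so injected truth and classifier
  output coincide exactly;
* heavy-tailed engagement counts from per-phase negative-binomial
  models whose theoretical medians hit the published per-phase targets
  (likes 43 / 17.5 / 8, shares 26 / 1 / 0, comments 2 / 2 / 0), with
  zero inflation where the target median is zero;
* comment text seeded from the published concern-phrase inventories
  (public and government pools) for the collocation miner;
* a weekly confirmed-case series totalling 381 cases over the outbreak
  weeks.

One master seed drives independent child streams for structure,
engagement and comments; the same seed reproduces the corpus bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .codebook import (
    Codebook,
    Comment,
    Post,
    classify_post,
    default_codebook,
)
from .timeline import CaseSeries, EpiWeek, Phase, PhaseScheme, DEFAULT_SCHEME, to_epi_week

__all__ = [
    "SyntheticCorpusConfig",
    "SyntheticCorpus",
    "PaperFixtures",
    "generate_corpus",
    "generate_engagement",
    "generate_comments",
    "paper_fixtures",
    "solve_negative_binomial_mean",
    "THEME_ORDER",
    "DEFAULT_THEME_PREVALENCE",
    "DEFAULT_ENGAGEMENT_TARGETS",
]

THEME_ORDER = (
    "Risk Messages",
    "Warnings",
    "Preparations",
    "Uncertainty Reduction",
    "Efficacy",
    "Reassurance",
    "Dengue",
)

PHASES = (Phase.PRE_OUTBREAK, Phase.OUTBREAK, Phase.POST_OUTBREAK)

#: published theme-level present counts per phase (of 11 / 54 / 7 posts)
_TABLE3_THEME_COUNTS: dict[str, tuple[int, int, int]] = {
    "Risk Messages": (10, 45, 3),
    "Warnings": (10, 40, 2),
    "Preparations": (9, 53, 3),
    "Uncertainty Reduction": (10, 50, 3),
    "Efficacy": (9, 34, 7),
    "Reassurance": (7, 46, 2),
    "Dengue": (4, 16, 4),
}

_TABLE3_SUBCATEGORY_COUNTS: dict[tuple[str, str], tuple[int, int, int]] = {
    ("Risk Messages", "Disease mechanisms"): (8, 35, 2),
    ("Risk Messages", "Symptoms"): (7, 18, 2),
    ("Warnings", "Risk factors"): (10, 37, 2),
    ("Warnings", "Danger"): (7, 12, 0),
    ("Preparations", "Responders"): (7, 44, 2),
    ("Preparations", "Recommendations"): (9, 28, 3),
    ("Uncertainty Reduction", "Case report"): (8, 42, 2),
    ("Uncertainty Reduction", "Local locality"): (5, 42, 2),
    ("Uncertainty Reduction", "Information resources"): (8, 45, 3),
    ("Efficacy", "Personal prevention measures"): (8, 23, 3),
    ("Efficacy", "Common responsibility"): (9, 30, 6),
    # the printed count/percentage for this row are transposed in the
    # source table; 6 posts (8.3%) is the consistent reading
    ("Reassurance", "Thanking and regards"): (1, 4, 1),
    ("Reassurance", "Calming"): (5, 45, 2),
    ("Reassurance", "Government interventions"): (7, 34, 2),
    ("Dengue", "Dengue"): (4, 16, 4),
    ("Dengue", "Wolbachia"): (1, 1, 0),
}

_PHASE_N = (11, 54, 7)

DEFAULT_THEME_PREVALENCE: dict[tuple[str, str], float] = {
    (theme, ph.value): counts[i] / _PHASE_N[i]
    for theme, counts in _TABLE3_THEME_COUNTS.items()
    for i, ph in enumerate(PHASES)
}

#: per-phase target medians for (likes, shares, comments)
DEFAULT_ENGAGEMENT_TARGETS: dict[str, dict[str, float]] = {
    Phase.PRE_OUTBREAK.value: {"likes": 43.0, "shares": 26.0, "comments": 2.0},
    Phase.OUTBREAK.value: {"likes": 17.5, "shares": 1.0, "comments": 2.0},
    Phase.POST_OUTBREAK.value: {"likes": 8.0, "shares": 0.0, "comments": 0.0},
}

#: dispersion (NB size parameter) per engagement metric — heavy tails
DEFAULT_DISPERSION = {"likes": 1.5, "shares": 0.7, "comments": 0.9}

#: theme-unique keyword realisations: each phrase fires exactly one theme
#: of the default codebook (validated at generation time)
THEME_INJECTION_PHRASES: dict[str, tuple[str, ...]] = {
    "Risk Messages": ("aedes", "mosquito-borne", "microcephaly", "conjunctivitis", "febrile"),
    "Warnings": ("stagnant water", "breeding", "threat"),
    "Preparations": ("urge", "advise", "precaution", "take action"),
    "Uncertainty Reduction": ("cluster", "geylang", "health advisory", "bishan"),
    "Efficacy": ("repellent", "condom", "everyone", "work together", "mozzie wipeout"),
    "Reassurance": ("well done", "surveillance", "vector control", "fogging"),
    "Dengue": ("dengue", "wolbachia"),
}

#: keyword-free filler sentences (validated against the codebook in tests)
FILLER_SENTENCES = (
    "The evening settles quietly over the harbour tonight.",
    "Volunteers gathered near the community garden this weekend.",
    "A gentle breeze moved through the old banyan trees.",
    "Children played games along the waterfront after school.",
    "The library opened its doors early on Saturday.",
    "Fresh produce arrived at the market before sunrise.",
    "The ferry glided across the calm strait at dusk.",
    "Street lamps flickered softly under the monsoon clouds.",
    "Neighbours shared recipes during the afternoon gathering.",
    "Cyclists rolled past the botanical gardens at noon.",
)

_CARRIER_TEMPLATE = "Tonight the district bulletin mentions {phrase} once again."

#: published public-comment concern phrases (word-cloud inventory)
PUBLIC_COMMENT_PHRASES = (
    "vector control",
    "vector control measures",
    "to prevent",
    "own risk assessments",
    "next course of protection",
    "new cases",
    "confirmed cases",
    "affected areas",
    "the location",
    "no longer quarantine",
    "pregnant mommies group",
    "as an expecting mom",
    "mommies of earlier pregnancy",
    "earlier pregnancy trimester",
    "NEA please",
    "MOH NEA please",
    "more transparent in releasing the info",
)

#: published government-comment phrases
GOVERNMENT_COMMENT_PHRASES = (
    "NEA has",
    "NEA had",
    "control measures",
    "vector control",
    "mosquito breeding habitats",
    "construction sites",
    "search and destroy efforts",
    "indoor spaying",
    "outdoor fogging",
)

_COMMENT_FILLERS = (
    "hoping for an update about {phrase} soon",
    "everyone here keeps talking about {phrase} these days",
    "what about {phrase} in our neighbourhood",
    "thanks for the reply regarding {phrase}",
    "still waiting to hear more on {phrase} from the agency",
)

_COMMENT_PLAIN = (
    "thanks for keeping us posted",
    "appreciate the quick response",
    "stay safe everybody",
    "good to know, sharing with my family",
)


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """All knobs of the generator; identical seed → identical corpus."""

    n_posts_per_phase: tuple[int, int, int] = _PHASE_N
    theme_prevalence: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_THEME_PREVALENCE)
    )
    engagement_targets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ENGAGEMENT_TARGETS.items()}
    )
    dispersion: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DISPERSION))
    zero_inflation: float = 0.6  # P(structural zero) where the target median is 0
    agency_weights: tuple[float, float, float] = (33 / 72, 37 / 72, 2 / 72)
    government_comment_rate: float = 0.025  # share of comments by agencies (≈ 6 / 236)
    comment_phrase_rate: float = 0.8  # share of comments embedding a pool phrase
    public_phrase_pool: tuple[str, ...] = PUBLIC_COMMENT_PHRASES
    government_phrase_pool: tuple[str, ...] = GOVERNMENT_COMMENT_PHRASES
    outbreak_cases_total: int = 381
    epidemic_shape: tuple[float, ...] = (0.16, 0.34, 0.26, 0.16, 0.08)
    scheme: PhaseScheme = DEFAULT_SCHEME
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_posts_per_phase) <= 0:
            raise ValueError("posts per phase must be positive")
        for key, p in self.theme_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence out of [0,1] for {key}: {p}")
            if p > 0 and key[0] not in THEME_INJECTION_PHRASES:
                raise ValueError(f"no injection keywords for theme {key[0]!r}")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0,1)")


@dataclass
class SyntheticCorpus:
    posts: list[Post]
    truth: dict[str, frozenset[str]]  # post_id -> injected theme labels
    case_series: CaseSeries
    config: SyntheticCorpusConfig
    metadata: dict


# ---------------------------------------------------------------------------
# negative-binomial median calibration
# ---------------------------------------------------------------------------


def solve_negative_binomial_mean(
    target_median: float, dispersion: float, tol: float = 1e-10
) -> float:
    """Mean of an NB(size=dispersion) whose median equals ``target_median``.

    Solves P(X < t) + P(X = t)/2 = 1/2 by bisection (for half-integer
    targets this reduces to F(floor(t)) = 1/2, putting the sample median
    midway between the two bracketing integers).  Infeasible targets
    (median 0 without zero inflation heavy enough) raise ValueError.
    """
    if target_median <= 0:
        raise ValueError("use zero inflation for a zero target median")
    k = int(np.floor(target_median))
    half = target_median != k

    def centred_cdf(mu: float) -> float:
        p = dispersion / (dispersion + mu)
        if half:
            return float(sps.nbinom.cdf(k, dispersion, p))
        below = float(sps.nbinom.cdf(k - 1, dispersion, p)) if k > 0 else 0.0
        return below + float(sps.nbinom.pmf(k, dispersion, p)) / 2.0

    lo, hi = 1e-9, 1e7
    if centred_cdf(lo) < 0.5 or centred_cdf(hi) > 0.5:
        raise ValueError(f"median {target_median} unreachable at dispersion {dispersion}")
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if centred_cdf(mid) > 0.5:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, lo):
            break
    return (lo + hi) / 2.0


def _draw_engagement(
    rng: np.random.Generator,
    n: int,
    target_median: float,
    dispersion: float,
    zero_inflation: float,
) -> np.ndarray:
    if target_median <= 0:
        # structural zeros guarantee a zero median; the NB tail keeps
        # occasional non-zero counts, as in the real data
        mu = 1.5
        p = dispersion / (dispersion + mu)
        base = rng.negative_binomial(dispersion, p, size=n)
        zeros = rng.random(n) < max(zero_inflation, 0.55)
        return np.where(zeros, 0, base)
    mu = solve_negative_binomial_mean(target_median, dispersion)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p, size=n)


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def _validate_injection_phrases(codebook: Codebook) -> None:
    for theme, phrases in THEME_INJECTION_PHRASES.items():
        for phrase in phrases:
            sentence = _CARRIER_TEMPLATE.format(phrase=phrase)
            hit = classify_post(sentence, codebook).themes
            if hit != {theme}:
                raise RuntimeError(
                    f"injection phrase {phrase!r} classifies as {sorted(hit)}, "
                    f"expected exactly {{{theme!r}}}"
                )


def _default_case_series(config: SyntheticCorpusConfig) -> CaseSeries:
    scheme = config.scheme
    first = to_epi_week(scheme.pre_start)
    last = to_epi_week(scheme.post_end)
    weeks: list[EpiWeek] = [first]
    while weeks[-1] < last:
        weeks.append(weeks[-1].next())
    outbreak_weeks = sorted(
        {
            to_epi_week(scheme.outbreak_start + timedelta(days=i))
            for i in range((scheme.outbreak_end - scheme.outbreak_start).days + 1)
        }
    )
    shape = np.asarray(config.epidemic_shape, dtype=float)
    if len(outbreak_weeks) != len(shape):
        shape = np.interp(
            np.linspace(0, 1, len(outbreak_weeks)), np.linspace(0, 1, len(shape)), shape
        )
    shape = shape / shape.sum()
    alloc = np.floor(shape * config.outbreak_cases_total).astype(int)
    alloc[int(np.argmax(shape))] += config.outbreak_cases_total - int(alloc.sum())
    counts = {w: 0 for w in weeks}
    counts.update(dict(zip(outbreak_weeks, (int(a) for a in alloc))))
    return CaseSeries(counts=counts)


def generate_corpus(
    config: SyntheticCorpusConfig | None = None, codebook: Codebook | None = None
) -> SyntheticCorpus:
    """Generate a full synthetic corpus: posts, truth labels, case series.

    Each theme is present in each post independently with its configured
    per-phase probability, realised by splicing a theme-unique keyword
    phrase into keyword-free filler text — so the classifier recovers the
    injected truth exactly (sensitivity 1, no accidental labels).
    Engagement counts and comments are attached by
    :func:`generate_engagement` and :func:`generate_comments`.
    """
    config = config or SyntheticCorpusConfig()
    codebook = codebook or default_codebook()
    _validate_injection_phrases(codebook)

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    rng_posts = np.random.default_rng(seeds[0])

    posts: list[Post] = []
    truth: dict[str, frozenset[str]] = {}
    pid = 0
    for phase, n_posts in zip(PHASES, config.n_posts_per_phase):
        start, end = config.scheme.phase_range(phase)
        n_days = (end - start).days + 1
        for _ in range(n_posts):
            pid += 1
            post_id = f"p{pid:05d}"
            day = start + timedelta(days=int(rng_posts.integers(0, n_days)))
            agency = ("NEA", "MOH", "HPB")[
                int(rng_posts.choice(3, p=config.agency_weights))
            ]
            themes = [
                t
                for t in THEME_ORDER
                if rng_posts.random() < config.theme_prevalence.get((t, phase.value), 0.0)
            ]
            filler = FILLER_SENTENCES[int(rng_posts.integers(0, len(FILLER_SENTENCES)))]
            sentences = [filler]
            for t in themes:
                pool = THEME_INJECTION_PHRASES[t]
                phrase = pool[int(rng_posts.integers(0, len(pool)))]
                sentences.append(_CARRIER_TEMPLATE.format(phrase=phrase))
            posts.append(
                Post(
                    post_id=post_id,
                    agency=agency,
                    timestamp=datetime.combine(day, time(10, 0)),
                    text=" ".join(sentences),
                )
            )
            truth[post_id] = frozenset(themes)

    generate_engagement(config, posts, rng=np.random.default_rng(seeds[1]))
    generate_comments(config, posts, rng=np.random.default_rng(seeds[2]))

    metadata = {
        "seed": config.seed,
        "child_streams": ["posts", "engagement", "comments"],
        "n_posts": len(posts),
        "n_posts_per_phase": list(config.n_posts_per_phase),
    }
    return SyntheticCorpus(
        posts=posts,
        truth=truth,
        case_series=_default_case_series(config),
        config=config,
        metadata=metadata,
    )


def generate_engagement(
    config: SyntheticCorpusConfig,
    posts: Sequence[Post],
    rng: np.random.Generator | None = None,
) -> None:
    """Attach likes/shares/comment counts drawn per phase in place.

    Negative-binomial draws whose theoretical median equals the
    configured per-phase target; targets of zero use zero inflation.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    by_phase: dict[str, list[int]] = {}
    from .timeline import assign_phase  # local import to avoid cycle at module load

    for i, post in enumerate(posts):
        by_phase.setdefault(assign_phase(post.timestamp, config.scheme).value, []).append(i)
    for phase_value, idx in by_phase.items():
        targets = config.engagement_targets[phase_value]
        for metric in ("likes", "shares", "comments"):
            draws = _draw_engagement(
                rng,
                len(idx),
                float(targets[metric]),
                float(config.dispersion[metric]),
                config.zero_inflation,
            )
            for j, i in enumerate(idx):
                value = int(draws[j])
                if metric == "likes":
                    posts[i].likes = value
                elif metric == "shares":
                    posts[i].shares = value
                else:
                    posts[i].comment_count = value


def generate_comments(
    config: SyntheticCorpusConfig,
    posts: Sequence[Post],
    rng: np.random.Generator | None = None,
) -> None:
    """Attach comment texts in place, sampling the concern-phrase pools.

    Public comments draw from the public pool, government comments from
    the agency pool; a configurable share of comments embeds a phrase,
    the rest are plain fillers.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    for post in posts:
        comments: list[Comment] = []
        for _ in range(post.comment_count):
            gov = rng.random() < config.government_comment_rate
            pool = config.government_phrase_pool if gov else config.public_phrase_pool
            if rng.random() < config.comment_phrase_rate and pool:
                phrase = pool[int(rng.integers(0, len(pool)))]
                template = _COMMENT_FILLERS[int(rng.integers(0, len(_COMMENT_FILLERS)))]
                text = template.format(phrase=phrase)
            else:
                text = _COMMENT_PLAIN[int(rng.integers(0, len(_COMMENT_PLAIN)))]
            comments.append(Comment(author_kind="government" if gov else "public", text=text))
        post.comments = comments


# ---------------------------------------------------------------------------
# published-table fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PaperFixtures:
    """The published contingency tables and medians as data.

    ``theme_counts`` / ``subcategory_counts`` hold present counts per
    phase (pre, outbreak, post) out of ``phase_n`` posts;
    ``median_engagement`` holds the published per-phase medians for each
    metric; ``codebook`` is the built-in default.
    """

    phase_n: tuple[int, int, int]
    theme_counts: Mapping[str, tuple[int, int, int]]
    subcategory_counts: Mapping[tuple[str, str], tuple[int, int, int]]
    median_engagement: Mapping[str, Mapping[str, float]]
    codebook: Codebook

    @property
    def n_total(self) -> int:
        return sum(self.phase_n)

    def contingency(self, theme: str, subcategory: str | None = None) -> np.ndarray:
        """Present/absent × phase counts for one theme or subcategory."""
        present = (
            self.theme_counts[theme]
            if subcategory is None
            else self.subcategory_counts[(theme, subcategory)]
        )
        absent = tuple(n - k for n, k in zip(self.phase_n, present))
        return np.array([present, absent], dtype=np.int64)


def paper_fixtures() -> PaperFixtures:
    """Published tables as a regression-test substrate."""
    all_medians = {
        "likes": {"all": 17.5, "pre_outbreak": 43.0, "outbreak": 17.5, "post_outbreak": 8.0},
        "shares": {"all": 0.0, "pre_outbreak": 26.0, "outbreak": 1.0, "post_outbreak": 0.0},
        "comments": {"all": 2.0, "pre_outbreak": 2.0, "outbreak": 2.0, "post_outbreak": 0.0},
    }
    return PaperFixtures(
        phase_n=_PHASE_N,
        theme_counts=dict(_TABLE3_THEME_COUNTS),
        subcategory_counts=dict(_TABLE3_SUBCATEGORY_COUNTS),
        median_engagement=all_medians,
        codebook=default_codebook(),
    )
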