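# Methods

This note records the package's statistical conventions, the design
choices that were genuinely open, and what the synthetic-data tests do
and do not establish about real data.

## Codebook classification

Classification is dictionary-based and deterministic: a post is
labelled with a (theme, subcategory) pair iff at least one of the
subcategory's keyword patterns matches its normalised text, and with a
theme iff any of its subcategories is labelled. Prevalence is
post-level — a post counts once per theme however many keywords fire.
There is no stemming, lemmatisation or machine learning; the only
morphological device is the pattern dialect itself:

| pattern form | semantics | example |
|---|---|---|
| `word` | exact token | `dengue` |
| `word*` | token prefix ("derivatives") | `measure*` → measures, measurement |
| `*word*` | token substring | `*pain*` → painful, backpain |
| `a b` | contiguous token phrase | `vector control` |
| `a…b` | ordered gap within the document | `prevent…by` |
| `x/y z` | alternation, expanded at load | `has/have been` |
| `http`, `www.` | token prefix (URL tokens) | `www.moh.gov.sg` |

Normalisation lowercases, tokenises with offsets into the original
text, keeps URLs as single tokens, and splits hashtag camel case while
retaining the fused form (`#MozzieWipeout` → `mozziewipeout`,
`mozzie`, `wipeout` as adjacent tokens) — the `mozzie wipeout` phrase
keyword depends on this. Matching is on normalised text throughout,
including the web keywords. Punctuation breaks phrases because tokens
are matched contiguously in the token stream.

The token-prefix reading of `*` is the simplest rule consistent with
the codebook's own gloss ("measure\* includes measure, measures,
measured …"). The substring reading of the two-sided forms `*pain*` /
`*ache*` is required for them to mean anything beyond the prefix rule.
The gap reading of `prevent…by` (both parts, in order, anywhere in the
post) is the weakest rule that the printed example sentence satisfies;
a stricter windowed rule would be arbitrary without more examples.

The built-in codebook (7 themes, 16 subcategories, shipped as an
editable UTF-8 TSV with comma-separated keyword cells) includes the
locality names as data, not code.

## Timeline

Epi-weeks follow the MMWR convention: weeks run Sunday–Saturday and
week 1 of a year is the week containing at least four January days —
equivalently, the week whose Wednesday falls in January. The converter
is exercised against all boundary dates of the study window
(1 Jan 2016 = week 52 of 2015, 20/21 Aug = weeks 33/34, 24/25 Sep =
weeks 38/39, 31 Dec = week 52). ISO week numbering is deliberately not
offered; the study's printed date↔week pairs are MMWR.

Phases are assigned by calendar date (inclusive bounds), not by
epi-week: the phase definition is given in dates, and epi-weeks are
reporting coordinates. Timestamps are reduced to their local calendar
date; time of day is ignored. The epidemic narrative gives 19 September
as the closing of the first cluster while the operational phase bound
is 24 September; the package uses the operational bound.

## Contingency and rank statistics

- **Chi-square.** Pearson's statistic without continuity correction,
  p from the upper χ² tail at df = (r−1)(c−1). This convention is
  pinned by the regression suite: all 22 published theme and
  subcategory statistics reproduce to ±0.01 from their printed
  present/absent × phase counts. Expected cells below 5 — common with
  a 7-post phase — raise a warning flag, never a switch to Fisher's
  exact test, because the published analysis reports Pearson χ²
  throughout.
- **Kruskal–Wallis.** H on mid-ranks with tie correction (scipy),
  p from the χ² approximation with k−1 df; identical groups short-cut
  to H = 0, p = 1.
- **Mann–Whitney.** U is the first ("present") sample's statistic;
  z is the tie-corrected normal approximation without continuity
  correction, signed positive when the present group ranks higher.
  The two-sided p uses the exact permutation distribution when both
  samples have ≤ 8 observations and no ties, and the normal
  approximation otherwise: at n = 3–6 per group the plain approximation
  can differ from the exact p by > 0.15, which would make small-stratum
  contrasts meaningless. z and p therefore come from different
  approximations in small samples; z is reported as an effect
  direction/size summary, p as the test.
- **Medians** use the standard midpoint rule (even counts can yield
  half-values such as 17.5). Empty strata are reported as missing, not
  zero.
- **Multiplicity.** No correction is applied, mirroring the source
  analysis; every report records the number of tests run so readers can
  judge the false-positive budget themselves. The significance-star
  legend is \* p<0.05, \*\* p<0.01, \*\*\* p<0.001, and the rank-test
  report filters to p ≤ α (default 0.05) with a show-all flag.

## Collocation mining

Comments are mined separately by author kind (public vs government).
Tokenisation keeps stop-words — the expressions of interest ("to
prevent", "NEA has") are fixed phrases whose function words carry the
signal. An n-gram (n ≤ 4) is accepted as a collocation when its raw
within-document count reaches `min_count` (default 2) and some split
into two adjacent units — single words or already-accepted shorter
collocations — has pointwise mutual information above
`merge_score_threshold` (default 0). Reported frequencies are always
raw contiguous n-gram counts, which guarantees that an n-gram is never
more frequent than its constituent (n−1)-grams. Word-cloud export
filters strictly (frequency > threshold, defaults 5 for public and 3
for government comments) and emits term/frequency tables only; drawing
the cloud is out of scope. The original analysis used an external
collocation routine whose statistic is unstated; PMI with a count floor
was chosen as the standard, reproducible equivalent for frequent fixed
phrases, with the threshold left as a knob.

## Synthetic-data generator

The generator's defaults are the study conditions: 11/54/7 posts per
phase over the 2016 window; NEA/MOH/HPB sampled at 33:37:2; per-phase
theme prevalences equal to the published cross-tabulation proportions;
engagement medians 43/26/2 (pre), 17.5/1/2 (outbreak), 8/0/0 (post)
for likes/shares/comments; a 381-case outbreak curve over the five
outbreak epi-weeks; comment text seeded from the published public and
government concern-phrase inventories.

Themes are injected by splicing a theme-unique keyword realisation
(e.g. `aedes`, `stagnant water`, `well done`) into filler sentences
that are verified keyword-free against the codebook, so the injected
truth and the classifier output coincide exactly — sensitivity is 1 by
construction and false labels cannot arise. This is what makes the
recovery experiments sharp: classified prevalence is exactly the
realised Bernoulli draw, so its coverage of the 95% binomial acceptance
region is a property of the generator, not of classifier noise. The
filler/injection vocabulary is validated at generation time; an edited
codebook that collides with it fails loudly.

Engagement counts are negative binomial (NB2) with per-metric
dispersion (likes 1.5, shares 0.7, comments 0.9 — heavy-tailed, chosen
once as plausible for social-media counts). The mean is solved by
bisection so that the distribution's continuity-corrected median
equation P(X < t) + P(X = t)/2 = ½ holds at the target t; for
half-integer targets this puts the sample median midway between the
bracketing integers. Zero-median targets use a structural-zero mixture
with mass ≥ 0.55. One master seed spawns independent child streams for
post structure, engagement and comments; the same seed reproduces the
corpus bit for bit, and stream identities are recorded in the output
metadata.

What the generator does **not** emulate: real post length and style
(filler text is deliberately bland), correlation between themes within
a post (themes are independent Bernoulli), correlation between
engagement metrics, burstiness of posting within a phase (timestamps
are uniform), and comment-thread structure. Passing recovery tests
therefore show that the pipeline's bookkeeping and statistics are
correct under the designed distributions — they do not show that the
codebook would code real Facebook posts the way human coders did.

## Problem sizes in the test and acceptance runs

The regression suite runs the chi-square battery on the bundled counts
(instant). Rank-test accuracy is checked over 200 random two-group
cases with group sizes 3–7 against full permutation enumeration.
Recovery experiments use 20 seeded replicates of 500 posts per phase
(30,000 classified posts) for prevalence coverage, and 10,000 draws
per phase × metric for median calibration — sizes at which binomial and
median sampling error are small relative to the tolerances, while the
whole suite stays in the low minutes.

## Known limitations

- The codebook reproduces the printed keyword lists; any typo in the
  source propagates (e.g. "Harvey Cresent", "Joo Avenue" are kept as
  printed). One printed count/percentage pair ("Thanking and regards":
  "8.3 (6%)") is transposed in the source; the bundled fixture stores
  6 posts with a 1/4/1 phase split, under which the printed χ² of 0.39
  reproduces exactly.
- Whether the original keyword matching ran on raw or normalised text
  for URL keywords is unstated; this package matches on normalised
  tokens.
- Raw-corpus quantities (per-theme engagement medians, published Z
  values, total like/share/comment counts, the weekly post series)
  cannot be reproduced without the unpublished post corpus; they are
  covered by the distributional property checks above instead.
- The published Ns for comments (230 public, 6 government) cannot be
  audited; the generator's government-comment rate (2.5%) mirrors
  their ratio only.
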