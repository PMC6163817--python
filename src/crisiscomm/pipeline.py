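"""End-to-end orchestration: file I/O, validation, analysis run, manifest.

The pipeline reads a posts file (CSV or JSON-lines) and an optional
comments companion file, classifies posts against a codebook, assigns
crisis phases, runs the contingency/chi-square and median/rank-test
batteries, mines comment collocations, and writes a reproducible report
set plus a manifest with input/output checksums.  Identical inputs and
config produce identical outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .codebook import (
    AGENCIES,
    Codebook,
    Comment,
    Post,
    classify_corpus,
    default_codebook,
    load_codebook,
)
from .collocations import (
    CommentCorpus,
    build_word_cloud_data,
    extract_collocations,
    tokenize_comments,
)
from .stats import (
    EngagementRecord,
    engagement_test_report,
    median_engagement_report,
    theme_phase_report,
)
from .timeline import (
    CaseSeries,
    DEFAULT_SCHEME,
    OutOfWindowError,
    PhaseScheme,
    assign_phase,
    weekly_aggregate,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "InputError",
    "read_posts",
    "write_posts",
    "read_comments",
    "write_comments",
    "validate_inputs",
    "run_analysis",
]

logger = logging.getLogger("crisiscomm")

POST_FIELDS = ("post_id", "agency", "timestamp", "text", "likes", "shares", "comment_count")
COMMENT_FIELDS = ("post_id", "author_kind", "text")


class InputError(ValueError):
    """Schema violation in an input file."""


# ---------------------------------------------------------------------------
# posts / comments file dialects (CSV or JSON-lines, chosen by extension)
# ---------------------------------------------------------------------------


def _records_from_file(path: Path) -> list[dict]:
    if path.suffix in (".jsonl", ".ndjson", ".json"):
        records = []
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise InputError(f"{path}: line {i}: invalid JSON ({exc})") from exc
        return records
    with open(path, encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh))


def _check_fields(record: dict, required: Sequence[str], path, rowno: int) -> None:
    missing = [f for f in required if f not in record or record[f] is None]
    if missing:
        raise InputError(f"{path}: row {rowno}: missing column(s) {missing}")


def _parse_post(record: dict, path, rowno: int) -> Post:
    _check_fields(record, POST_FIELDS, path, rowno)
    try:
        ts = datetime.fromisoformat(str(record["timestamp"]))
    except ValueError as exc:
        raise InputError(
            f"{path}: row {rowno}: bad timestamp {record['timestamp']!r} (expected ISO-8601)"
        ) from exc
    agency = str(record["agency"])
    if agency not in AGENCIES:
        raise InputError(f"{path}: row {rowno}: unknown agency {agency!r} (expected {AGENCIES})")
    try:
        likes, shares, n_comments = (
            int(record["likes"]),
            int(record["shares"]),
            int(record["comment_count"]),
        )
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path}: row {rowno}: non-integer engagement count") from exc
    try:
        return Post(
            post_id=str(record["post_id"]),
            agency=agency,
            timestamp=ts,
            text=str(record["text"]),
            likes=likes,
            shares=shares,
            comment_count=n_comments,
        )
    except ValueError as exc:
        raise InputError(f"{path}: row {rowno}: {exc}") from exc


def read_posts(path) -> list[Post]:
    path = Path(path)
    posts = [ _parse_post(r, path, i) for i, r in enumerate(_records_from_file(path), start=2) ]
    ids = [p.post_id for p in posts]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"{path}: duplicate post_id(s) {dupes}")
    return posts


def write_posts(posts: Sequence[Post], path) -> None:
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        with open(path, "w", encoding="utf-8") as fh:
            for p in posts:
                fh.write(
                    json.dumps(
                        {
                            "post_id": p.post_id,
                            "agency": p.agency,
                            "timestamp": p.timestamp.isoformat(),
                            "text": p.text,
                            "likes": p.likes,
                            "shares": p.shares,
                            "comment_count": p.comment_count,
                        }
                    )
                    + "\n"
                )
        return
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(POST_FIELDS)
        for p in posts:
            writer.writerow(
                [p.post_id, p.agency, p.timestamp.isoformat(), p.text, p.likes, p.shares, p.comment_count]
            )


def read_comments(path, posts: Sequence[Post] | None = None) -> dict[str, list[Comment]]:
    """Load the comments companion file; optionally attach to posts in place."""
    path = Path(path)
    by_post: dict[str, list[Comment]] = {}
    for i, record in enumerate(_records_from_file(path), start=2):
        _check_fields(record, COMMENT_FIELDS, path, i)
        kind = str(record["author_kind"])
        if kind not in ("public", "government"):
            raise InputError(f"{path}: row {i}: author_kind must be public/government, got {kind!r}")
        by_post.setdefault(str(record["post_id"]), []).append(
            Comment(author_kind=kind, text=str(record["text"]))
        )
    if posts is not None:
        for p in posts:
            p.comments = by_post.get(p.post_id, [])
    return by_post


def write_comments(posts: Sequence[Post], path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COMMENT_FIELDS)
        for p in posts:
            for c in p.comments:
                writer.writerow([p.post_id, c.author_kind, c.text])


def validate_inputs(posts_path, comments_path=None) -> list[str]:
    """Schema check without running the analysis; returns per-row diagnostics."""
    violations: list[str] = []
    try:
        posts = read_posts(posts_path)
    except InputError as exc:
        return [str(exc)]
    if comments_path is not None:
        try:
            by_post = read_comments(comments_path)
        except InputError as exc:
            violations.append(str(exc))
        else:
            known = {p.post_id for p in posts}
            for pid in by_post:
                if pid not in known:
                    violations.append(f"{comments_path}: comment references unknown post_id {pid!r}")
    return violations


# ---------------------------------------------------------------------------
# run configuration and manifest
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    posts_path: str
    out_dir: str
    comments_path: str | None = None
    codebook_path: str | None = None
    case_series_path: str | None = None
    scheme: PhaseScheme = field(default_factory=lambda: DEFAULT_SCHEME)
    alpha: float = 0.05
    show_all: bool = False
    colloc_max_n: int = 4
    colloc_min_count: int = 2
    colloc_merge_threshold: float = 0.0
    wordcloud_public_min_freq: int = 5
    wordcloud_government_min_freq: int = 3
    integer_percentages: bool = False
    log_level: str = "INFO"


@dataclass
class RunManifest:
    config: dict
    input_checksums: dict[str, str]
    artifact_version: str
    stage_counts: dict[str, int]
    warnings: list[str]
    excluded_posts: list[dict]
    outputs: dict[str, str]  # filename -> sha256

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json_mirror(df: pd.DataFrame, path: Path) -> None:
    records = json.loads(df.to_json(orient="records"))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_terms_tsv(terms, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["expression", "n", "frequency"])
        for t in terms:
            writer.writerow([t.expression, t.n, t.frequency])


def run_analysis(config: RunConfig) -> RunManifest:
    """Execute classify → phase-assign → statistics → collocations.

    Emits the report set (cross-tabulation, rank tests, medians, weekly
    aggregates, collocation and word-cloud tables) under
    ``config.out_dir`` and returns the manifest, which enumerates any
    posts excluded for out-of-window dates together with all output
    checksums.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    excluded: list[dict] = []
    input_checksums: dict[str, str] = {}

    # --- load -------------------------------------------------------------
    posts = read_posts(config.posts_path)
    input_checksums["posts"] = _sha256(Path(config.posts_path))
    if config.comments_path:
        read_comments(config.comments_path, posts)
        input_checksums["comments"] = _sha256(Path(config.comments_path))
    codebook: Codebook
    if config.codebook_path:
        codebook = load_codebook(config.codebook_path)
        input_checksums["codebook"] = _sha256(Path(config.codebook_path))
    else:
        codebook = default_codebook()
    case_series = None
    if config.case_series_path:
        case_series = CaseSeries.read_csv(config.case_series_path)
        input_checksums["case_series"] = _sha256(Path(config.case_series_path))
    logger.info("[load] %d posts", len(posts))

    # --- phase assignment (no silent drops) -------------------------------
    kept: list[Post] = []
    phases = []
    for p in posts:
        if not p.text.strip():
            excluded.append({"post_id": p.post_id, "reason": "empty text"})
            continue
        try:
            phases.append(assign_phase(p.timestamp, config.scheme))
        except OutOfWindowError as exc:
            excluded.append({"post_id": p.post_id, "reason": str(exc)})
            continue
        kept.append(p)
    if excluded:
        warnings.append(f"{len(excluded)} post(s) excluded; see excluded_posts")
    if not kept:
        raise InputError("no posts remain after filtering")
    logger.info("[phase] %d posts in window, %d excluded", len(kept), len(excluded))

    # --- classification ---------------------------------------------------
    assignments, prevalence = classify_corpus(kept, codebook)
    logger.info("[classify] %d themes tracked", len(prevalence.theme_counts))

    theme_matrix = pd.DataFrame(
        [
            {"post_id": a.post_id, **{t: int(t in a.themes) for t in codebook.theme_names}}
            for a in assignments
        ]
    )

    # --- statistics -------------------------------------------------------
    report3 = theme_phase_report(
        assignments, phases, codebook, integer_percentages=config.integer_percentages
    )
    if report3["low_expected"].any():
        warnings.append(
            "chi-square expected cell < 5 in "
            + ", ".join(
                (r.theme if not r.subcategory else f"{r.theme}/{r.subcategory}")
                for r in report3[report3.low_expected].itertuples()
            )
        )
    records = [
        EngagementRecord(
            post_id=p.post_id,
            phase=ph,
            themes=a.themes,
            likes=p.likes,
            shares=p.shares,
            comments=p.comment_count,
        )
        for p, ph, a in zip(kept, phases, assignments)
    ]
    medians = median_engagement_report(records, codebook)
    tests = engagement_test_report(records, codebook, alpha=config.alpha, show_all=config.show_all)
    weekly = weekly_aggregate(kept, case_series=case_series, span=config.scheme.window)
    logger.info("[stats] %d rank tests run", tests.attrs.get("n_tests_run", 0))

    # --- collocations -----------------------------------------------------
    colloc_outputs: dict[str, tuple] = {}
    for kind, min_freq in (
        ("public", config.wordcloud_public_min_freq),
        ("government", config.wordcloud_government_min_freq),
    ):
        texts = tuple(c.text for p in kept for c in p.comments if c.author_kind == kind)
        terms = extract_collocations(
            tokenize_comments(CommentCorpus(author_kind=kind, documents=texts)),
            max_n=config.colloc_max_n,
            min_count=config.colloc_min_count,
            merge_score_threshold=config.colloc_merge_threshold,
        )
        cloud = build_word_cloud_data(terms, min_frequency=min_freq)
        colloc_outputs[kind] = (terms, cloud)
    logger.info(
        "[collocations] public=%d government=%d terms",
        len(colloc_outputs["public"][0]),
        len(colloc_outputs["government"][0]),
    )

    # --- write outputs ----------------------------------------------------
    outputs: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        outputs[name] = _sha256(path)

    emit(
        "assignments.jsonl",
        lambda p: p.write_text(
            "".join(json.dumps(a.to_record(), sort_keys=True) + "\n" for a in assignments),
            encoding="utf-8",
        ),
    )
    emit("theme_matrix.csv", lambda p: theme_matrix.to_csv(p, index=False))
    emit("theme_phase_report.csv", lambda p: report3.to_csv(p, index=False))
    emit("theme_phase_report.json", lambda p: _write_json_mirror(report3, p))
    emit("median_engagement.csv", lambda p: medians.to_csv(p, index=False))
    emit("engagement_tests.csv", lambda p: tests.to_csv(p, index=False))
    emit("engagement_tests.json", lambda p: _write_json_mirror(tests, p))
    emit("weekly_aggregate.csv", lambda p: weekly.to_csv(p, index=False))
    for kind, (terms, cloud) in colloc_outputs.items():
        emit(f"collocations_{kind}.tsv", lambda p, terms=terms: _write_terms_tsv(terms, p))
        emit(
            f"wordcloud_{kind}.tsv",
            lambda p, cloud=cloud: p.write_text(
                "expression\tfrequency\n"
                + "".join(f"{e}\t{f}\n" for e, f in sorted(cloud.terms.items(), key=lambda kv: (-kv[1], kv[0]))),
                encoding="utf-8",
            ),
        )

    manifest = RunManifest(
        config={k: str(v) for k, v in asdict(config).items()},
        input_checksums=input_checksums,
        artifact_version=__version__,
        stage_counts={
            "posts_read": len(posts),
            "posts_analysed": len(kept),
            "posts_excluded": len(excluded),
            "rank_tests_run": int(tests.attrs.get("n_tests_run", 0)),
        },
        warnings=warnings,
        excluded_posts=excluded,
        outputs=outputs,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
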