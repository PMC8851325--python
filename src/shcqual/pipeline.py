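"""End-to-end orchestration: locate -> gather -> score, for a batch of
(university, topic) pairs, with per-phase wall-time accounting.

Per-university failures (SHC not found, every fetch dead, a stalled site)
produce a status row and never abort the batch.  Phases are classified as
network (locate, search, fetch, navigate) or compute (extract, metrics) so
the network/compute runtime split is recomputable from any run log.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Callable, Optional, Sequence

from . import gatherer, locator, metrics
from .errors import InvalidInputError, ShcqualError
from .types import (
    ConsolidatedContent,
    NavigationResult,
    QualityReport,
    TopicSpec,
    UniversityRecord,
)
from .urls import host_of, netloc_of

log = logging.getLogger(__name__)

_NETWORK_PHASES = frozenset({"locate", "search", "fetch", "navigate"})

REPORT_COLUMNS = [
    "university_name", "topic", "status", "fre", "fkgl", "prevalence",
    "coverage_pct", "objectivity", "polarity", "nav_clicks", "nav_trace",
    "n_pages", "timeliness", "similarity",
]


@dataclass
class BackendBundle:
    """Everything the pipeline needs to talk to the (live or fixture) web."""

    search_backend: object  # locator queries: .search(text) -> [SearchResult]
    fetcher: object
    redirect_resolver: Callable[[str], str]
    # host -> site-restricted search backend (None -> BFS crawl fallback)
    site_search_for_host: Callable[[str], Optional[object]] = lambda host: None


@dataclass
class RunConfig:
    universities_csv: str | Path
    topics: Sequence[TopicSpec]
    backend: BackendBundle
    reference_docs: dict[str, str] = field(default_factory=dict)  # topic -> path
    timeout_seconds: float = 30.0
    retries: int = 1
    level_cap: int = 10
    context_window: int = 5
    output_csv: Optional[str | Path] = None
    log_path: Optional[str | Path] = None
    # when set, gathered text is dumped here as UTF-8 plain text,
    # one sentence per line, for audit
    audit_dir: Optional[str | Path] = None

    def __post_init__(self) -> None:
        if self.timeout_seconds <= 0:
            raise InvalidInputError("timeout_seconds must be > 0")
        if self.level_cap < 0:
            raise InvalidInputError("level_cap must be >= 0")
        if not self.topics:
            raise InvalidInputError("at least one topic is required")


def read_universities_csv(path: str | Path) -> list[UniversityRecord]:
    """CSV with a header row and a 'university_name' column."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        if "university_name" not in reader.fieldnames:
            raise InvalidInputError(
                "universities CSV must have a 'university_name' column"
            )
        return [
            UniversityRecord(name=row["university_name"])
            for row in reader
            if (row.get("university_name") or "").strip()
        ]


class _PhaseTimer:
    def __init__(self, records: list[dict], university: str, topic: str):
        self.records = records
        self.university = university
        self.topic = topic

    def time(self, phase: str):
        timer = self

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, *exc):
                elapsed_ms = (time.perf_counter() - self.t0) * 1000.0
                timer.records.append(
                    {
                        "university": timer.university,
                        "topic": timer.topic,
                        "phase": phase,
                        "status": "error" if exc_type else "ok",
                        "elapsed_ms": elapsed_ms,
                        "kind": "network" if phase in _NETWORK_PHASES
                        else "compute",
                    }
                )
                return False

        return _Ctx()


def _assess_one(
    university: UniversityRecord,
    topic: TopicSpec,
    config: RunConfig,
    reference_text: Optional[str],
    timer: _PhaseTimer,
) -> QualityReport:
    backend = config.backend
    with timer.time("locate"):
        location = locator.locate_shc(
            university, backend.search_backend, backend.redirect_resolver
        )
    if not location.found:
        return QualityReport(
            university=university.name, topic=topic.name, status="shc_not_found"
        )
    home_url = location.home_url
    host = host_of(home_url)

    with timer.time("search"):
        site_backend = backend.site_search_for_host(netloc_of(home_url))
        if site_backend is not None:
            query = gatherer.build_topic_query(topic, host)
            result_urls = gatherer.site_search(query, site_backend)
        else:
            result_urls = gatherer.crawl_search(
                home_url, topic, backend.fetcher, config.level_cap,
                config.timeout_seconds, config.retries,
            )

    with timer.time("fetch"):
        pages = gatherer.fetch_pages(
            result_urls, backend.fetcher, config.timeout_seconds, config.retries
        )

    with timer.time("extract"):
        from .htmltext import html_to_sentences
        from .urls import normalize_url

        extracts, urls_ok, pages_ok = [], [], []
        for page in pages:
            if page.status != "ok":
                log.warning(
                    "%s/%s: skipping %s (%s)", university.name, topic.name,
                    page.requested_url, page.status,
                )
                continue
            sentences = html_to_sentences(page.html)
            extracts.append(
                gatherer.extract_keyword_context(
                    sentences, topic, source_url=normalize_url(page.final_url),
                    window=config.context_window,
                )
            )
            urls_ok.append(normalize_url(page.final_url))
            pages_ok.append(page)
        content = gatherer.consolidate(extracts, urls_ok)
        if config.audit_dir is not None:
            _dump_audit(config.audit_dir, university.name, topic.name, content)

    with timer.time("navigate"):
        if result_urls:
            nav = metrics.navigation(
                home_url, result_urls, backend.fetcher, config.level_cap,
                config.timeout_seconds, config.retries,
            )
        else:
            nav = NavigationResult(clicks=-1, trace=())

    with timer.time("metrics"):
        report = _score(
            university.name, topic, content, pages_ok, nav, reference_text
        )
        report.shc_home_url = home_url
    return report


def _score(
    university_name: str,
    topic: TopicSpec,
    content: ConsolidatedContent,
    pages_ok: list,
    nav: NavigationResult,
    reference_text: Optional[str],
) -> QualityReport:
    report = QualityReport(
        university=university_name,
        topic=topic.name,
        status="ok" if len(content) else "no_content",
        navigation=nav,
        n_pages=len(pages_ok),
        timeliness=metrics.timeliness(pages_ok),
        prevalence=metrics.prevalence(content, topic),
        coverage_pct=metrics.coverage(content, topic),
    )
    if len(content):
        scores = metrics.readability(content)
        report.fre, report.fkgl = scores.fre, scores.fkgl
        senti = metrics.sentiment(content)
        report.objectivity = senti.objectivity
        report.polarity = senti.polarity
        if reference_text is not None:
            report.similarity = metrics.similarity(content, reference_text)
    return report


def run_pipeline(config: RunConfig) -> tuple[list[QualityReport], list[dict]]:
    """Assess every (university, topic) pair; returns (reports, phase log).

    Writes the report CSV and the JSON-lines phase log when configured.
    """
    universities = read_universities_csv(config.universities_csv)
    references = {
        topic_name: Path(p).read_text(encoding="utf-8")
        for topic_name, p in config.reference_docs.items()
    }
    reports: list[QualityReport] = []
    records: list[dict] = []
    for university in universities:
        for topic in config.topics:
            timer = _PhaseTimer(records, university.name, topic.name)
            try:
                report = _assess_one(
                    university, topic, config, references.get(topic.name), timer
                )
            except ShcqualError as exc:
                log.error("%s/%s failed: %s", university.name, topic.name, exc)
                report = QualityReport(
                    university=university.name, topic=topic.name, status="error"
                )
            reports.append(report)
    if config.output_csv is not None:
        write_report_csv(reports, config.output_csv)
    if config.log_path is not None:
        with open(config.log_path, "w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return reports, records


def _dump_audit(
    audit_dir: str | Path,
    university: str,
    topic: str,
    content: ConsolidatedContent,
) -> None:
    directory = Path(audit_dir)
    directory.mkdir(parents=True, exist_ok=True)
    slug = "-".join(
        "".join(c if c.isalnum() else "-" for c in part).strip("-").lower()
        for part in (university, topic)
    )
    (directory / f"{slug}.txt").write_text(
        "".join(s.text + "\n" for s in content.sentences), encoding="utf-8"
    )


# --------------------------------------------------------------------------
# report serialization


def _fmt(value: Optional[float], digits: int = 4) -> str:
    return "" if value is None else f"{value:.{digits}f}"


def _fmt_timestamp(stamp) -> str:
    if isinstance(stamp, datetime):
        return stamp.isoformat()
    return str(stamp)  # the -1 sentinel, written literally


def report_row(report: QualityReport) -> dict[str, str]:
    return {
        "university_name": report.university,
        "topic": report.topic,
        "status": report.status,
        "fre": _fmt(report.fre),
        "fkgl": _fmt(report.fkgl),
        "prevalence": str(report.prevalence),
        "coverage_pct": f"{report.coverage_pct:.2f}",
        "objectivity": _fmt(report.objectivity),
        "polarity": _fmt(report.polarity),
        "nav_clicks": str(report.navigation.clicks),
        "nav_trace": "|".join(report.navigation.trace),
        "n_pages": str(report.n_pages),
        "timeliness": ";".join(
            f"{url}={_fmt_timestamp(stamp)}"
            for url, stamp in report.timeliness.items()
        ),
        "similarity": _fmt(report.similarity),
    }


def write_report_csv(reports: Sequence[QualityReport], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for report in reports:
            writer.writerow(report_row(report))


# --------------------------------------------------------------------------
# timing


def timing_report(records: Sequence[dict]) -> dict[str, dict[str, float]]:
    """Per-university network/compute seconds and fractions from a phase log.

    Fractions sum to 1 (up to floating error) whenever any time was
    recorded.
    """
    out: dict[str, dict[str, float]] = {}
    for rec in records:
        entry = out.setdefault(
            rec["university"],
            {"network_time": 0.0, "compute_time": 0.0},
        )
        key = "network_time" if rec["kind"] == "network" else "compute_time"
        entry[key] += rec["elapsed_ms"] / 1000.0
    for entry in out.values():
        total = entry["network_time"] + entry["compute_time"]
        entry["total_time"] = total
        entry["network_fraction"] = entry["network_time"] / total if total else 0.0
        entry["compute_fraction"] = entry["compute_time"] / total if total else 0.0
    return out
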