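"""Phase 2: gather topic-relevant text from an SHC site.

Pipeline: build a disjunctive site-restricted query from the topic
keywords; ask the search backend (or, with no backend, breadth-first crawl
the site) for keyword-bearing pages; fetch them; segment each page into
sentences; keep every anchor sentence (contains a keyword) plus a
+-window of context sentences, truncated at page boundaries; and
consolidate across pages, dropping duplicate sentences (first occurrence
wins, after case-folding/whitespace/terminal-punctuation normalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence

from .errors import InvalidInputError
from .fetch import DEFAULT_RETRIES, DEFAULT_TIMEOUT_SECONDS, Fetcher, fetch_page
from .htmltext import extract_links, html_to_sentences
from .text import contains_any_keyword, normalize_sentence
from .types import ConsolidatedContent, FetchedPage, SentenceRecord, TopicSpec
from .urls import host_of, normalize_url, same_site

log = logging.getLogger(__name__)

DEFAULT_CONTEXT_WINDOW = 5


@dataclass(frozen=True)
class TopicQuery:
    """A disjunctive keyword query restricted to one site host.

    Serialization to a concrete engine syntax (e.g. "kw1, kw2; site:host")
    is the backend's job; the pipeline only handles the structured form.
    """

    keywords: tuple[str, ...]
    restrict_host: str


class SiteSearchBackend(Protocol):
    def site_search(self, query: TopicQuery) -> list[str]:  # pragma: no cover
        ...


def build_topic_query(topic: TopicSpec, site_host: str) -> TopicQuery:
    if not site_host or not site_host.strip():
        raise InvalidInputError("site_host must be non-empty")
    return TopicQuery(keywords=topic.keywords, restrict_host=site_host.strip().lower())


def site_search(query: TopicQuery, backend: SiteSearchBackend) -> list[str]:
    """Backend results filtered to the restricted host, order preserved."""
    urls = backend.site_search(query)
    return [u for u in urls if same_site(host_of(u), query.restrict_host)]


def crawl_search(
    home_url: str,
    topic: TopicSpec,
    fetcher: Fetcher,
    level_cap: int = 10,
    timeout_seconds: float = DEFAULT_TIMEOUT_SECONDS,
    retries: int = DEFAULT_RETRIES,
) -> list[str]:
    """Search-backend fallback: BFS-crawl the site (same traversal rules as
    the navigation metric) and return every reachable keyword-bearing page
    in visit order.  Results carry "crawl" provenance in the run log."""
    from .metrics import _bfs_walk  # shared traversal engine

    hits: list[str] = []
    for url, _level, page in _bfs_walk(
        home_url, fetcher, level_cap, timeout_seconds, retries
    ):
        if page is not None and page.status == "ok":
            text = " ".join(html_to_sentences(page.html))
            if contains_any_keyword(text, topic.keywords):
                hits.append(url)
    return hits


def fetch_pages(
    urls: Sequence[str],
    fetcher: Fetcher | None = None,
    timeout_seconds: float = DEFAULT_TIMEOUT_SECONDS,
    retries: int = DEFAULT_RETRIES,
) -> list[FetchedPage]:
    """Fetch result pages; dead pages are kept with their failure status."""
    return [
        fetch_page(u, fetcher, timeout_seconds, retries) for u in urls
    ]


def extract_keyword_context(
    sentences: Sequence[str],
    topic: TopicSpec,
    source_url: str = "",
    window: int = DEFAULT_CONTEXT_WINDOW,
) -> list[SentenceRecord]:
    """Anchor sentences plus +-*window* context, in document order.

    Windows overlapping at page boundaries are truncated; a sentence
    appears at most once even when windows overlap.
    """
    if window < 0:
        raise InvalidInputError("window must be >= 0")
    anchors = [
        i for i, s in enumerate(sentences)
        if contains_any_keyword(s, topic.keywords)
    ]
    keep: set[int] = set()
    for i in anchors:
        keep.update(range(max(0, i - window), min(len(sentences), i + window + 1)))
    anchor_set = set(anchors)
    return [
        SentenceRecord(
            text=sentences[i], source_url=source_url, index=i,
            is_anchor=i in anchor_set,
        )
        for i in sorted(keep)
    ]


def consolidate(
    extracts: Sequence[Sequence[SentenceRecord]],
    result_urls: Sequence[str] = (),
) -> ConsolidatedContent:
    """Concatenate per-page extracts and drop duplicate sentences.

    Page order then sentence order is preserved; the first occurrence of
    each normalized sentence text is kept.
    """
    seen: set[str] = set()
    kept: list[SentenceRecord] = []
    for page_extract in extracts:
        for record in page_extract:
            key = normalize_sentence(record.text)
            if key and key not in seen:
                seen.add(key)
                kept.append(record)
    urls = list(result_urls) or list(dict.fromkeys(r.source_url for r in kept))
    return ConsolidatedContent(sentences=tuple(kept), source_urls=tuple(urls))


def gather(
    home_url: str,
    topic: TopicSpec,
    fetcher: Fetcher,
    backend: SiteSearchBackend | None = None,
    window: int = DEFAULT_CONTEXT_WINDOW,
    timeout_seconds: float = DEFAULT_TIMEOUT_SECONDS,
    retries: int = DEFAULT_RETRIES,
    level_cap: int = 10,
) -> tuple[ConsolidatedContent, list[FetchedPage], list[str]]:
    """Run phase 2 end to end for one site and topic.

    Returns (consolidated content, fetched pages, result URLs).
    """
    query = build_topic_query(topic, host_of(home_url))
    if backend is not None:
        result_urls = site_search(query, backend)
    else:
        log.info("no search backend configured; crawling %s", home_url)
        result_urls = crawl_search(
            home_url, topic, fetcher, level_cap, timeout_seconds, retries
        )
    pages = fetch_pages(result_urls, fetcher, timeout_seconds, retries)
    extracts = []
    urls_ok: list[str] = []
    for page in pages:
        if page.status != "ok":
            log.warning("skipping %s (%s)", page.requested_url, page.status)
            continue
        sentences = html_to_sentences(page.html)
        extracts.append(
            extract_keyword_context(
                sentences, topic, source_url=normalize_url(page.final_url),
                window=window,
            )
        )
        urls_ok.append(normalize_url(page.final_url))
    content = consolidate(extracts, urls_ok)
    return content, pages, result_urls


__all__ = [
    "TopicQuery", "SiteSearchBackend", "build_topic_query", "site_search",
    "crawl_search", "fetch_pages", "extract_keyword_context", "consolidate",
    "gather", "extract_links",
]
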