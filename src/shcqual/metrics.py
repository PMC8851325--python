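"""Phase 3: the eight information-quality metrics.

readability   Flesch Reading Ease / Flesch-Kincaid Grade Level over the
              consolidated text.
prevalence    cumulative keyword occurrence count (shared matcher).
coverage      % of distinct keywords found at least once, in [0, 100].
objectivity   1 - lexicon subjectivity.
polarity      lexicon polarity in [-1, 1].
navigation    minimum clicks from the home page to the nearest
              keyword-bearing page, by breadth-first traversal of
              within-domain hyperlinks; -1 outside the level cap.
timeliness    per-page Last-Modified instant, -1 when absent/unparseable.
similarity    cosine of term-frequency vectors of the gathered text and an
              expert-written reference document.
"""

from __future__ import annotations

import logging
from collections import deque
from datetime import datetime, timezone
from email.utils import parsedate_to_datetime
from typing import Iterator, Sequence

from .errors import EmptyContentError
from .fetch import DEFAULT_RETRIES, DEFAULT_TIMEOUT_SECONDS, Fetcher, fetch_page
from .htmltext import extract_links
from .sentiment import score_text
from .syllables import count_syllables
from .text import contains_keyword, count_keyword, word_tokens
from .types import (
    ConsolidatedContent,
    FetchedPage,
    NavigationResult,
    ReadabilityScores,
    SentimentScores,
    Timestamp,
    TopicSpec,
)
from .urls import host_of, normalize_url

log = logging.getLogger(__name__)

DEFAULT_LEVEL_CAP = 10

# Standard Flesch-Kincaid coefficients.
_FRE_BASE, _FRE_WPS, _FRE_SPW = 206.835, 1.015, 84.6
_FKGL_WPS, _FKGL_SPW, _FKGL_BASE = 0.39, 11.8, 15.59


# --------------------------------------------------------------------------
# Metric 1: readability

def readability(content: ConsolidatedContent | Sequence[str]) -> ReadabilityScores:
    """FRE and FKGL from sentence, word, and syllable counts.

    Raises EmptyContentError when there is no sentence or no word; the
    report layer turns that into an explicit "no content" marker so
    absence is distinguishable from easy-to-read text.
    """
    if isinstance(content, ConsolidatedContent):
        sentences = [s.text for s in content.sentences]
    else:
        sentences = list(content)
    n_sentences = len(sentences)
    words = [w for s in sentences for w in word_tokens(s)]
    n_words = len(words)
    if n_sentences == 0 or n_words == 0:
        raise EmptyContentError("readability needs at least one sentence and word")
    n_syllables = sum(count_syllables(w) for w in words)
    wps = n_words / n_sentences
    spw = n_syllables / n_words
    fre = _FRE_BASE - _FRE_WPS * wps - _FRE_SPW * spw
    fkgl = _FKGL_WPS * wps + _FKGL_SPW * spw - _FKGL_BASE
    return ReadabilityScores(
        fre=fre, fkgl=fkgl, n_sentences=n_sentences,
        n_words=n_words, n_syllables=n_syllables,
    )


# --------------------------------------------------------------------------
# Metrics 2 & 3: prevalence and coverage

def prevalence(content: ConsolidatedContent, topic: TopicSpec) -> int:
    """Cumulative frequency of all keywords in the consolidated text.

    Overlapping keywords (e.g. "IUD" and "hormonal IUD") are each counted
    independently.
    """
    text = content.text
    return sum(count_keyword(text, kw) for kw in topic.keywords)


def coverage(content: ConsolidatedContent, topic: TopicSpec) -> float:
    """100 x (distinct keywords present) / (total keywords), in [0, 100]."""
    text = content.text
    found = sum(1 for kw in topic.keywords if contains_keyword(text, kw))
    return 100.0 * found / len(topic.keywords)


# --------------------------------------------------------------------------
# Metrics 4 & 5: objectivity and polarity

def sentiment(content: ConsolidatedContent | str) -> SentimentScores:
    """Lexicon polarity/subjectivity of the whole text; empty text scores
    (0, 0) by convention (subjectivity 0 => objectivity 1)."""
    text = content if isinstance(content, str) else content.text
    return score_text(text)


# --------------------------------------------------------------------------
# Metric 6: navigation

def _bfs_walk(
    home_url: str,
    fetcher: Fetcher,
    level_cap: int,
    timeout_seconds: float,
    retries: int,
) -> Iterator[tuple[str, int, FetchedPage | None]]:
    """Breadth-first walk over within-domain hyperlinks.

    Yields (url, level, fetched page) in FIFO pop order; links are
    enqueued in document order.  The visited set is keyed on normalized
    URLs, which cannot change the minimum distance (the first visit in a
    BFS is along a shortest path) but prevents re-enqueueing on cycles.
    Nodes whose level exceeds *level_cap* are not yielded.
    """
    home_host = host_of(home_url)
    queue: deque[tuple[str, int]] = deque([(home_url, 0)])
    visited = {normalize_url(home_url)}
    while queue:
        url, level = queue.popleft()
        if level > level_cap:
            return
        page = fetch_page(url, fetcher, timeout_seconds, retries)
        yield url, level, page
        if page.status != "ok":
            continue
        for link in extract_links(page.html, page.final_url):
            if host_of(link) != home_host:
                continue  # outside the SHC web domain
            key = normalize_url(link)
            if key in visited:
                continue
            visited.add(key)
            queue.append((link, level + 1))


def navigation(
    home_url: str,
    target_urls: Sequence[str],
    fetcher: Fetcher,
    level_cap: int = DEFAULT_LEVEL_CAP,
    timeout_seconds: float = DEFAULT_TIMEOUT_SECONDS,
    retries: int = DEFAULT_RETRIES,
) -> NavigationResult:
    """Minimum clicks from *home_url* to any target, with the click trace.

    FIFO breadth-first traversal from the home page; a node is tested
    against the targets before its links are expanded, so a keyword-bearing
    home page yields 0 clicks.  Returns -1 with an empty trace when a
    popped node's level exceeds *level_cap* or the queue empties; a home
    page that cannot be fetched additionally sets home_unreachable.
    """
    targets = {normalize_url(u) for u in target_urls}
    home_host = host_of(home_url)
    queue: deque[tuple[str, int, tuple[str, ...]]] = deque(
        [(home_url, 0, (home_url,))]
    )
    visited = {normalize_url(home_url)}
    first = True
    while queue:
        url, level, trace = queue.popleft()
        if level > level_cap:
            return NavigationResult(clicks=-1, trace=())
        if normalize_url(url) in targets:
            return NavigationResult(clicks=level, trace=trace)
        page = fetch_page(url, fetcher, timeout_seconds, retries)
        if page.status != "ok":
            if first:
                return NavigationResult(clicks=-1, trace=(), home_unreachable=True)
            continue
        first = False
        for link in extract_links(page.html, page.final_url):
            if host_of(link) != home_host:
                continue
            key = normalize_url(link)
            if key in visited:
                continue
            visited.add(key)
            queue.append((link, level + 1, trace + (link,)))
    return NavigationResult(clicks=-1, trace=())


# --------------------------------------------------------------------------
# Metric 7: timeliness

def timeliness(pages: Sequence[FetchedPage]) -> dict[str, Timestamp]:
    """Per-page Last-Modified instant (UTC); -1 when absent or unparseable."""
    out: dict[str, Timestamp] = {}
    for page in pages:
        url = normalize_url(page.final_url)
        stamp: Timestamp = -1
        if page.last_modified:
            try:
                parsed = parsedate_to_datetime(page.last_modified)
                if parsed.tzinfo is None:
                    parsed = parsed.replace(tzinfo=timezone.utc)
                stamp = parsed.astimezone(timezone.utc)
            except (TypeError, ValueError):
                log.warning(
                    "unparseable Last-Modified %r for %s",
                    page.last_modified, url,
                )
        out[url] = stamp
    return out


# --------------------------------------------------------------------------
# Metric 8: relevancy / similarity

def similarity(content: ConsolidatedContent | str, reference: str) -> float:
    """Cosine of raw term-frequency vectors over case-folded word tokens.

    No stop-word removal and no weighting: 1 means identical direction,
    0 orthogonal vocabularies.  Empty gathered content scores 0.
    """
    if not reference or not word_tokens(reference):
        raise EmptyContentError("reference document must be non-empty")
    text = content if isinstance(content, str) else content.text
    if not word_tokens(text):
        return 0.0
    from sklearn.feature_extraction.text import CountVectorizer
    from sklearn.metrics.pairwise import cosine_similarity

    vectorizer = CountVectorizer(analyzer=word_tokens)
    matrix = vectorizer.fit_transform([text, reference])
    return float(cosine_similarity(matrix[0], matrix[1])[0, 0])


__all__ = [
    "readability", "prevalence", "coverage", "sentiment", "navigation",
    "timeliness", "similarity", "count_syllables", "DEFAULT_LEVEL_CAP",
]
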