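"""Locating a university's student-health-center (SHC) home page.

The lookup is a four-step procedure: build a search query from the
institution name plus the phrase "student health center"; run it against a
search backend; take the first of the top three results hosted under .edu
(none → the SHC is declared not found; results past rank 3 are never
consulted); and sanitize the winning URL into the canonical home URL by
following redirects and stripping a known utility sub-path such as
/contacts, /appointments or /location.

The search backend is an injected interface (query text -> ordered
results) so commercial engines and offline fixture universes are
interchangeable.  The .edu test is applied to the raw result host; a
non-.edu result that would redirect into .edu does not qualify.
"""

from __future__ import annotations

from typing import Callable, Iterable, Protocol
from urllib.parse import urlsplit, urlunsplit

from .errors import InvalidInputError
from .types import SearchResult, ShcLocation, UniversityRecord
from .urls import host_of, is_edu_host

SHC_PHRASE = "student health center"

#: Trailing path segments that point inside an SHC site rather than at its
#: home page.  Configurable; matching is exact and at most one segment is
#: removed per sanitization pass.
DEFAULT_STRIP_SEGMENTS = frozenset({"contacts", "appointments", "location"})

#: resolver contract: absolute URL -> final URL after following redirects.
#: Must raise FetchTimeoutError on timeout and RedirectLoopError after
#: more than 10 hops.
RedirectResolver = Callable[[str], str]


class SearchBackend(Protocol):
    """Query text in, ranked results out (ranks unique, starting at 1)."""

    def search(self, query: str) -> list[SearchResult]:  # pragma: no cover
        ...


def build_locator_query(university: UniversityRecord) -> str:
    """The search query: trimmed institution name + 'student health center'."""
    name = university.name.strip()
    if not name:
        raise InvalidInputError("university name must be non-empty")
    return f"{name} {SHC_PHRASE}"


def select_shc_url(results: Iterable[SearchResult], top_n: int = 3) -> ShcLocation:
    """First of the top *top_n* results hosted under .edu, else not_found."""
    for result in list(results)[:top_n]:
        if is_edu_host(host_of(result.url)):
            return ShcLocation(status="found", home_url=result.url)
    return ShcLocation(status="not_found")


def sanitize_home_url(
    url: str,
    resolver: RedirectResolver,
    strip_segments: frozenset[str] = DEFAULT_STRIP_SEGMENTS,
) -> str:
    """Canonical SHC home URL: redirects resolved, one utility suffix
    stripped, query string and fragment dropped."""
    final = resolver(url)
    parts = urlsplit(final)
    path = parts.path
    segments = [seg for seg in path.split("/") if seg]
    if segments and segments[-1].lower() in strip_segments:
        segments = segments[:-1]
        path = "/" + "/".join(segments)
        if segments:
            path += "/"
    if not path:
        path = "/"
    return urlunsplit((parts.scheme, parts.netloc, path, "", ""))


def locate_shc(
    university: UniversityRecord,
    backend: SearchBackend,
    resolver: RedirectResolver,
    strip_segments: frozenset[str] = DEFAULT_STRIP_SEGMENTS,
) -> ShcLocation:
    """Full phase-1 lookup: query, select among top 3, sanitize."""
    results = backend.search(build_locator_query(university))
    location = select_shc_url(results)
    if not location.found:
        return location
    home = sanitize_home_url(location.home_url, resolver, strip_segments)
    return ShcLocation(status="found", home_url=home)
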