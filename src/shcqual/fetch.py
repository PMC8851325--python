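"""HTTP fetching with timeouts, retries, and a bounded redirect follower.

Failures are encoded in FetchedPage.status ("timeout", "http_error")
rather than raised, so one dead page can never abort a batch run.  The
redirect resolver used by URL sanitization *does* raise
(FetchTimeoutError / RedirectLoopError) because locating the home page
cannot proceed without an answer.
"""

from __future__ import annotations

import logging
import socket
import urllib.error
import urllib.request
from datetime import datetime, timezone
from typing import Protocol

from .errors import FetchTimeoutError, RedirectLoopError
from .urls import absolutize

log = logging.getLogger(__name__)

DEFAULT_TIMEOUT_SECONDS = 30.0
DEFAULT_RETRIES = 1
MAX_REDIRECT_HOPS = 10

_USER_AGENT = "shcqual/0.1 (health-information quality metrics)"

# import here so FetchedPage users get one canonical class
from .types import FetchedPage  # noqa: E402


class Fetcher(Protocol):
    """Contract shared by the live HTTP fetcher and fixture fetchers."""

    def fetch(self, url: str, timeout: float) -> FetchedPage:  # pragma: no cover
        ...

    def resolve(self, url: str) -> str:  # pragma: no cover
        ...


def _now() -> datetime:
    return datetime.now(timezone.utc)


class HttpFetcher:
    """Live fetcher over urllib with an explicit redirect hop cap."""

    def fetch(self, url: str, timeout: float) -> FetchedPage:
        current = url
        for _hop in range(MAX_REDIRECT_HOPS + 1):
            req = urllib.request.Request(
                current, headers={"User-Agent": _USER_AGENT}
            )
            opener = urllib.request.build_opener(_NoRedirect)
            try:
                with opener.open(req, timeout=timeout) as resp:
                    code = resp.getcode()
                    if code in (301, 302, 303, 307, 308):
                        location = resp.headers.get("Location", "")
                        current = absolutize(current, location)
                        continue
                    body = resp.read()
                    charset = resp.headers.get_content_charset() or "utf-8"
                    return FetchedPage(
                        requested_url=url,
                        final_url=current,
                        status="ok",
                        html=body.decode(charset, errors="replace"),
                        last_modified=resp.headers.get("Last-Modified"),
                        fetched_at=_now(),
                        http_status=code,
                    )
            except urllib.error.HTTPError as exc:
                if exc.code in (301, 302, 303, 307, 308):
                    current = absolutize(current, exc.headers.get("Location", ""))
                    continue
                return FetchedPage(
                    requested_url=url, final_url=current, status="http_error",
                    fetched_at=_now(), http_status=exc.code,
                )
            except (socket.timeout, TimeoutError):
                return FetchedPage(
                    requested_url=url, final_url=current, status="timeout",
                    fetched_at=_now(),
                )
            except urllib.error.URLError as exc:
                if isinstance(exc.reason, (socket.timeout, TimeoutError)):
                    return FetchedPage(
                        requested_url=url, final_url=current, status="timeout",
                        fetched_at=_now(),
                    )
                log.warning("fetch failed for %s: %s", url, exc.reason)
                return FetchedPage(
                    requested_url=url, final_url=current, status="http_error",
                    fetched_at=_now(),
                )
        # redirect budget exhausted
        return FetchedPage(
            requested_url=url, final_url=current, status="http_error",
            fetched_at=_now(),
        )

    def resolve(self, url: str, timeout: float = DEFAULT_TIMEOUT_SECONDS) -> str:
        """Final URL after redirects; raises on timeout or redirect loops."""
        current = url
        for _hop in range(MAX_REDIRECT_HOPS):
            nxt = self._redirect_target(current, timeout)
            if nxt is None:
                return current
            current = nxt
        if self._redirect_target(current, timeout) is not None:
            raise RedirectLoopError(url)
        return current

    def _redirect_target(self, url: str, timeout: float) -> str | None:
        req = urllib.request.Request(url, headers={"User-Agent": _USER_AGENT})
        opener = urllib.request.build_opener(_NoRedirect)
        try:
            with opener.open(req, timeout=timeout) as resp:
                if resp.getcode() in (301, 302, 303, 307, 308):
                    return absolutize(url, resp.headers.get("Location", ""))
                return None
        except urllib.error.HTTPError as exc:
            if exc.code in (301, 302, 303, 307, 308):
                return absolutize(url, exc.headers.get("Location", ""))
            return None
        except (socket.timeout, TimeoutError):
            raise FetchTimeoutError(url)
        except urllib.error.URLError as exc:
            if isinstance(exc.reason, (socket.timeout, TimeoutError)):
                raise FetchTimeoutError(url)
            return None


class _NoRedirect(urllib.request.HTTPRedirectHandler):
    def redirect_request(self, req, fp, code, msg, headers, newurl):
        return None


def fetch_page(
    url: str,
    fetcher: Fetcher | None = None,
    timeout_seconds: float = DEFAULT_TIMEOUT_SECONDS,
    retries: int = DEFAULT_RETRIES,
) -> FetchedPage:
    """Fetch one page, retrying timeouts; never raises on page failure."""
    if timeout_seconds <= 0:
        raise ValueError("timeout_seconds must be > 0")
    fetcher = fetcher or HttpFetcher()
    page = fetcher.fetch(url, timeout_seconds)
    attempts = 0
    while page.status == "timeout" and attempts < retries:
        attempts += 1
        log.info("retrying %s after timeout (attempt %d)", url, attempts + 1)
        page = fetcher.fetch(url, timeout_seconds)
    return page
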