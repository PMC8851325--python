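"""Live search backend over the Google Custom Search JSON API.

One backend serves both roles: ranked locator queries and site-restricted
topic queries (the disjunctive keyword query is serialized as
'"kw1" OR "kw2" ... site:host').  Credentials come from the environment
(GOOGLE_API_KEY, GOOGLE_CSE_ID).  On quota errors the backend retries with
exponential backoff (1, 2, 4 ... seconds, 5 attempts) — a documented
default, configurable at construction.
"""

from __future__ import annotations

import json
import logging
import os
import time
import urllib.error
import urllib.parse
import urllib.request

from .errors import SearchBackendError
from .gatherer import TopicQuery
from .types import SearchResult

log = logging.getLogger(__name__)

_ENDPOINT = "https://www.googleapis.com/customsearch/v1"


class GoogleSearchBackend:
    def __init__(
        self,
        api_key: str | None = None,
        cse_id: str | None = None,
        max_attempts: int = 5,
        backoff_base_seconds: float = 1.0,
    ):
        self.api_key = api_key or os.environ.get("GOOGLE_API_KEY")
        self.cse_id = cse_id or os.environ.get("GOOGLE_CSE_ID")
        if not self.api_key or not self.cse_id:
            raise SearchBackendError(
                "live backend needs GOOGLE_API_KEY and GOOGLE_CSE_ID"
            )
        self.max_attempts = max_attempts
        self.backoff_base_seconds = backoff_base_seconds

    def _request(self, query: str) -> list[str]:
        params = urllib.parse.urlencode(
            {"key": self.api_key, "cx": self.cse_id, "q": query}
        )
        url = f"{_ENDPOINT}?{params}"
        delay = self.backoff_base_seconds
        for attempt in range(self.max_attempts):
            try:
                with urllib.request.urlopen(url, timeout=30) as resp:
                    data = json.loads(resp.read().decode("utf-8"))
                return [item["link"] for item in data.get("items", [])]
            except urllib.error.HTTPError as exc:
                if exc.code in (403, 429) and attempt < self.max_attempts - 1:
                    log.warning("search quota hit; backing off %.0fs", delay)
                    time.sleep(delay)
                    delay *= 2
                    continue
                raise SearchBackendError(f"search failed: HTTP {exc.code}") from exc
            except urllib.error.URLError as exc:
                raise SearchBackendError(f"search failed: {exc.reason}") from exc
        raise SearchBackendError("search retries exhausted")

    def search(self, query: str) -> list[SearchResult]:
        urls = self._request(query)
        return [SearchResult(rank=i + 1, url=u) for i, u in enumerate(urls)]

    def site_search(self, query: TopicQuery) -> list[str]:
        disjuncts = " OR ".join(f'"{kw}"' for kw in query.keywords)
        return self._request(f"{disjuncts} site:{query.restrict_host}")
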