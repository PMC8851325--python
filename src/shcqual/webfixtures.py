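"""Deterministic synthetic SHC-like websites.

These fixtures stand in for live university sites: a multi-page site under
one domain with a known hyperlink graph, keyword occurrences placed on
chosen pages, per-page Last-Modified headers, redirect chains, and
unresponsive (stalling) pages.  The JSON manifest written next to the HTML
is the single source of ground truth for oracle tests (link graph,
sentences, headers, behaviors).

A materialized site can be served two ways: from disk through DiskFetcher
(fast unit tests; stalls are simulated) or over a real local HTTP server
(FixtureHttpServer) that sleeps on stall pages, emits declared redirects
and Last-Modified headers — required to exercise the live fetch path.
"""

from __future__ import annotations

import json
import math
import random
import threading
import time
from dataclasses import dataclass, replace
from email.utils import format_datetime
from datetime import datetime, timezone
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Mapping, Optional
from urllib.parse import quote, unquote, urlsplit

from .errors import FetchTimeoutError, InvalidSpecError, RedirectLoopError
from .fetch import HttpFetcher, MAX_REDIRECT_HOPS
from .text import contains_any_keyword
from .types import FetchedPage, SearchResult, TopicSpec
from .gatherer import TopicQuery
from .urls import same_site

# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class PageSpec:
    """One synthetic page: content, outgoing links, headers, behavior."""

    path: str
    body_sentences: tuple[str, ...] = ()
    link_paths: tuple[str, ...] = ()
    external_links: tuple[str, ...] = ()
    last_modified: Optional[str] = None  # HTTP-date, or absent
    behavior: str = "ok"  # "ok" | "stall" | "http_error" | "redirect:<path>"


@dataclass(frozen=True)
class SiteSpec:
    """A whole synthetic site; the home page must exist among the pages."""

    domain: str
    home_path: str
    pages: tuple[PageSpec, ...]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        paths = [p.path for p in self.pages]
        if len(set(paths)) != len(paths):
            raise InvalidSpecError("duplicate page paths in site spec")
        if self.home_path not in set(paths):
            raise InvalidSpecError(f"home_path {self.home_path!r} has no page")

    def page(self, path: str) -> Optional[PageSpec]:
        for p in self.pages:
            if p.path == path:
                return p
        return None


@dataclass(frozen=True)
class MaterializedSite:
    root: Path
    spec: SiteSpec

    @property
    def manifest_path(self) -> Path:
        return self.root / "manifest.json"


def _filename_for(path: str) -> str:
    stem = quote(path.strip("/"), safe="") or "index"
    return stem + ".html"


# --------------------------------------------------------------------------
# materialization

_PAGE_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>{title}</title></head>
<body>
<main>
{paragraphs}
</main>
<nav>
{links}
</nav>
</body>
</html>
"""


def render_page(page: PageSpec) -> str:
    """Deterministic HTML for one page: sentences as paragraphs, links (in
    declared document order) inside <nav> so they are navigation, not text."""
    paragraphs = "\n".join(f"<p>{s}</p>" for s in page.body_sentences)
    hrefs = list(page.link_paths) + list(page.external_links)
    links = "\n".join(f'<a href="{h}">{h}</a>' for h in hrefs)
    return _PAGE_TEMPLATE.format(title=page.path, paragraphs=paragraphs, links=links)


def generate_site(spec: SiteSpec, out_dir: str | Path) -> MaterializedSite:
    """Write one HTML file per page plus the JSON manifest.

    Byte-identical across runs for the same spec (sorted JSON keys, no
    timestamps, deterministic file naming).
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    filenames = [_filename_for(p.path) for p in spec.pages]
    if len(set(filenames)) != len(filenames):
        raise InvalidSpecError("page paths collide after filename mapping")
    for page, fname in zip(spec.pages, filenames):
        (root / fname).write_text(render_page(page), encoding="utf-8")
    manifest = {
        "domain": spec.domain,
        "home_path": spec.home_path,
        "seed": spec.seed,
        "pages": [
            {
                "path": p.path,
                "filename": fname,
                "body_sentences": list(p.body_sentences),
                "link_paths": list(p.link_paths),
                "external_links": list(p.external_links),
                "last_modified": p.last_modified,
                "behavior": p.behavior,
            }
            for p, fname in zip(spec.pages, filenames)
        ],
    }
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return MaterializedSite(root=root, spec=spec)


def load_site(manifest_path: str | Path) -> MaterializedSite:
    """Reload a materialized site from its manifest."""
    path = Path(manifest_path)
    data = json.loads(path.read_text(encoding="utf-8"))
    pages = tuple(
        PageSpec(
            path=p["path"],
            body_sentences=tuple(p["body_sentences"]),
            link_paths=tuple(p["link_paths"]),
            external_links=tuple(p.get("external_links", ())),
            last_modified=p.get("last_modified"),
            behavior=p.get("behavior", "ok"),
        )
        for p in data["pages"]
    )
    spec = SiteSpec(
        domain=data["domain"], home_path=data["home_path"],
        pages=pages, seed=data.get("seed"),
    )
    return MaterializedSite(root=path.parent, spec=spec)


# --------------------------------------------------------------------------
# random sites

# Neutral, single-sentence health-information bank: no sentiment keywords
# of the bundled topics, every line one declarative sentence.
SENTENCE_BANK: tuple[str, ...] = (
    "The clinic is open Monday through Friday from nine to five.",
    "Students can schedule an appointment through the patient portal.",
    "The center offers immunizations for influenza and tetanus.",
    "Walk-in visits are handled in order of arrival each morning.",
    "A registered nurse reviews every incoming phone message.",
    "Laboratory results are posted to the portal within three days.",
    "The pharmacy fills prescriptions written by campus providers.",
    "Annual physical examinations satisfy most program requirements.",
    "Health education workshops run during the fall and spring terms.",
    "Students should bring their campus identification to each visit.",
    "The billing office can explain charges posted to a student account.",
    "Medical records may be requested in writing at any time.",
    "Allergy injections are administered by appointment on weekdays.",
    "After-hours concerns are handled by the advice line.",
    "Interpreters can be arranged for appointments in advance.",
    "The clinic follows state reporting rules for communicable disease.",
    "Nutrition counseling appointments last about forty minutes.",
    "Physical therapy referrals require a provider evaluation first.",
    "A travel consultation is recommended eight weeks before departure.",
    "Routine screenings are part of every yearly examination.",
    "Blood pressure checks are offered without an appointment.",
    "The health fee covers most services delivered on campus.",
    "Insurance questions can be directed to the enrollment office.",
    "Sports clearance forms are processed within five business days.",
)

_KEYWORD_TEMPLATES: tuple[str, ...] = (
    "The clinic provides {kw} services to enrolled students.",
    "Ask a nurse about {kw} at your next visit.",
    "Information about {kw} can be requested from the front desk.",
    "Providers discuss {kw} during routine appointments.",
)

_PATH_WORDS: tuple[str, ...] = (
    "services", "visits", "records", "billing", "portal", "forms",
    "providers", "programs", "resources", "education", "pharmacy",
    "lab", "referrals", "immunization", "screening", "travel",
    "nutrition", "therapy", "insurance", "orientation",
)


def random_site(
    seed: int,
    n_pages: int = 20,
    link_prob: float = 0.15,
    topic: Optional[TopicSpec] = None,
    keyword_page_fraction: float = 0.3,
    domain: str = "shc.example.edu",
) -> SiteSpec:
    """Seeded random site: same seed, same spec.

    The home page is always present (path "/").  Keywords from *topic* are
    injected into ceil(keyword_page_fraction * n_pages) pages chosen by
    the seeded generator; every other sentence comes from the neutral
    bank, so readability and sentiment on fixtures are deterministic.
    """
    if n_pages < 1:
        raise InvalidSpecError("n_pages must be >= 1")
    if not 0.0 <= link_prob <= 1.0:
        raise InvalidSpecError("link_prob must be in [0, 1]")
    rng = random.Random(seed)
    paths = ["/"]
    while len(paths) < n_pages:
        candidate = f"/{rng.choice(_PATH_WORDS)}-{len(paths)}"
        if candidate not in paths:
            paths.append(candidate)

    n_keyword_pages = 0
    keyword_pages: set[int] = set()
    if topic is not None and keyword_page_fraction > 0:
        n_keyword_pages = min(n_pages, math.ceil(keyword_page_fraction * n_pages))
        keyword_pages = set(rng.sample(range(n_pages), n_keyword_pages))

    pages = []
    for i, path in enumerate(paths):
        sentences = [
            rng.choice(SENTENCE_BANK) for _ in range(rng.randint(3, 8))
        ]
        if i in keyword_pages and topic is not None:
            for kw in rng.sample(topic.keywords, k=min(2, len(topic.keywords))):
                template = rng.choice(_KEYWORD_TEMPLATES)
                sentences.insert(
                    rng.randrange(len(sentences) + 1), template.format(kw=kw)
                )
        links = tuple(
            paths[j] for j in range(n_pages)
            if j != i and rng.random() < link_prob
        )
        last_modified = None
        if rng.random() < 0.7:
            when = datetime(
                2020, rng.randint(1, 12), rng.randint(1, 28),
                rng.randint(0, 23), rng.randint(0, 59), tzinfo=timezone.utc,
            )
            last_modified = format_datetime(when, usegmt=True)
        pages.append(
            PageSpec(
                path=path,
                body_sentences=tuple(sentences),
                link_paths=links,
                last_modified=last_modified,
            )
        )
    return SiteSpec(domain=domain, home_path="/", pages=tuple(pages), seed=seed)


def restructure_site(spec: SiteSpec, rename: Mapping[str, str]) -> SiteSpec:
    """Rename paths bijectively; content, link graph and headers unchanged.

    *rename* may cover a subset of paths (unmapped paths keep their name)
    but the induced full map must stay a bijection.
    """
    paths = {p.path for p in spec.pages}
    unknown = set(rename) - paths
    if unknown:
        raise InvalidSpecError(f"rename keys are not site paths: {sorted(unknown)}")
    full = {path: rename.get(path, path) for path in paths}
    if len(set(full.values())) != len(full):
        raise InvalidSpecError("rename map is not a bijection over site paths")
    pages = tuple(
        replace(
            p,
            path=full[p.path],
            link_paths=tuple(full.get(lp, lp) for lp in p.link_paths),
        )
        for p in spec.pages
    )
    return SiteSpec(
        domain=spec.domain, home_path=full[spec.home_path],
        pages=pages, seed=spec.seed,
    )


def link_graph(spec: SiteSpec) -> dict[str, list[str]]:
    """Adjacency (path -> linked page paths) from the manifest; dangling
    link targets are dropped.  Ground truth for shortest-path oracles."""
    paths = {p.path for p in spec.pages}
    return {
        p.path: [lp for lp in p.link_paths if lp in paths]
        for p in spec.pages
    }


# --------------------------------------------------------------------------
# backends over a materialized site


@dataclass
class FixtureBackends:
    fetcher: object
    search_backend: object
    redirect_resolver: object


class DiskFetcher:
    """Serve a materialized site from disk, honoring page behaviors.

    Stall pages report a timeout without sleeping; redirect chains are
    followed with the standard hop cap; unknown paths get an http_error
    page, as a real server would.
    """

    def __init__(self, site: MaterializedSite, base_url: Optional[str] = None):
        self.site = site
        self.base = (base_url or f"http://{site.spec.domain}").rstrip("/")
        self._by_path = {p.path: p for p in site.spec.pages}

    def url_for(self, path: str) -> str:
        return self.base + path

    def _lookup(self, url: str) -> Optional[PageSpec]:
        path = unquote(urlsplit(url).path) or "/"
        page = self._by_path.get(path)
        if page is None and path != "/" and path.rstrip("/") != path:
            page = self._by_path.get(path.rstrip("/"))
        return page

    def fetch(self, url: str, timeout: float) -> FetchedPage:
        current = url
        for _hop in range(MAX_REDIRECT_HOPS + 1):
            page = self._lookup(current)
            if page is None or page.behavior == "http_error":
                return FetchedPage(
                    requested_url=url, final_url=current,
                    status="http_error", http_status=404,
                )
            if page.behavior == "stall":
                return FetchedPage(
                    requested_url=url, final_url=current, status="timeout",
                )
            if page.behavior.startswith("redirect:"):
                current = self.url_for(page.behavior.split(":", 1)[1])
                continue
            html = (self.site.root / _filename_for(page.path)).read_text(
                encoding="utf-8"
            )
            return FetchedPage(
                requested_url=url, final_url=current, status="ok",
                html=html, last_modified=page.last_modified,
            )
        return FetchedPage(
            requested_url=url, final_url=current, status="http_error",
        )

    def resolve(self, url: str, timeout: float = 30.0) -> str:
        current = url
        for _hop in range(MAX_REDIRECT_HOPS):
            page = self._lookup(current)
            if page is None:
                return current
            if page.behavior == "stall":
                raise FetchTimeoutError(current)
            if page.behavior.startswith("redirect:"):
                current = self.url_for(page.behavior.split(":", 1)[1])
                continue
            return current
        raise RedirectLoopError(url)


class FixtureSiteSearch:
    """Brute-force manifest scan: returns the URLs of pages whose declared
    sentences contain any query keyword, in path order.  Exact by
    construction — the oracle the gatherer is tested against."""

    def __init__(self, site: MaterializedSite, base_url: Optional[str] = None):
        self.spec = site.spec
        self.base = (base_url or f"http://{site.spec.domain}").rstrip("/")

    def site_search(self, query: TopicQuery) -> list[str]:
        host = urlsplit(self.base).hostname or self.spec.domain
        if not same_site(host, query.restrict_host):
            return []
        hits = []
        for page in sorted(self.spec.pages, key=lambda p: p.path):
            text = " ".join(page.body_sentences)
            if contains_any_keyword(text, query.keywords):
                hits.append(self.base + page.path)
        return hits


def fixture_backends(
    site: MaterializedSite,
    base_url: Optional[str] = None,
    fetcher: object = None,
) -> FixtureBackends:
    """Bundle (fetcher, search backend, redirect resolver) for one site.

    Default is disk mode; pass the base URL of a FixtureHttpServer plus an
    HttpFetcher to exercise the live network path.
    """
    disk = DiskFetcher(site, base_url)
    f = fetcher or disk
    resolver = f.resolve if hasattr(f, "resolve") else disk.resolve
    return FixtureBackends(
        fetcher=f,
        search_backend=FixtureSiteSearch(site, base_url),
        redirect_resolver=resolver,
    )


# --------------------------------------------------------------------------
# HTTP serving


class FixtureHttpServer:
    """Serve a materialized site over loopback HTTP, honoring behaviors.

    Stall pages sleep for *stall_seconds* (set it past the client timeout
    to trigger timeouts); redirect pages answer 302 with the declared
    target; Last-Modified headers are emitted when present.
    """

    def __init__(self, site: MaterializedSite, stall_seconds: float = 5.0):
        self.site = site
        self.stall_seconds = stall_seconds
        by_path = {p.path: p for p in site.spec.pages}
        root = site.root
        stall_ref = self

        class Handler(BaseHTTPRequestHandler):
            def log_message(self, *args):  # quiet
                pass

            def do_GET(self):
                path = unquote(urlsplit(self.path).path) or "/"
                page = by_path.get(path) or by_path.get(path.rstrip("/") or "/")
                if page is None or page.behavior == "http_error":
                    self.send_error(404)
                    return
                if page.behavior == "stall":
                    time.sleep(stall_ref.stall_seconds)
                elif page.behavior.startswith("redirect:"):
                    self.send_response(302)
                    self.send_header(
                        "Location", page.behavior.split(":", 1)[1]
                    )
                    self.end_headers()
                    return
                body = (root / _filename_for(page.path)).read_bytes()
                self.send_response(200)
                self.send_header("Content-Type", "text/html; charset=utf-8")
                self.send_header("Content-Length", str(len(body)))
                if page.last_modified:
                    self.send_header("Last-Modified", page.last_modified)
                self.end_headers()
                self.wfile.write(body)

        class _QuietServer(ThreadingHTTPServer):
            daemon_threads = True

            def handle_error(self, request, client_address):
                # clients disconnecting mid-response (timeouts on stall
                # pages, shutdown races) are expected, not reportable
                pass

        self._server = _QuietServer(("127.0.0.1", 0), Handler)
        self._thread = threading.Thread(
            target=self._server.serve_forever, daemon=True
        )

    @property
    def base_url(self) -> str:
        host, port = self._server.server_address[:2]
        return f"http://{host}:{port}"

    def url_for(self, path: str) -> str:
        return self.base_url + path

    def backends(self) -> FixtureBackends:
        return fixture_backends(
            self.site, base_url=self.base_url, fetcher=HttpFetcher()
        )

    def aliased_fetcher(self) -> HostAliasFetcher:
        """An HttpFetcher that accepts the site's canonical-domain URLs and
        routes them to this server."""
        return HostAliasFetcher(
            HttpFetcher(), f"http://{self.site.spec.domain}", self.base_url
        )

    def __enter__(self) -> "FixtureHttpServer":
        self._thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self._server.shutdown()
        self._server.server_close()


class HostAliasFetcher:
    """Fetch canonical-domain URLs through a differently-addressed server.

    Plays the role of a hosts-file override: URLs keep the fixture's
    canonical .edu domain everywhere in the pipeline (locator rules,
    traces, reports) while the actual sockets go to *real_base* (for
    example a loopback FixtureHttpServer).
    """

    def __init__(self, inner, canonical_base: str, real_base: str):
        self.inner = inner
        self.canonical = canonical_base.rstrip("/")
        self.real = real_base.rstrip("/")

    def _to_real(self, url: str) -> str:
        return self.real + url[len(self.canonical):] \
            if url.startswith(self.canonical) else url

    def _to_canonical(self, url: str) -> str:
        return self.canonical + url[len(self.real):] \
            if url.startswith(self.real) else url

    def fetch(self, url: str, timeout: float) -> FetchedPage:
        page = self.inner.fetch(self._to_real(url), timeout)
        page.requested_url = url
        page.final_url = self._to_canonical(page.final_url)
        return page

    def resolve(self, url: str, timeout: float = 30.0) -> str:
        return self._to_canonical(self.inner.resolve(self._to_real(url), timeout))


# --------------------------------------------------------------------------
# a multi-university fixture universe for the locator


class FixtureUniverse:
    """Locator-level search backend over named fixture sites.

    Answers the phase-1 query "<university name> student health center"
    with the home URL of that university's fixture site; unknown names get
    an empty result list (SHC not found).  Extra ranked results can be
    injected per university to exercise the top-3 .edu rule.
    """

    def __init__(self) -> None:
        self._sites: dict[str, tuple[MaterializedSite, str, object]] = {}
        self._extra: dict[str, list[SearchResult]] = {}

    def add(
        self,
        university_name: str,
        site: MaterializedSite,
        base_url: Optional[str] = None,
        leading_results: Optional[list[str]] = None,
        fetcher: object = None,
    ) -> None:
        base = (base_url or f"http://{site.spec.domain}").rstrip("/")
        key = university_name.strip().casefold()
        self._sites[key] = (site, base, fetcher)
        if leading_results:
            self._extra[key] = leading_results

    def search(self, query: str) -> list[SearchResult]:
        suffix = " student health center"
        name = query[: -len(suffix)].strip().casefold() if query.endswith(suffix) else query.casefold()
        entry = self._sites.get(name)
        if entry is None:
            return []
        site, base, _fetcher = entry
        urls = list(self._extra.get(name, [])) + [base + site.spec.home_path]
        return [SearchResult(rank=i + 1, url=u) for i, u in enumerate(urls)]

    def site_for(self, university_name: str):
        return self._sites.get(university_name.strip().casefold())

    def bundle(self):
        """A pipeline BackendBundle that dispatches every request to the
        fixture site serving the requested host."""
        from .pipeline import BackendBundle
        from .urls import netloc_of

        universe = self

        def site_search_for_host(host: str):
            backends = universe.backends_for_host(host)
            return backends.search_backend if backends else None

        class _DispatchFetcher:
            @staticmethod
            def fetch(url: str, timeout: float) -> FetchedPage:
                backends = universe.backends_for_host(netloc_of(url))
                if backends is None:
                    return FetchedPage(
                        requested_url=url, final_url=url, status="http_error"
                    )
                return backends.fetcher.fetch(url, timeout)

            @staticmethod
            def resolve(url: str, timeout: float = 30.0) -> str:
                backends = universe.backends_for_host(netloc_of(url))
                if backends is None:
                    return url
                return backends.redirect_resolver(url)

        return BackendBundle(
            search_backend=universe,
            fetcher=_DispatchFetcher(),
            redirect_resolver=_DispatchFetcher.resolve,
            site_search_for_host=site_search_for_host,
        )

    def backends_for_host(self, host: str) -> Optional[FixtureBackends]:
        """Backends for the site serving *host* (a host or host:port)."""
        host = host.lower()
        for site, base, fetcher in self._sites.values():
            netloc = (urlsplit(base).netloc or site.spec.domain).lower()
            hostname = (urlsplit(base).hostname or site.spec.domain).lower()
            if host == netloc or (
                ":" not in netloc and same_site(host.partition(":")[0], hostname)
            ):
                return fixture_backends(site, base_url=base, fetcher=fetcher)
        return None
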