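"""URL helpers: host extraction, .edu test, and the normal form used by the
breadth-first crawler's visited set and by target matching.

Normal form: scheme and host lowercased, default ports dropped, fragment
stripped, empty path rendered as "/", a single trailing slash removed from
non-root paths.  The query string is preserved (distinct queries are distinct
pages).
"""

from urllib.parse import urljoin, urlsplit, urlunsplit

_DEFAULT_PORTS = {"http": 80, "https": 443}


def host_of(url: str) -> str:
    """Lowercased host name of an absolute URL ('' when there is none)."""
    host = urlsplit(url).hostname
    return (host or "").lower().rstrip(".")


def netloc_of(url: str) -> str:
    """Lowercased host[:port] of an absolute URL."""
    parts = urlsplit(url)
    host = (parts.hostname or "").lower().rstrip(".")
    if parts.port is not None and parts.port != _DEFAULT_PORTS.get(parts.scheme.lower()):
        return f"{host}:{parts.port}"
    return host


def is_edu_host(host: str) -> bool:
    """True when *host* is in the .edu top-level domain (case-insensitive)."""
    host = host.lower().rstrip(".")
    return host == "edu" or host.endswith(".edu")


def same_site(host: str, restrict_host: str) -> bool:
    """True when *host* equals *restrict_host* or is a subdomain of it."""
    host = host.lower().rstrip(".")
    restrict_host = restrict_host.lower().rstrip(".")
    return host == restrict_host or host.endswith("." + restrict_host)


def normalize_url(url: str) -> str:
    parts = urlsplit(url)
    scheme = parts.scheme.lower()
    host = (parts.hostname or "").lower().rstrip(".")
    port = parts.port
    netloc = host
    if port is not None and port != _DEFAULT_PORTS.get(scheme):
        netloc = f"{host}:{port}"
    path = parts.path or "/"
    if path != "/" and path.endswith("/"):
        path = path.rstrip("/")
    return urlunsplit((scheme, netloc, path, parts.query, ""))


def absolutize(base_url: str, href: str) -> str:
    return urljoin(base_url, href)
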