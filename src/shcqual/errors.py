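"""Exception types shared across the pipeline."""


class ShcqualError(Exception):
    """Base class for package errors."""


class InvalidInputError(ShcqualError, ValueError):
    """User-supplied input (university name, topic, config) is malformed."""


class InvalidSpecError(ShcqualError, ValueError):
    """A fixture site specification violates its invariants."""


class FetchTimeoutError(ShcqualError):
    """A fetch exceeded the configured timeout.

    Carries the offending URL so batch callers can report which page stalled.
    """

    def __init__(self, url: str, message: str | None = None):
        self.url = url
        super().__init__(message or f"timed out fetching {url}")


class RedirectLoopError(ShcqualError):
    """More redirect hops than the cap (10) while resolving a URL."""

    def __init__(self, url: str):
        self.url = url
        super().__init__(f"redirect loop (>10 hops) resolving {url}")


class SearchBackendError(ShcqualError):
    """The search backend failed to answer a query."""


class EmptyContentError(ShcqualError):
    """A metric that needs text was asked to score empty content."""
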