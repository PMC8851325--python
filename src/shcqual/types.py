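"""Domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence, Union

from .errors import InvalidInputError
from .text import dedupe_keywords


@dataclass(frozen=True)
class UniversityRecord:
    """An institution to assess, identified by its official name."""

    name: str

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise InvalidInputError("university name must be non-empty")


@dataclass(frozen=True)
class SearchResult:
    """One ranked hit from a search backend (ranks start at 1)."""

    rank: int
    url: str


@dataclass(frozen=True)
class ShcLocation:
    """Outcome of the student-health-center website lookup."""

    status: str  # "found" | "not_found"
    home_url: Optional[str] = None

    @property
    def found(self) -> bool:
        return self.status == "found"


@dataclass(frozen=True)
class TopicSpec:
    """A named health topic and the keyword vocabulary that represents it."""

    name: str
    keywords: tuple[str, ...]

    def __init__(self, name: str, keywords: Sequence[str]):
        deduped = dedupe_keywords(keywords)
        if not deduped:
            raise InvalidInputError(f"topic {name!r} needs at least one keyword")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "keywords", tuple(deduped))


@dataclass
class FetchedPage:
    """One retrieved web page plus the HTTP metadata the metrics need."""

    requested_url: str
    final_url: str
    status: str  # "ok" | "timeout" | "http_error"
    html: Optional[str] = None
    last_modified: Optional[str] = None  # raw HTTP-date header value
    fetched_at: Optional[datetime] = None
    http_status: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.html is not None):
            raise InvalidInputError("html must be present exactly when status is ok")


@dataclass(frozen=True)
class SentenceRecord:
    """One sentence with its provenance inside a page's sentence list."""

    text: str
    source_url: str
    index: int
    is_anchor: bool


@dataclass(frozen=True)
class ConsolidatedContent:
    """Deduplicated topic-anchored sentences for one site, with sources."""

    sentences: tuple[SentenceRecord, ...]
    source_urls: tuple[str, ...]

    @property
    def text(self) -> str:
        return " ".join(s.text for s in self.sentences)

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass(frozen=True)
class ReadabilityScores:
    fre: float
    fkgl: float
    n_sentences: int
    n_words: int
    n_syllables: int


@dataclass(frozen=True)
class SentimentScores:
    polarity: float
    subjectivity: float

    @property
    def objectivity(self) -> float:
        return 1.0 - self.subjectivity


@dataclass(frozen=True)
class NavigationResult:
    """Minimum click count from the home page to a target, with the path.

    clicks is -1 when no target is reachable within the level cap; the trace
    is then empty.  home_unreachable flags the degenerate case where the
    home page itself could not be fetched.
    """

    clicks: int
    trace: tuple[str, ...]
    home_unreachable: bool = False

    def __post_init__(self) -> None:
        if (self.clicks == -1) != (len(self.trace) == 0):
            raise InvalidInputError("clicks == -1 iff trace is empty")


Timestamp = Union[datetime, int]  # a parsed Last-Modified instant, or -1


@dataclass
class QualityReport:
    """The eight quality metrics for one (university, topic) pair."""

    university: str
    topic: str
    status: str  # "ok" | "shc_not_found" | "no_content" | "error"
    fre: Optional[float] = None
    fkgl: Optional[float] = None
    prevalence: int = 0
    coverage_pct: float = 0.0
    objectivity: Optional[float] = None
    polarity: Optional[float] = None
    navigation: NavigationResult = field(
        default_factory=lambda: NavigationResult(-1, ())
    )
    timeliness: dict[str, Timestamp] = field(default_factory=dict)
    similarity: Optional[float] = None
    n_pages: int = 0
    shc_home_url: Optional[str] = None
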