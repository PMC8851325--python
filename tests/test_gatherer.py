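"""Gathering topical text: queries, site search, fetching, sentence
extraction with context windows, and consolidation."""

import pytest

from shcqual import (
    TopicSpec,
    build_topic_query,
    consolidate,
    extract_keyword_context,
    generate_site,
    site_search,
)
from shcqual.errors import InvalidInputError
from shcqual.fetch import fetch_page
from shcqual.htmltext import extract_links, html_to_sentences
from shcqual.types import SentenceRecord
from shcqual.webfixtures import DiskFetcher, PageSpec, SiteSpec, fixture_backends

from helpers import NEUTRAL


def test_topic_query_is_disjunctive_and_host_restricted():
    topic = TopicSpec("covid", ["Corona", "coronavirus", "COVID"])
    query = build_topic_query(topic, "health.sfsu.edu")
    assert set(query.keywords) == {"Corona", "coronavirus", "COVID"}
    assert query.restrict_host == "health.sfsu.edu"


def test_topic_query_collapses_casefold_duplicates():
    topic = TopicSpec("t", ["IUD", "iud", "Iud"])
    query = build_topic_query(topic, "x.edu")
    assert query.keywords == ("IUD",)


def test_topic_query_single_keyword():
    query = build_topic_query(TopicSpec("t", ["condom"]), "x.edu")
    assert query.keywords == ("condom",)


def _six_page_site(tmp_path):
    pages = [
        PageSpec(
            path="/" if i == 0 else f"/page-{i}",
            body_sentences=(NEUTRAL,),
            link_paths=(),
        )
        for i in range(6)
    ]
    pages[2] = PageSpec(path="/page-2",
                        body_sentences=("We offer IUD insertion.",))
    pages[5] = PageSpec(path="/page-5",
                        body_sentences=("Ask about the contraceptive shot.",))
    spec = SiteSpec(domain="six.example.edu", home_path="/", pages=tuple(pages))
    return generate_site(spec, tmp_path / "six")


def test_site_search_returns_exactly_keyword_pages(tmp_path, larc_topic):
    site = _six_page_site(tmp_path)
    backends = fixture_backends(site)
    query = build_topic_query(larc_topic, "six.example.edu")
    urls = site_search(query, backends.search_backend)
    assert urls == [
        "http://six.example.edu/page-2",
        "http://six.example.edu/page-5",
    ]


def test_site_search_no_keyword_pages_is_empty(tmp_path):
    site = _six_page_site(tmp_path)
    backends = fixture_backends(site)
    query = build_topic_query(TopicSpec("t", ["zika"]), "six.example.edu")
    assert site_search(query, backends.search_backend) == []


def test_site_search_wrong_host_is_empty(tmp_path, larc_topic):
    site = _six_page_site(tmp_path)
    backends = fixture_backends(site)
    query = build_topic_query(larc_topic, "elsewhere.example.edu")
    assert site_search(query, backends.search_backend) == []


class TestFetchPage:
    @pytest.fixture
    def fetcher(self, tmp_path):
        spec = SiteSpec(
            domain="f.example.edu",
            home_path="/",
            pages=(
                PageSpec(path="/", body_sentences=("Hello there.",)),
                PageSpec(path="/slow", behavior="stall"),
                PageSpec(path="/gone", behavior="http_error"),
                PageSpec(path="/moved", behavior="redirect:/"),
            ),
        )
        return DiskFetcher(generate_site(spec, tmp_path / "f"))

    def test_ok_page_has_html(self, fetcher):
        page = fetch_page("http://f.example.edu/", fetcher)
        assert page.status == "ok" and "Hello there." in page.html

    def test_stall_page_times_out_without_raising(self, fetcher):
        page = fetch_page("http://f.example.edu/slow", fetcher, retries=1)
        assert page.status == "timeout" and page.html is None

    def test_missing_page_is_http_error(self, fetcher):
        page = fetch_page("http://f.example.edu/gone", fetcher)
        assert page.status == "http_error"

    def test_redirect_reaches_final_url(self, fetcher):
        page = fetch_page("http://f.example.edu/moved", fetcher)
        assert page.status == "ok"
        assert page.final_url == "http://f.example.edu/"

    def test_nonpositive_timeout_rejected(self, fetcher):
        with pytest.raises(ValueError):
            fetch_page("http://f.example.edu/", fetcher, timeout_seconds=0)


class TestHtmlToSentences:
    def test_paragraphs_become_sentences(self):
        assert html_to_sentences("<p>A red dog. A blue cat.</p>") == [
            "A red dog.", "A blue cat.",
        ]

    def test_script_and_style_text_is_dropped(self):
        html = "<script>var x = 'Secret phrase.';</script><p>Visible.</p>"
        assert html_to_sentences(html) == ["Visible."]

    def test_unparseable_markup_gives_empty_list(self):
        assert html_to_sentences("") == []

    def test_fixture_page_roundtrips_manifest_sentences(self, tmp_path):
        sentences = ("First fact here.", "Second fact there.")
        spec = SiteSpec(
            domain="r.example.edu", home_path="/",
            pages=(PageSpec(path="/", body_sentences=sentences,
                            link_paths=(), external_links=("https://cdc.gov/",)),),
        )
        site = generate_site(spec, tmp_path / "r")
        html = (site.root / "index.html").read_text()
        assert html_to_sentences(html) == list(sentences)
        assert extract_links(html, "http://r.example.edu/") == ["https://cdc.gov/"]


class TestExtractKeywordContext:
    def _sentences(self, n, anchor_indices, keyword="IUD"):
        return [
            f"Sentence {i} mentions {keyword}." if i in anchor_indices
            else f"Sentence {i} is plain."
            for i in range(n)
        ]

    def test_window_five_around_single_anchor(self, larc_topic):
        sentences = self._sentences(12, {6})
        records = extract_keyword_context(sentences, larc_topic, window=5)
        assert [r.index for r in records] == list(range(1, 12))
        assert [r.is_anchor for r in records].count(True) == 1

    def test_no_anchor_no_output(self, larc_topic):
        assert extract_keyword_context(
            self._sentences(8, set()), larc_topic
        ) == []

    def test_overlapping_windows_union_each_once(self, larc_topic):
        sentences = self._sentences(10, {2, 4})
        records = extract_keyword_context(sentences, larc_topic, window=5)
        assert [r.index for r in records] == list(range(10))

    def test_window_zero_is_exactly_anchors(self, larc_topic):
        sentences = self._sentences(9, {1, 7})
        records = extract_keyword_context(sentences, larc_topic, window=0)
        assert [r.index for r in records] == [1, 7]
        assert all(r.is_anchor for r in records)

    def test_window_truncated_at_page_bounds(self, larc_topic):
        records = extract_keyword_context(
            self._sentences(4, {0}), larc_topic, window=5
        )
        assert [r.index for r in records] == [0, 1, 2, 3]

    def test_negative_window_rejected(self, larc_topic):
        with pytest.raises(InvalidInputError):
            extract_keyword_context(["IUD info."], larc_topic, window=-1)


class TestConsolidate:
    def _rec(self, text, url="http://s.edu/a", index=0, anchor=True):
        return SentenceRecord(text=text, source_url=url, index=index,
                              is_anchor=anchor)

    def test_shared_disclaimer_kept_once(self):
        disclaimer = "Call 911 in an emergency."
        page_a = [self._rec("IUD info here."), self._rec(disclaimer, index=1)]
        page_b = [self._rec(disclaimer, url="http://s.edu/b"),
                  self._rec("Implant info.", url="http://s.edu/b", index=1)]
        content = consolidate([page_a, page_b],
                              ["http://s.edu/a", "http://s.edu/b"])
        texts = [s.text for s in content.sentences]
        assert texts.count(disclaimer) == 1
        # first occurrence (page a) wins
        assert content.sentences[1].source_url == "http://s.edu/a"

    def test_near_duplicate_after_normalization_dropped(self):
        page_a = [self._rec("The clinic is open.")]
        page_b = [self._rec("  the Clinic   is open ", url="http://s.edu/b")]
        content = consolidate([page_a, page_b])
        assert len(content) == 1

    def test_empty_extracts(self):
        content = consolidate([])
        assert len(content) == 0 and content.source_urls == ()

    def test_idempotent(self):
        pages = [[self._rec("A fact."), self._rec("Another fact.", index=1)]]
        once = consolidate(pages, ["http://s.edu/a"])
        twice = consolidate([once.sentences], list(once.source_urls))
        assert twice.sentences == once.sentences

    def test_every_source_url_listed(self):
        page = [self._rec("A fact.")]
        content = consolidate([page])
        assert all(s.source_url in content.source_urls
                   for s in content.sentences)
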