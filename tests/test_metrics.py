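"""The eight quality metrics against hand-computed and oracle values."""

from datetime import datetime, timezone

import pytest

from shcqual import (
    TopicSpec,
    coverage,
    generate_site,
    navigation,
    prevalence,
    readability,
    sentiment,
    similarity,
    timeliness,
)
from shcqual.errors import EmptyContentError
from shcqual.gatherer import consolidate, extract_keyword_context
from shcqual.types import ConsolidatedContent, FetchedPage, SentenceRecord
from shcqual.webfixtures import (
    DiskFetcher,
    PageSpec,
    SiteSpec,
    fixture_backends,
)

from helpers import NEUTRAL, chain_site_spec


def as_content(sentences, url="http://s.example.edu/p"):
    records = tuple(
        SentenceRecord(text=s, source_url=url, index=i, is_anchor=True)
        for i, s in enumerate(sentences)
    )
    return ConsolidatedContent(sentences=records, source_urls=(url,))


# ---------------------------------------------------------------------------
# readability

#: (sentences, expected sentence/word/syllable counts, expected FRE, FKGL);
#: the expectations are closed-form evaluations of the Flesch formulas on
#: hand-counted sentence/word/syllable tallies.
READABILITY_CASES = [
    (["The cat sat.", "The dog ran."], (2, 6, 6), 119.19, -2.62),
    (["Go."], (1, 1, 1), 121.22, -3.40),
    (["The doctor is here."], (1, 4, 5), 97.025, 0.72),
    (["Students visit the health center.", "The nurse can help."],
     (2, 9, 12), 89.4675, 1.8983333333),
    (["The university offers information."], (1, 4, 12), -51.025, 21.37),
    (["Call the clinic.", "Ask for a doctor.", "Stay well."],
     (3, 9, 11), 100.39, 0.0022222222),
    (["Emergency care is available."], (1, 4, 10), -8.725, 15.47),
    (["The copper device works.", "The hormone implant works."],
     (2, 8, 12), 75.875, 3.67),
    (["Schedule your appointment now."], (1, 4, 7), 54.725, 6.62),
    (["Medical insurance questions are common.", "Ask the billing office."],
     (2, 9, 17), 42.4675, 8.4538888889),
]


@pytest.mark.parametrize("sentences, counts, fre, fkgl", READABILITY_CASES)
def test_readability_matches_hand_computation(sentences, counts, fre, fkgl):
    scores = readability(sentences)
    assert (scores.n_sentences, scores.n_words, scores.n_syllables) == counts
    assert scores.fre == pytest.approx(fre, abs=1e-4)
    assert scores.fkgl == pytest.approx(fkgl, abs=1e-4)


def test_readability_higher_fre_means_easier():
    easy = readability(["The cat sat on the mat."])
    hard = readability(["Comprehensive immunological documentation available."])
    assert easy.fre > hard.fre and easy.fkgl < hard.fkgl


def test_readability_empty_content_is_explicit():
    with pytest.raises(EmptyContentError):
        readability([])


# ---------------------------------------------------------------------------
# prevalence / coverage

def test_prevalence_counts_cumulative_frequency():
    topic = TopicSpec("t", ["IUD", "condom", "implant"])
    content = as_content(["An IUD or an IUD works.", "A condom also works."])
    assert prevalence(content, topic) == 3


def test_prevalence_empty_content_zero(larc_topic):
    assert prevalence(as_content([]), larc_topic) == 0


def test_prevalence_counts_overlapping_keywords_independently():
    topic = TopicSpec("t", ["IUD", "copper IUD"])
    content = as_content(["The copper IUD is an option."])
    assert prevalence(content, topic) == 2


@pytest.mark.parametrize(
    "sentences, expected",
    [
        (["IUD, condom and implant."], 100.0),
        ([NEUTRAL], 0.0),
        (["An IUD and a condom."], pytest.approx(66.67, abs=0.005)),
    ],
)
def test_coverage_fraction_of_keywords_found(sentences, expected):
    topic = TopicSpec("t", ["IUD", "condom", "implant"])
    assert coverage(as_content(sentences), topic) == expected


def test_coverage_zero_iff_prevalence_zero(larc_topic):
    content = as_content([NEUTRAL, "Ask about the contraceptive shot."])
    assert (coverage(content, larc_topic) == 0) == \
        (prevalence(content, larc_topic) == 0)


# ---------------------------------------------------------------------------
# sentiment

def test_sentiment_objectivity_complements_subjectivity():
    scores = sentiment(as_content(["The staff is very friendly and helpful."]))
    assert scores.objectivity == pytest.approx(1.0 - scores.subjectivity)
    assert scores.polarity > 0


def test_sentiment_empty_content_convention():
    scores = sentiment(as_content([]))
    assert scores.polarity == 0.0 and scores.subjectivity == 0.0


def test_sentiment_negation_flips_and_attenuates():
    plain = sentiment("The clinic is good.").polarity
    negated = sentiment("The clinic is not good.").polarity
    assert plain > 0 > negated
    assert abs(negated) < abs(plain)


def test_sentiment_intensifier_strengthens():
    assert sentiment("very good").polarity > sentiment("good").polarity


# ---------------------------------------------------------------------------
# navigation

def test_navigation_home_is_target(chain_site):
    backends = fixture_backends(chain_site)
    home = "http://chain.example.edu/"
    result = navigation(home, [home], backends.fetcher)
    assert result.clicks == 0 and result.trace == (home,)


def test_navigation_depth_two(chain_site):
    backends = fixture_backends(chain_site)
    result = navigation(
        "http://chain.example.edu/",
        ["http://chain.example.edu/p2"],
        backends.fetcher,
    )
    assert result.clicks == 2
    assert result.trace == (
        "http://chain.example.edu/",
        "http://chain.example.edu/p1",
        "http://chain.example.edu/p2",
    )
    # consecutive trace pages are linked in the declared graph
    for src, dst in zip(result.trace, result.trace[1:]):
        src_page = chain_site.spec.page(src.replace("http://chain.example.edu", "") or "/")
        assert dst.replace("http://chain.example.edu", "") in src_page.link_paths


def test_navigation_beyond_level_cap_is_sentinel(chain_site):
    backends = fixture_backends(chain_site)
    result = navigation(
        "http://chain.example.edu/",
        ["http://chain.example.edu/p11"],
        backends.fetcher,
        level_cap=10,
    )
    assert result.clicks == -1 and result.trace == ()


def test_navigation_level_cap_boundary_still_examined(chain_site):
    backends = fixture_backends(chain_site)
    result = navigation(
        "http://chain.example.edu/",
        ["http://chain.example.edu/p10"],
        backends.fetcher,
        level_cap=10,
    )
    assert result.clicks == 10


def test_navigation_unfetchable_home_flagged(tmp_path):
    spec = SiteSpec(
        domain="dead.example.edu", home_path="/",
        pages=(PageSpec(path="/", behavior="stall"),),
    )
    backends = fixture_backends(generate_site(spec, tmp_path / "dead"))
    result = navigation(
        "http://dead.example.edu/", ["http://dead.example.edu/x"],
        backends.fetcher,
    )
    assert result.clicks == -1 and result.home_unreachable


def test_navigation_survives_cycles(tmp_path):
    spec = SiteSpec(
        domain="cyc.example.edu", home_path="/",
        pages=(
            PageSpec(path="/", body_sentences=(NEUTRAL,), link_paths=("/a",)),
            PageSpec(path="/a", body_sentences=(NEUTRAL,), link_paths=("/", "/b")),
            PageSpec(path="/b", body_sentences=("IUD facts.",), link_paths=("/a",)),
        ),
    )
    backends = fixture_backends(generate_site(spec, tmp_path / "cyc"))
    result = navigation(
        "http://cyc.example.edu/", ["http://cyc.example.edu/b"],
        backends.fetcher,
    )
    assert result.clicks == 2


def test_navigation_ignores_external_links(tmp_path):
    spec = SiteSpec(
        domain="ext.example.edu", home_path="/",
        pages=(
            PageSpec(path="/", body_sentences=(NEUTRAL,),
                     external_links=("http://other.example.org/hit",)),
        ),
    )
    backends = fixture_backends(generate_site(spec, tmp_path / "ext"))
    result = navigation(
        "http://ext.example.edu/", ["http://other.example.org/hit"],
        backends.fetcher,
    )
    assert result.clicks == -1


# ---------------------------------------------------------------------------
# timeliness

def _page(url, last_modified):
    return FetchedPage(requested_url=url, final_url=url, status="ok",
                       html="<p>x</p>", last_modified=last_modified)


def test_timeliness_parses_http_date():
    out = timeliness([_page("http://s.edu/a", "Wed, 21 Oct 2015 07:28:00 GMT")])
    assert out["http://s.edu/a"] == datetime(2015, 10, 21, 7, 28,
                                             tzinfo=timezone.utc)


def test_timeliness_missing_header_is_sentinel():
    assert timeliness([_page("http://s.edu/a", None)])["http://s.edu/a"] == -1


def test_timeliness_malformed_date_is_sentinel():
    out = timeliness([_page("http://s.edu/a", "sometime last year")])
    assert out["http://s.edu/a"] == -1


# ---------------------------------------------------------------------------
# similarity

def test_similarity_identity_is_one():
    content = as_content(["The IUD is effective."])
    assert similarity(content, content.text) == pytest.approx(1.0)


def test_similarity_disjoint_vocabulary_is_zero():
    assert similarity(as_content(["alpha beta"]), "gamma delta") == 0.0


def test_similarity_term_frequency_cosine_hand_value():
    # tf vectors (2,1) vs (1,2): cos = (2+2) / (sqrt(5)*sqrt(5)) = 0.8
    value = similarity(as_content(["iud iud condom"]), "iud condom condom")
    assert value == pytest.approx(0.8)


def test_similarity_symmetric_and_scale_invariant():
    a, b = "iud implant condom iud", "condom shot iud"
    assert similarity(as_content([a]), b) == pytest.approx(
        similarity(as_content([b]), a)
    )
    assert similarity(as_content([a + " " + a]), b) == pytest.approx(
        similarity(as_content([a]), b)
    )


def test_similarity_empty_content_is_zero():
    assert similarity(as_content([]), "iud condom") == 0.0


def test_similarity_empty_reference_rejected():
    with pytest.raises(EmptyContentError):
        similarity(as_content(["text"]), "")
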