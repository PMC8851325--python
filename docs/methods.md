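# Methods

This note documents the models and procedures behind `shcqual`, the
choices made where the design was genuinely open, and what the synthetic
test surface does and does not establish about live websites.

## Pipeline model and assumptions

The tool models an SHC website as a directed graph of HTML pages under one
host, with health content expressed as plain visible text. Three phases
run per (university, topic) pair.

**Locating.** The SHC home page is resolved by searching
"*name* student health center" and accepting the first of the top three
results whose host is under `.edu`. The `.edu` test is a host-suffix
test (case-insensitive), applied to the raw result URL before any
redirect is followed; a non-`.edu` result that redirects into `.edu` does
not qualify. This deliberately narrows scope to US institutions.
Sanitization follows redirects (hop cap 10, error past it) and then
removes at most one trailing path segment from the configurable strip
list `{contacts, appointments, location}`; removal is exact-match only,
so `/healthcenter` never loses its tail. One-segment-per-pass keeps the
rule predictable; on realistic URLs (no nested strip segments) the
operation is idempotent.

**Gathering.** The topic query is a disjunction of the topic keywords
restricted to the SHC host. When no search backend is configured the
gatherer falls back to a breadth-first crawl of the site (same traversal
engine and level cap as the navigation metric) and treats every reachable
keyword-bearing page as a hit. From each result page, visible text
(scripts, styles, and `nav`/`header`/`footer` boilerplate removed) is
segmented into sentences; every sentence containing a keyword is an
anchor, and a window of 5 sentences on each side is kept, truncated at
page boundaries — windows never span pages, because cross-page adjacency
is a rendering accident, not discourse. Consolidation concatenates pages
in result order and drops duplicate sentences; two sentences are
duplicates when they agree after case-folding, whitespace collapsing, and
terminal-punctuation stripping. This catches boilerplate repeated across
pages without attempting fuzzy matching.

**Keyword matching** is one shared matcher everywhere (anchor detection,
fixture search, prevalence, coverage): case-insensitive whole-token
matching, with multi-word keywords matched as contiguous token phrases
whose parts may be separated by whitespace or hyphens. So `IUD` matches
"iud" but not "liudmila", and "Depo Provera" matches "Depo-Provera".
Overlapping keywords (e.g. `IUD` and `copper IUD`) are counted
independently — prevalence is a cumulative frequency, not a partition.

## The metrics

* **Readability** uses the standard Flesch coefficients
  (FRE = 206.835 − 1.015·W/S − 84.6·Y/W; FKGL = 0.39·W/S + 11.8·Y/W −
  15.59). Words are case-folded alphanumeric tokens (internal apostrophes
  and hyphens kept). Syllables are counted heuristically: maximal vowel
  groups (`aeiouy`) with silent-`e`, consonant-`le`, `-ed`, and `-es`
  corrections; any lettered word counts at least 1, numerals count 1. The
  counter is validated against a hand-checked 50-word lexicon in the test
  suite.
* **Sentiment** is a curated weighted-lexicon scorer. Each lexicon entry
  carries polarity [−1, 1], subjectivity [0, 1], and an intensity used
  when the word acts as an adverbial modifier. Scoring walks the token
  stream: a modifier immediately before a sentiment word merges with it,
  rescaling by its intensity ("very good" is one assessment); a negation
  within two tokens flips and attenuates polarity by −0.5 ("not good" is
  mildly negative); the text score is the unweighted mean of assessments,
  and a text with no lexicon hits scores (0, 0) — so purely factual prose
  is maximally objective by convention. Objectivity is 1 − subjectivity.
* **Navigation** is breadth-first search from the home page over
  within-domain hyperlinks (FIFO queue, links enqueued in document
  order). A node is tested against the target URLs *before* expansion, so
  a keyword-bearing home page scores 0. Nodes at level 10 are still
  examined; popping a level-11 node (or exhausting the queue) returns −1
  with an empty trace, so reported clicks lie in {−1, 0..10}. A visited
  set keyed on normalized URLs (lowercased scheme/host, fragment
  stripped, trailing slash normalized, query kept) prevents exponential
  re-enqueueing on cyclic sites and cannot change the minimum distance,
  since the first BFS visit is along a shortest path. "Within the SHC
  domain" means host equality with the sanitized home URL — the
  strictest testable reading. Target matching uses the same URL normal
  form. An unfetchable home page is reported as −1 with a distinct
  `home_unreachable` flag.
* **Timeliness** parses the HTTP `Last-Modified` header per
  keyword-bearing page with the standard HTTP-date grammar (RFC 5322 via
  `email.utils`), normalized to UTC; missing or unparseable headers
  become the −1 sentinel.
* **Similarity** is the cosine of raw term-frequency vectors over the
  shared word tokenizer (scikit-learn vectorization), no stop-word
  removal, no idf weighting — the minimal deterministic choice, and
  documented as swappable. Empty gathered content scores 0.

Empty gathered content is reported as an explicit `no_content` status
with blank readability/sentiment/similarity cells rather than zeros, so
"nothing found" is never confused with "easy, neutral text".

## Tunable parameters

| Parameter | Default | Why |
|---|---|---|
| per-request timeout | 30 s | generous for slow campus servers; the stall-isolation behavior matters more than the constant |
| retries after timeout | 1 | one transient failure forgiven; a dead site costs at most 2× timeout per page |
| navigation/crawl level cap | 10 levels | past ten clicks content is effectively unreachable for a human user |
| context window | 5 sentences each side | keeps topical discourse while excluding unrelated page content |
| redirect hop cap | 10 hops | loops beyond this are reported as errors, not followed |
| home-URL strip list | `{contacts, appointments, location}` | common utility sub-pages that search engines surface instead of the home page; configurable |

## The synthetic-website generator

`webfixtures.random_site(seed, …)` emulates the structural features the
pipeline depends on: one domain, a seeded random link graph, keyword
sentences injected into a chosen fraction of pages, optional per-page
`Last-Modified` headers (~70% of pages), and page behaviors (stall,
HTTP error, redirect chains). Defaults — 20 pages, link probability 0.15,
keyword page fraction 0.3, 3–8 sentences per page drawn from a neutral
health-sentence bank — were chosen once as a plausible small SHC site:
real SHC sites in the tool's intended population have tens of pages and
sparse internal linking, and topic content typically sits on a minority
of pages. Sentences come from a fixed bank plus keyword templates, so
readability and sentiment on fixtures are deterministic.

The generator does **not** emulate: JavaScript-rendered content, cookies
or authentication, text embedded in images/PDFs, natural prose
variability, or realistic search-engine ranking (the fixture search
backend is an exact manifest scan). Passing tests therefore establish
the correctness of the algorithms — traversal distances against an
independent graph oracle, counts against brute-force scans, invariance
under site restructuring, timeout isolation over a real local HTTP
server — not the empirical behavior of commercial search engines or of
live, messy HTML.

## Numerical and degenerate-input choices

* Readability is undefined on empty text; this raises internally and is
  reported as `no_content`, never as a 0 score.
* Coverage is exact rational arithmetic times 100; ties and rounding only
  appear at CSV serialization (4 decimals for scores, 2 for coverage).
* Navigation ties (equal-length paths) resolve by document order of
  links, which is deterministic for fixed HTML.
* `FixtureHttpServer` binds an ephemeral loopback port; the
  `HostAliasFetcher` keeps canonical `.edu` URLs in all reports while
  routing sockets to the local server, so URL-based rules behave
  identically in disk, HTTP, and live modes.
* CSV output contains no wall-clock values, so reruns on unchanged
  fixtures are bit-identical — the precondition for longitudinal use.

## Known limitations

* Results are only as good as the user-supplied keyword lists; missing
  synonyms depress prevalence/coverage and can bias conclusions.
* The sentiment lexicon is compact and English-only; prose built from
  vocabulary outside it scores (0, 0). US English is assumed throughout
  (tokenizer, syllables, `.edu` rule).
* The syllable heuristic mispronounces some hiatus words ("science",
  "media"-type patterns); the Flesch aggregates tolerate occasional
  one-syllable errors.
* The live search backend implements the Google Custom Search JSON API
  but cannot be exercised offline; all guarantees above are established
  on the fixture backends that share its contract.
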