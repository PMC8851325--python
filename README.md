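# shcqual

Quantitative quality metrics for the health information published on
university **student health center (SHC)** websites.

SHC websites are a primary source of health information for students, yet
no governing body reviews what they publish. Manually auditing hundreds of
sites for readability, completeness, tone, and freshness is slow and
inconsistent. `shcqual` automates the audit: given a list of university
names and one or more health topics (each a set of keywords, e.g. *IUD,
intrauterine device, contraceptive implant* for long-acting reversible
contraception), it

1. **locates** each university's SHC home page — it searches for
   *"&lt;university name&gt; student health center"*, takes the first of the top
   three results hosted under `.edu` (otherwise the SHC is reported as not
   found), follows redirects, and strips utility sub-paths such as
   `/contacts`;
2. **gathers** topic text — a site-restricted disjunctive keyword search
   (or an offline breadth-first crawl) finds keyword-bearing pages; from
   each page it keeps every *anchor sentence* (contains a keyword) plus
   five sentences of context on each side, then consolidates across pages
   and drops duplicate sentences;
3. **scores** the gathered text with eight metrics.

## The metrics

| Metric | Definition |
|---|---|
| Reading ease (FRE) | `206.835 − 1.015·(words/sentences) − 84.6·(syllables/words)`; higher = easier |
| Grade level (FKGL) | `0.39·(words/sentences) + 11.8·(syllables/words) − 15.59`; a US school grade |
| Prevalence | cumulative occurrence count of all topic keywords |
| Coverage | `100 × (distinct keywords found) / (total keywords)`, in [0, 100] |
| Objectivity | `1 − subjectivity` from a curated weighted sentiment lexicon, in [0, 1] |
| Polarity | lexicon sentiment in [−1, 1]; negative = unfavorable framing |
| Navigation | minimum clicks from the SHC home page to the nearest keyword-bearing page, by breadth-first traversal of within-domain links; `−1` if none within 10 levels |
| Timeliness | per-page HTTP `Last-Modified` timestamp; `−1` when the header is absent |
| Similarity | cosine of term-frequency vectors between the gathered text and an expert-written reference document, in [0, 1] (optional) |

Every stage is testable offline: `shcqual.webfixtures` generates
deterministic synthetic SHC-like sites (known link graph, keyword
placements, headers, redirects, stalling pages) that can be served from
disk or over a local HTTP server, with a JSON manifest as ground truth.

## Worked example

Generate a three-university fixture universe and assess it for two topics:

```bash
python examples/build_demo_universe.py demo-universe 1
shcqual --universities examples/universities.csv \
        --topics examples/topics.json \
        --backend fixture --fixture-manifest demo-universe/sites.json \
        --reference-doc LARC=examples/reference_larc.txt \
        --out report.csv
```

This prints `wrote 6 report rows to report.csv`; the first data row is

```text
Alpha State University,LARC,ok,41.5301,9.6643,11,66.67,0.6250,0.2750,0,
http://shc.alpha-state.edu/,5,http://shc.alpha-state.edu/=-1;...,0.5714
```

read as: the gathered LARC text on Alpha State's fixture site has reading
ease 41.5 (FKGL grade 9.7 — fairly dense prose), the topic keywords occur
11 times (prevalence) and 6 of 9 distinct keywords appear (coverage
66.67%), the text is mostly factual (objectivity 0.63) with mildly
positive framing (polarity 0.28), LARC content is reachable in 0 clicks
(it is on the home page), 5 pages carried keywords (one of them without a
`Last-Modified` header, hence the `-1` sentinel), and the text has cosine
similarity 0.57 to the expert reference document. Gamma College's rows
show `no_content` with empty metric cells: its fixture site contains no
topic keywords, and absence is deliberately distinguishable from neutral
text. Live runs work the same way with `--backend live` (Google Custom
Search credentials in `GOOGLE_API_KEY` / `GOOGLE_CSE_ID`).

Per-university network vs compute wall time is logged per phase
(`--log run.jsonl`, summarized with `--timing`).

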