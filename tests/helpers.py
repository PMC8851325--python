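"""Shared fixture-site builders and independent oracles for the tests.

Oracles here deliberately avoid the package's own matching / traversal
code paths: keyword counting is a token-list subsequence scan, and graph
distances come from networkx over the manifest adjacency list.
"""

from __future__ import annotations

import re

import networkx as nx

from shcqual.webfixtures import PageSpec, SiteSpec, link_graph

NEUTRAL = "The clinic is open Monday through Friday from nine to five."


def chain_site_spec(n_pages: int = 12, keyword: str = "IUD",
                    domain: str = "chain.example.edu") -> SiteSpec:
    """home -> p1 -> ... -> p{n-1}, keyword only on the deepest page."""
    pages = []
    for i in range(n_pages):
        path = "/" if i == 0 else f"/p{i}"
        links = (f"/p{i + 1}",) if i < n_pages - 1 else ()
        sentences = [NEUTRAL]
        if i == n_pages - 1:
            sentences.append(f"Ask a nurse about {keyword} at your next visit.")
        pages.append(
            PageSpec(path=path, body_sentences=tuple(sentences), link_paths=links)
        )
    return SiteSpec(domain=domain, home_path="/", pages=tuple(pages))


# ---------------------------------------------------------------------------
# independent keyword-count oracle: token-subsequence scan

_TOKEN = re.compile(r"[a-z0-9]+")


def _toks(text: str) -> list[str]:
    return _TOKEN.findall(text.lower())


def brute_force_count(text: str, keyword: str) -> int:
    """Occurrences of the keyword token sequence in the text token list."""
    hay, needle = _toks(text), _toks(keyword)
    if not needle:
        return 0
    return sum(
        1
        for i in range(len(hay) - len(needle) + 1)
        if hay[i:i + len(needle)] == needle
    )


def brute_force_prevalence(text: str, keywords) -> int:
    return sum(brute_force_count(text, kw) for kw in keywords)


def brute_force_coverage(text: str, keywords) -> float:
    found = sum(1 for kw in keywords if brute_force_count(text, kw) > 0)
    return 100.0 * found / len(keywords)


# ---------------------------------------------------------------------------
# independent navigation oracle: shortest path on the manifest graph


def oracle_min_clicks(spec: SiteSpec, target_paths, level_cap: int = 10) -> int:
    """BFS shortest-path distance from home to the nearest target path,
    computed by networkx on the declared adjacency; -1 beyond the cap."""
    graph = nx.DiGraph()
    graph.add_nodes_from(p.path for p in spec.pages)
    for src, dsts in link_graph(spec).items():
        for dst in dsts:
            graph.add_edge(src, dst)
    lengths = nx.single_source_shortest_path_length(graph, spec.home_path)
    reachable = [lengths[t] for t in target_paths if t in lengths]
    if not reachable:
        return -1
    best = min(reachable)
    return best if best <= level_cap else -1


def keyword_page_paths(spec: SiteSpec, keywords) -> list[str]:
    return [
        p.path
        for p in spec.pages
        if brute_force_prevalence(" ".join(p.body_sentences), keywords) > 0
    ]
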