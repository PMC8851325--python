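"""Shared text primitives.

Every module that looks at text goes through this file, so keyword matching
is guaranteed to behave identically in the gatherer (anchor detection, the
fixture search backend) and in the metrics (prevalence, coverage).

Keyword matching is case-insensitive, whole-token matching on word
boundaries; a multi-word keyword matches as a contiguous token phrase with
flexible whitespace/hyphen separators.  "IUD" therefore matches "IUD" and
"iud" but never the inside of "liudmila"; "Depo Provera" matches
"Depo-Provera".
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Iterable

# --------------------------------------------------------------------------
# word tokenization

_WORD_RE = re.compile(r"[A-Za-z0-9]+(?:['’-][A-Za-z0-9]+)*")


def word_tokens(text: str) -> list[str]:
    """Case-folded word tokens; apostrophes/hyphens kept word-internal."""
    return [m.group(0).lower() for m in _WORD_RE.finditer(text)]


# --------------------------------------------------------------------------
# sentence segmentation

# Common abbreviations that end with a period but do not end a sentence.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "rev", "hon", "st", "jr", "sr",
    "vs", "etc", "approx", "dept", "fig", "no", "inc", "ltd", "co",
    "e.g", "i.e", "u.s", "u.k", "ph.d", "m.d", "a.m", "p.m",
}

_SENT_END_RE = re.compile(r"[.!?]+[\"')\]]*\s+")


def split_sentences(text: str) -> list[str]:
    """Segment visible text into sentences in document order.

    Punctuation-based with an abbreviation list; decimal numbers and
    initials do not break sentences.  Newlines between blocks are treated
    as hard sentence breaks (HTML paragraphs arrive newline-separated).
    """
    sentences: list[str] = []
    for block in re.split(r"\n+", text):
        block = block.strip()
        if not block:
            continue
        start = 0
        for m in _SENT_END_RE.finditer(block):
            candidate = block[start:m.end()].strip()
            prefix = block[start:m.start()]
            last = prefix.rsplit(None, 1)[-1] if prefix.split() else ""
            last = last.lstrip("(\"'[").lower()
            if last.rstrip(".") in _ABBREVIATIONS:
                continue  # abbreviation, keep scanning
            if re.fullmatch(r"\d+", last):
                # "No. 5" / "3." enumerators: only break if next char is upper
                nxt = block[m.end():m.end() + 1]
                if nxt and not nxt.isupper():
                    continue
            if candidate:
                sentences.append(candidate)
            start = m.end()
        tail = block[start:].strip()
        if tail:
            sentences.append(tail)
    return sentences


# --------------------------------------------------------------------------
# sentence normalization (for duplicate filtering)

def normalize_sentence(sentence: str) -> str:
    """Case-fold, collapse internal whitespace, strip terminal punctuation."""
    s = " ".join(sentence.split()).casefold()
    return s.rstrip(".!?;:,… ")


# --------------------------------------------------------------------------
# keyword matching (the single shared matcher)

@lru_cache(maxsize=4096)
def _keyword_regex(keyword: str) -> re.Pattern[str]:
    parts = [re.escape(p) for p in re.split(r"[\s-]+", keyword.strip()) if p]
    body = r"[\s\-]+".join(parts)
    return re.compile(rf"(?<![A-Za-z0-9]){body}(?![A-Za-z0-9])", re.IGNORECASE)


def count_keyword(text: str, keyword: str) -> int:
    """Number of whole-token occurrences of *keyword* in *text*."""
    return sum(1 for _ in _keyword_regex(keyword).finditer(text))


def contains_keyword(text: str, keyword: str) -> bool:
    return _keyword_regex(keyword).search(text) is not None


def contains_any_keyword(text: str, keywords: Iterable[str]) -> bool:
    return any(contains_keyword(text, k) for k in keywords)


def dedupe_keywords(keywords: Iterable[str]) -> list[str]:
    """Collapse duplicates after case-folding, preserving first-seen order."""
    seen: set[str] = set()
    out: list[str] = []
    for k in keywords:
        key = k.strip().casefold()
        if key and key not in seen:
            seen.add(key)
            out.append(k.strip())
    return out
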