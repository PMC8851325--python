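"""HTML parsing: visible-text extraction and in-document hyperlink lists."""

from __future__ import annotations

import logging

import lxml.etree
import lxml.html

from .text import split_sentences
from .urls import absolutize

log = logging.getLogger(__name__)

# Elements whose text is boilerplate or invisible, not page content.
_DROP_TAGS = ("script", "style", "noscript", "template", "nav", "header",
              "footer", "aside", "title")

_SKIP_SCHEMES = ("mailto:", "javascript:", "tel:", "data:")


def _parse(html: str) -> lxml.html.HtmlElement | None:
    if not html or not html.strip():
        return None
    try:
        return lxml.html.fromstring(html)
    except (lxml.etree.ParserError, lxml.etree.XMLSyntaxError, ValueError):
        log.warning("unparseable markup; treating page as empty")
        return None


def visible_text(html: str) -> str:
    """Human-visible text, block elements separated by newlines."""
    root = _parse(html)
    if root is None:
        return ""
    for el in root.iter():
        if isinstance(el.tag, str) and el.tag.lower() in _DROP_TAGS:
            el.drop_tree()
    text = root.text_content()
    lines = [" ".join(ln.split()) for ln in text.splitlines()]
    return "\n".join(ln for ln in lines if ln)


def html_to_sentences(html: str) -> list[str]:
    """Visible text segmented into sentences in document order."""
    return split_sentences(visible_text(html))


def extract_links(html: str, base_url: str) -> list[str]:
    """Absolute hyperlink targets in document order.

    Fragment-only links and non-navigational schemes are skipped;
    duplicates are preserved (the caller's visited set handles them).
    """
    root = _parse(html)
    if root is None:
        return []
    links: list[str] = []
    for a in root.iter("a"):
        href = (a.get("href") or "").strip()
        if not href or href.startswith("#"):
            continue
        if href.lower().startswith(_SKIP_SCHEMES):
            continue
        links.append(absolutize(base_url, href))
    return links
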