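"""Lexicon-based sentiment scoring (polarity and subjectivity).

The scorer walks the token stream and collects an *assessment* for every
token found in the curated lexicon:

* an adverbial modifier immediately before a sentiment word rescales that
  word's polarity and subjectivity by the modifier's intensity
  ("very good" > "good");
* a negation within the two tokens before a sentiment word flips and
  attenuates its polarity by a factor of -0.5 ("not good" is mildly
  negative, not the mirror image of "good");
* all scores are clamped to their ranges.

The text's polarity and subjectivity are the unweighted means of the
assessment polarities and subjectivities; a text with no lexicon hits
scores (0, 0) — the documented convention for empty or purely factual
text.  Objectivity is 1 - subjectivity.
"""

from __future__ import annotations

import re

from ._sentiment_lexicon import LEXICON, MODIFIERS, NEGATIONS
from .types import SentimentScores

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?|n't")

_NEGATION_ATTENUATION = -0.5


def _tokens(text: str) -> list[str]:
    out: list[str] = []
    for tok in _TOKEN_RE.findall(text.lower()):
        if tok.endswith("n't") and tok != "n't":
            out.extend([tok[:-3], "n't"])
        else:
            out.append(tok)
    return out


def _clamp(x: float, lo: float, hi: float) -> float:
    return max(lo, min(hi, x))


def assessments(text: str) -> list[tuple[str, float, float]]:
    """All (word, polarity, subjectivity) assessments in *text*."""
    out: list[tuple[str, float, float]] = []
    modifier: float | None = None  # intensity of a directly preceding modifier
    negated = 0  # countdown of tokens over which a negation still applies
    for tok in _tokens(text):
        entry = LEXICON.get(tok)
        if entry is not None:
            p, s, intensity = entry
            if negated:
                p = _clamp(p * _NEGATION_ATTENUATION, -1.0, 1.0)
            if modifier is not None and out:
                # fold the modified word into the modifier's assessment
                p = _clamp(p * modifier, -1.0, 1.0)
                s = _clamp(s * modifier, 0.0, 1.0)
                out[-1] = (f"{out[-1][0]} {tok}", p, s)
            else:
                out.append((tok, p, s))
            is_modifier = tok in MODIFIERS or tok.endswith("ly")
            modifier = intensity if is_modifier else None
            negated = 0
        elif tok in NEGATIONS:
            negated = 3
            modifier = None
        else:
            modifier = None
            if negated:
                negated -= 1
    return out


def score_text(text: str) -> SentimentScores:
    """Polarity in [-1, 1] and subjectivity in [0, 1] for *text*."""
    found = assessments(text)
    if not found:
        return SentimentScores(polarity=0.0, subjectivity=0.0)
    polarity = sum(p for _, p, _ in found) / len(found)
    subjectivity = sum(s for _, _, s in found) / len(found)
    return SentimentScores(
        polarity=_clamp(polarity, -1.0, 1.0),
        subjectivity=_clamp(subjectivity, 0.0, 1.0),
    )
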