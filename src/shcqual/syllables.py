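"""Heuristic English syllable counting for the Flesch–Kincaid metrics.

Algorithm: count maximal vowel groups (a, e, i, o, u, y), then apply three
orthographic corrections —

* a final silent "e" is discounted ("nurse", "device"), except in "-ee"
  ("agree") and in consonant+"le", which is syllabic ("table", "available");
* a final "-ed" is silent after most consonants ("asked") but syllabic
  after t/d ("wanted", "needed");
* a final "-es" is silent after most consonants ("makes") but syllabic
  after sibilants and soft consonants ("boxes", "churches", "ages").

Any word containing a letter counts at least one syllable; purely numeric
tokens count one.  The counter is deterministic and is validated against a
hand-checked 50-word lexicon in the test suite.
"""

import re

_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")
_NON_ALPHA_RE = re.compile(r"[^a-z]")


def count_syllables(word: str) -> int:
    w = _NON_ALPHA_RE.sub("", word.lower())
    if not w:
        return 1 if any(ch.isdigit() for ch in word) else 0
    groups = len(_VOWEL_GROUP_RE.findall(w))
    if groups == 0:
        return 1
    if w.endswith("e") and not w.endswith("ee"):
        if not (w.endswith("le") and len(w) > 2 and w[-3] not in "aeiouy"):
            groups -= 1
    elif w.endswith("ed") and len(w) > 3 and w[-3] not in "aeiouytd":
        groups -= 1
    elif w.endswith("es") and len(w) > 3 and w[-3] not in "aeiouysxzhg":
        groups -= 1
    return max(1, groups)
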