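"""Curated sentiment lexicon: word -> (polarity, subjectivity, intensity).

Polarity is in [-1, 1], subjectivity in [0, 1].  Intensity is the
multiplier a word applies to the word it modifies when it acts as an
adverbial intensifier ("very good"); non-modifying words carry 1.0.

The entries are hand-assigned in the style of weighted sentiment lexicons:
evaluative adjectives/adverbs dominate, factual vocabulary is absent, and
hedging/limiting adverbs ("only") carry zero polarity but high
subjectivity.  Coverage favours the vocabulary of consumer health pages.
"""

LEXICON: dict[str, tuple[float, float, float]] = {
    # strong positive
    "best": (1.0, 0.3, 1.0),
    "excellent": (1.0, 1.0, 1.0),
    "outstanding": (0.9, 0.9, 1.0),
    "perfect": (1.0, 1.0, 1.0),
    "wonderful": (1.0, 1.0, 1.0),
    "amazing": (0.6, 0.9, 1.0),
    "exceptional": (0.8, 0.9, 1.0),
    "superb": (0.9, 0.9, 1.0),
    "fantastic": (0.9, 0.9, 1.0),
    "great": (0.8, 0.75, 1.0),
    "terrific": (0.8, 0.9, 1.0),
    "ideal": (0.8, 0.8, 1.0),
    # moderate positive
    "good": (0.7, 0.6, 1.0),
    "better": (0.5, 0.5, 1.0),
    "nice": (0.6, 1.0, 1.0),
    "helpful": (0.5, 0.5, 1.0),
    "friendly": (0.5, 0.6, 1.0),
    "caring": (0.5, 0.6, 1.0),
    "compassionate": (0.5, 0.7, 1.0),
    "supportive": (0.5, 0.5, 1.0),
    "effective": (0.5, 0.6, 1.0),
    "beneficial": (0.5, 0.6, 1.0),
    "safe": (0.5, 0.5, 1.0),
    "healthy": (0.5, 0.5, 1.0),
    "clean": (0.4, 0.4, 1.0),
    "comfortable": (0.5, 0.6, 1.0),
    "convenient": (0.4, 0.5, 1.0),
    "affordable": (0.4, 0.5, 1.0),
    "reliable": (0.5, 0.5, 1.0),
    "trusted": (0.5, 0.5, 1.0),
    "professional": (0.3, 0.4, 1.0),
    "qualified": (0.3, 0.4, 1.0),
    "experienced": (0.4, 0.5, 1.0),
    "welcoming": (0.5, 0.6, 1.0),
    "welcome": (0.5, 0.6, 1.0),
    "confidential": (0.2, 0.3, 1.0),
    "accessible": (0.3, 0.4, 1.0),
    "available": (0.4, 0.5, 1.0),
    "free": (0.4, 0.7, 1.0),
    "easy": (0.4, 0.8, 1.0),
    "simple": (0.3, 0.4, 1.0),
    "quick": (0.3, 0.5, 1.0),
    "fast": (0.2, 0.4, 1.0),
    "prompt": (0.3, 0.4, 1.0),
    "gentle": (0.4, 0.6, 1.0),
    "happy": (0.8, 1.0, 1.0),
    "glad": (0.5, 1.0, 1.0),
    "proud": (0.5, 0.8, 1.0),
    "positive": (0.2, 0.6, 1.0),
    "important": (0.4, 0.7, 1.0),
    "essential": (0.4, 0.6, 1.0),
    "valuable": (0.4, 0.6, 1.0),
    "recommended": (0.3, 0.4, 1.0),
    "successful": (0.5, 0.6, 1.0),
    "improved": (0.4, 0.5, 1.0),
    "modern": (0.2, 0.4, 1.0),
    "new": (0.1, 0.4, 1.0),
    "fresh": (0.3, 0.5, 1.0),
    "right": (0.3, 0.5, 1.0),
    "fine": (0.4, 0.5, 1.0),
    "well": (0.3, 0.4, 1.0),
    "love": (0.5, 0.6, 1.0),
    "like": (0.2, 0.3, 1.0),
    "enjoy": (0.5, 0.6, 1.0),
    "thorough": (0.3, 0.4, 1.0),
    "courteous": (0.4, 0.5, 1.0),
    "respectful": (0.4, 0.5, 1.0),
    "prepared": (0.3, 0.4, 1.0),
    "secure": (0.4, 0.5, 1.0),
    "strong": (0.4, 0.5, 1.0),
    "robust": (0.3, 0.4, 1.0),
    "timely": (0.3, 0.4, 1.0),
    # strong negative
    "worst": (-1.0, 1.0, 1.0),
    "terrible": (-1.0, 1.0, 1.0),
    "horrible": (-1.0, 1.0, 1.0),
    "awful": (-1.0, 1.0, 1.0),
    "atrocious": (-0.39, 0.75, 1.0),
    "dreadful": (-0.9, 0.9, 1.0),
    "appalling": (-0.9, 0.9, 1.0),
    "disgusting": (-0.9, 1.0, 1.0),
    "unacceptable": (-0.8, 0.8, 1.0),
    "dangerous": (-0.6, 0.7, 1.0),
    "harmful": (-0.6, 0.6, 1.0),
    "toxic": (-0.6, 0.6, 1.0),
    "fatal": (-0.7, 0.6, 1.0),
    "deadly": (-0.7, 0.6, 1.0),
    "severe": (-0.5, 0.6, 1.0),
    "serious": (-0.3, 0.5, 1.0),
    "critical": (-0.3, 0.6, 1.0),
    # moderate negative
    "bad": (-0.7, 0.67, 1.0),
    "poor": (-0.4, 0.6, 1.0),
    "worse": (-0.5, 0.6, 1.0),
    "sad": (-0.5, 1.0, 1.0),
    "unfortunate": (-0.5, 0.7, 1.0),
    "painful": (-0.6, 0.7, 1.0),
    "sick": (-0.5, 0.7, 1.0),
    "ill": (-0.4, 0.6, 1.0),
    "unwell": (-0.4, 0.6, 1.0),
    "weak": (-0.3, 0.5, 1.0),
    "dirty": (-0.6, 0.8, 1.0),
    "unsafe": (-0.5, 0.5, 1.0),
    "risky": (-0.4, 0.6, 1.0),
    "difficult": (-0.3, 0.6, 1.0),
    "hard": (-0.3, 0.4, 1.0),
    "slow": (-0.3, 0.4, 1.0),
    "late": (-0.3, 0.6, 1.0),
    "expensive": (-0.3, 0.6, 1.0),
    "costly": (-0.3, 0.5, 1.0),
    "rude": (-0.6, 0.9, 1.0),
    "unhelpful": (-0.4, 0.5, 1.0),
    "unprofessional": (-0.5, 0.6, 1.0),
    "unreliable": (-0.4, 0.5, 1.0),
    "confusing": (-0.3, 0.6, 1.0),
    "complicated": (-0.3, 0.5, 1.0),
    "outdated": (-0.3, 0.4, 1.0),
    "broken": (-0.4, 0.4, 1.0),
    "wrong": (-0.5, 0.5, 1.0),
    "negative": (-0.3, 0.6, 1.0),
    "fail": (-0.5, 0.5, 1.0),
    "failed": (-0.5, 0.5, 1.0),
    "problem": (-0.3, 0.4, 1.0),
    "pain": (-0.4, 0.5, 1.0),
    "worried": (-0.3, 0.6, 1.0),
    "afraid": (-0.4, 0.7, 1.0),
    "scary": (-0.5, 0.9, 1.0),
    "uncomfortable": (-0.4, 0.6, 1.0),
    "inconvenient": (-0.3, 0.5, 1.0),
    "limited": (-0.2, 0.4, 1.0),
    "hurt": (-0.4, 0.5, 1.0),
    # hedges / limiters: zero polarity, subjective framing
    "only": (0.0, 1.0, 1.0),
    "just": (0.0, 0.5, 1.0),
    "some": (0.0, 0.5, 1.0),
    "several": (0.0, 0.3, 1.0),
    "many": (0.2, 0.4, 1.0),
    "few": (-0.1, 0.3, 1.0),
    "certain": (0.2, 0.6, 1.0),
    "likely": (0.0, 0.6, 1.0),
    "possible": (0.0, 0.6, 1.0),
    "able": (0.3, 0.5, 1.0),
    "common": (-0.1, 0.4, 1.0),
    "general": (0.0, 0.3, 1.0),
    "normal": (0.1, 0.4, 1.0),
    "usual": (0.0, 0.3, 1.0),
    "typical": (0.0, 0.4, 1.0),
    "other": (-0.1, 0.3, 1.0),
    "different": (0.0, 0.5, 1.0),
    "same": (0.0, 0.1, 1.0),
    "first": (0.2, 0.3, 1.0),
    "last": (0.0, 0.1, 1.0),
    "full": (0.3, 0.4, 1.0),
    "open": (0.1, 0.4, 1.0),
    "early": (0.1, 0.3, 1.0),
    "long": (-0.05, 0.4, 1.0),
    "short": (0.0, 0.4, 1.0),
    "high": (0.1, 0.4, 1.0),
    "low": (0.0, 0.3, 1.0),
    "small": (-0.1, 0.4, 1.0),
    "large": (0.1, 0.4, 1.0),
    "much": (0.2, 0.2, 1.0),
    "more": (0.3, 0.3, 1.2),
    "most": (0.3, 0.4, 1.3),
    "less": (-0.2, 0.3, 0.8),
    "least": (-0.3, 0.4, 0.8),
    # adverbial intensifiers (intensity != 1 applies to the next word)
    "very": (0.2, 0.3, 1.3),
    "really": (0.2, 0.2, 1.3),
    "extremely": (-0.25, 1.0, 1.5),
    "highly": (0.3, 0.6, 1.4),
    "quite": (0.0, 0.5, 1.2),
    "rather": (-0.1, 0.5, 1.1),
    "fairly": (0.3, 0.6, 1.1),
    "truly": (0.4, 0.6, 1.3),
    "absolutely": (0.2, 0.6, 1.4),
    "completely": (0.1, 0.3, 1.3),
    "totally": (0.1, 0.3, 1.3),
    "especially": (0.2, 0.5, 1.3),
    "particularly": (0.1, 0.5, 1.2),
    "slightly": (0.0, 0.4, 0.8),
    "somewhat": (0.0, 0.4, 0.9),
    "barely": (-0.2, 0.4, 0.7),
    "hardly": (-0.2, 0.4, 0.7),
    "nearly": (0.0, 0.3, 0.9),
    "almost": (0.0, 0.3, 0.9),
}

# Words that invert/attenuate the next sentiment-bearing word.
NEGATIONS: frozenset[str] = frozenset(
    {"not", "no", "never", "n't", "none", "neither", "nor", "cannot", "dont",
     "don't", "doesn't", "isn't", "wasn't", "won't", "can't", "couldn't",
     "shouldn't", "wouldn't"}
)

# Non-"-ly" words that can act as intensifying modifiers of the next word.
MODIFIERS: frozenset[str] = frozenset(
    {"very", "quite", "rather", "more", "most", "less", "least"}
)
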