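"""Vocabulary for the synthetic post generator.

Three token pools: a neutral base vocabulary sampled with a Zipfian profile,
a distress lexicon whose usage rate rises with latent suicidality, and a
positive/religious lexicon whose rate falls with it.  The distress pool mixes
a core of real words (the kinds of negatively charged, swearing, distress and
physical-complaint words that separate at-risk users' language) with
deterministically generated morphological variants, so that the pool is large
enough for document-frequency contrasts to be measurable in class-level
TF-IDF.  Everything here is deterministic module-level data.
"""

from __future__ import annotations

import itertools

# ~180 common English function/content words; Zipf-weighted neutral base.
COMMON_WORDS: tuple[str, ...] = (
    "the", "i", "to", "and", "a", "of", "my", "in", "is", "it", "you",
    "for", "that", "me", "on", "this", "with", "so", "was", "at", "be",
    "have", "just", "we", "all", "but", "out", "up", "day", "not", "are",
    "get", "like", "go", "now", "today", "time", "what", "got", "good",
    "going", "new", "one", "work", "back", "home", "see", "know", "about",
    "some", "night", "come", "been", "when", "they", "there", "how", "if",
    "will", "can", "your", "had", "from", "who", "here", "week", "our",
    "them", "then", "him", "her", "she", "he", "really", "still", "much",
    "need", "want", "think", "right", "make", "off", "little", "over",
    "after", "morning", "people", "year", "thing", "way", "last", "first",
    "down", "house", "car", "dog", "cat", "kids", "school", "game", "watch",
    "movie", "show", "music", "song", "play", "food", "dinner", "lunch",
    "coffee", "weekend", "summer", "winter", "rain", "sun", "snow", "cold",
    "hot", "big", "old", "long", "next", "best", "better", "man", "guy",
    "girl", "boy", "baby", "again", "always", "never", "every", "anyone",
    "something", "nothing", "everything", "tonight", "tomorrow", "yesterday",
    "soon", "later", "maybe", "sure", "well", "yes", "no", "okay", "done",
    "ready", "finally", "almost", "around", "away", "into", "than", "because",
    "before", "while", "where", "why", "take", "made", "look", "looking",
    "found", "find", "give", "keep", "let", "put", "say", "said", "tell",
    "told", "ask", "call", "called", "try", "trying", "start", "started",
)

# Distress stems; suffixed variants are generated below.
_NEG_STEMS: tuple[str, ...] = (
    "bad", "worst", "bitch", "fucking", "mad", "cry", "hurt", "sad",
    "sick", "pain", "surgery", "hospital", "awful", "terrible", "hate",
    "angry", "lonely", "tired", "broken", "scared", "stress", "depress",
    "anxious", "miserable", "worthless", "hopeless", "ache", "sore",
    "exhausted", "fail", "ruin", "scream", "suffer", "numb", "empty",
    "dark", "lost", "alone", "panic", "shaking",
)

_NEG_SUFFIXES: tuple[str, ...] = (
    "", "s", "ed", "ing", "er", "ly", "ness", "ful",
)

# Positive / belonging / religious lexicon (usage falls with suicidality).
POSITIVE_WORDS: tuple[str, ...] = (
    "great", "happy", "perfect", "loving", "love", "peace", "wedding",
    "thanksgiving", "together", "friends", "mother", "wife", "blessed",
    "gift", "wishes", "christ", "church", "god", "faith", "grateful",
    "thankful", "joy", "beautiful", "wonderful", "celebrate", "family",
    "prayer", "blessing", "hope", "smile", "sunshine", "proud", "amazing",
    "holiday", "birthday", "vacation", "laugh", "fun", "awesome", "sweet",
)

# Explicit suicide-related lemmas with their fixed morphological variants;
# used both by the idiom templates below and by the keyword search default.
KEYWORD_VARIANTS: dict[str, tuple[str, ...]] = {
    "suicide": ("suicide", "suicidal", "suicides"),
    "kill": ("kill", "kills", "killed", "killing"),
    "die": ("die", "dies", "died", "dying"),
}

# Idiomatic, non-suicidal usages of the explicit lemmas, inserted at a low
# class-independent rate: in the source cohort such words almost never
# appeared in genuinely suicide-related messages.
IDIOM_TEMPLATES: tuple[str, ...] = (
    "my back is killing me",
    "cramps so bad i want to die",
    "this traffic is killing me",
    "i nearly died laughing at that",
    "my phone battery just died again",
    "dying to see the new movie this weekend",
    "these shoes are killing my feet",
)


def negative_words() -> tuple[str, ...]:
    """Distress pool: stems plus generated morphological variants (~320)."""
    out: list[str] = []
    for stem, suf in itertools.product(_NEG_STEMS, _NEG_SUFFIXES):
        out.append(stem + suf)
    return tuple(dict.fromkeys(out))


def neutral_words(n_extra: int = 600) -> tuple[str, ...]:
    """Common words plus a deterministic pseudo-word tail ("topic" words),
    giving the Zipf tail enough distinct types for document-frequency
    variation."""
    syll_a = ("ba", "re", "mo", "ta", "li", "so", "ne", "ka", "du", "pe",
              "vi", "ro", "sa", "te", "lo", "mi", "na", "ko", "fa", "ze")
    syll_b = ("ron", "mel", "tis", "dor", "lan", "vek", "sim", "pol", "nar",
              "ket", "bus", "mir", "tal", "zen", "gor", "lin", "dap", "fen",
              "rok", "sul", "ven", "tam", "pir", "nol", "gat", "lem", "dov",
              "fur", "rin", "sev")
    extra = [a + b for a, b in itertools.product(syll_a, syll_b)][:n_extra]
    return COMMON_WORDS + tuple(extra)
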