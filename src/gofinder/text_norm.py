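"""Shared text normalization.

Every piece of text that enters the semantic space — ontology concept
documents, sentences, abstracts — goes through the same pipeline:
lowercase tokenization on non-alphanumeric boundaries, stop-word removal,
and Porter stemming.  Gene symbols are *generalized* separately (letters
only, lowercased), which deliberately strips the digits that the tokenizer
keeps: "p38" tokenizes to ``p38`` but generalizes to ``p``.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from typing import Iterable, List, Sequence, Set

__all__ = [
    "tokenize",
    "remove_stopwords",
    "stem",
    "normalize_text",
    "generalize_symbol",
    "load_stoplist",
    "default_stoplist",
]

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")
_NON_ALPHA = re.compile(r"[^A-Za-z]+")


def tokenize(text: str) -> List[str]:
    """Lowercase *text* and split on maximal runs of non-alphanumerics.

    Empty tokens are dropped; an empty input yields an empty list.
    """
    return [t for t in _TOKEN_SPLIT.split(text.lower()) if t]


def remove_stopwords(tokens: Sequence[str], stoplist: Set[str]) -> List[str]:
    """Order-preserving filter removing tokens found in *stoplist*."""
    return [t for t in tokens if t not in stoplist]


def normalize_text(text: str, stoplist: Set[str]) -> List[str]:
    """Tokenize, remove stop words, Porter-stem. The single shared path."""
    return [stem(t) for t in remove_stopwords(tokenize(text), stoplist)]


def generalize_symbol(symbol: str) -> str:
    """Generalize a gene symbol: drop everything but letters, lowercase.

    ``"ASK1" -> "ask"``, ``"MAP2K4" -> "mapk"``, ``"p38" -> "p"``.
    An all-non-letter symbol generalizes to the empty string.
    """
    return _NON_ALPHA.sub("", symbol).lower()


def load_stoplist(path: str) -> Set[str]:
    """Read a stop-word file: one lowercase word per line, '#' comments."""
    words: Set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            word = line.split("#", 1)[0].strip().lower()
            if word:
                words.add(word)
    return words


@lru_cache(maxsize=1)
def default_stoplist() -> Set[str]:
    """The packaged standard English stop-word list."""
    text = resources.files("gofinder.data").joinpath("stopwords.txt").read_text("utf-8")
    words = set()
    for line in text.splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.add(word)
    return frozenset(words)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Porter stemmer — the original 1980 algorithm.
#
# Implemented from the algorithm definition: a word is [C](VC)^m[V]; each
# step strips the longest matching suffix whose condition on the remaining
# stem holds.  'y' counts as a vowel when preceded by a consonant.
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem_: str) -> int:
    """m in the [C](VC)^m[V] decomposition of *stem_*."""
    m = 0
    prev_vowel = False
    for i in range(len(stem_)):
        if _is_consonant(stem_, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _contains_vowel(stem_: str) -> bool:
    return any(not _is_consonant(stem_, i) for i in range(len(stem_)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # *o condition: stem ends consonant-vowel-consonant, final not w/x/y.
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            return w[:-1]
        return w
    stripped = None
    if w.endswith("ed") and _contains_vowel(w[:-2]):
        stripped = w[:-2]
    elif w.endswith("ing") and _contains_vowel(w[:-3]):
        stripped = w[:-3]
    if stripped is None:
        return w
    w = stripped
    if w.endswith(("at", "bl", "iz")):
        return w + "e"
    if _ends_double_consonant(w) and w[-1] not in "lsz":
        return w[:-1]
    if _measure(w) == 1 and _ends_cvc(w):
        return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _contains_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


# (suffix, replacement) pairs; within a step the longest matching suffix
# is the one applied (checked via ordering by length).
_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]
_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _apply_rules(w: str, rules, min_measure: int) -> str:
    for suffix, repl in sorted(rules, key=lambda r: -len(r[0])):
        if w.endswith(suffix):
            stem_ = w[: -len(suffix)]
            if _measure(stem_) > min_measure:
                return stem_ + repl
            return w
    return w


def _step4(w: str) -> str:
    for suffix in sorted(_STEP4, key=len, reverse=True):
        if w.endswith(suffix):
            stem_ = w[: -len(suffix)]
            if suffix == "ion" and not stem_.endswith(("s", "t")):
                continue
            if _measure(stem_) > 1:
                return stem_
            return w
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _ends_cvc(w[:-1])):
            w = w[:-1]
    if w.endswith("ll") and _measure(w) > 1:
        w = w[:-1]
    return w


@lru_cache(maxsize=65536)
def stem(token: str) -> str:
    """Porter (1980) stem of a lowercase *token*. Deterministic and pure."""
    if len(token) <= 2:
        return token
    w = _step1a(token)
    w = _step1b(w)
    w = _step1c(w)
    w = _apply_rules(w, _STEP2, 0)
    w = _apply_rules(w, _STEP3, 0)
    w = _step4(w)
    w = _step5(w)
    return w
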