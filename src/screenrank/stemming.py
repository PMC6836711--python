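"""Porter (1980) English suffix-stripping stemmer.

Conflates inflectional and some derivational variants ("outcomes",
"outcome" → "outcom") so that n-gram features generalize across surface
forms.  This is the classic five-step algorithm over the consonant/vowel
measure m of a stem ([C](VC)^m[V]); words of length <= 2 are returned
unchanged.  Stemming is applied token-wise after lower-casing.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in [C](VC)^m[V]."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if prev_vowel:
                m += 1
            prev_vowel = False
        else:
            prev_vowel = True
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant where the final consonant is not w, x or y
    return (
        len(word) >= 3
        and _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace(word: str, suffix: str, new: str, min_measure: int) -> str | None:
    """If word ends with suffix and the stem's measure exceeds the bound, swap."""
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > min_measure:
        return stem + new
    return word  # suffix matched but condition failed: the step still ends


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
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
    if _ends_double_consonant(w) and not w.endswith(("l", "s", "z")):
        return w[:-1]
    if _measure(w) == 1 and _ends_cvc(w):
        return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _contains_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        m = _measure(w[:-1])
        if m > 1 or (m == 1 and not _ends_cvc(w[:-1])):
            w = w[:-1]
    if _ends_double_consonant(w) and w.endswith("l") and _measure(w[:-1]) > 1:
        w = w[:-1]
    return w


@lru_cache(maxsize=1 << 18)
def stem_token(token: str) -> str:
    """Stem one lower-cased token."""
    w = token
    if len(w) <= 2:
        return w
    w = _step1a(w)
    w = _step1b(w)
    w = _step1c(w)
    for suffix, new in _STEP2:
        out = _replace(w, suffix, new, 0)
        if out is not None:
            w = out
            break
    for suffix, new in _STEP3:
        out = _replace(w, suffix, new, 0)
        if out is not None:
            w = out
            break
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if suffix == "ion":
                if stem.endswith(("s", "t")) and _measure(stem) > 1:
                    w = stem
            elif _measure(stem) > 1:
                w = stem
            break
    return _step5(w)


def stem_tokens(tokens: Sequence[str]) -> list[str]:
    """Stem a token sequence element-wise (length preserved)."""
    return [stem_token(t) for t in tokens]


__all__ = ["stem_token", "stem_tokens"]
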