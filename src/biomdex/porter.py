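"""Porter stemming algorithm.

Rule-based suffix stripping for English, used to normalise metadata word
forms before indexing ("Antibiotics", "antibiotic" -> "antibiot") so that a
single index key retrieves every sample annotated with any inflection of a
word.  This follows the author's canonical revision of the 1980 algorithm,
i.e. the behaviour of the widely distributed implementations, which differs
from the journal text in two amendments to step 2 ("bli" -> "ble" replacing
"abli" -> "able", and the added "logi" -> "log" rule).

Stemming is purely mechanical: stems are not guaranteed to be dictionary
words ("poni" for "ponies"), only to be stable across inflections.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in ``stem``: [C](VC)^m[V]."""
    m = 0
    i = 0
    n = len(stem)
    while i < n and _is_consonant(stem, i):
        i += 1
    while i < n:
        while i < n and not _is_consonant(stem, i):
            i += 1
        if i < n:
            m += 1
        while i < n and _is_consonant(stem, i):
            i += 1
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
    # *o condition: final consonant-vowel-consonant, last not w, x or y.
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
    flag = False
    if w.endswith("ed") and _contains_vowel(w[:-2]):
        w = w[:-2]
        flag = True
    elif w.endswith("ing") and _contains_vowel(w[:-3]):
        w = w[:-3]
        flag = True
    if flag:
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


# (suffix, replacement) tried longest-match-wins within each step.
_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("bli", "ble"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    ("logi", "log"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _longest_rule(w, rules):
    best = None
    for suffix, repl in rules:
        if w.endswith(suffix) and (best is None or len(suffix) > len(best[0])):
            best = (suffix, repl)
    return best


def _step2(w: str) -> str:
    hit = _longest_rule(w, _STEP2)
    if hit is not None:
        suffix, repl = hit
        stem = w[: len(w) - len(suffix)]
        if _measure(stem) > 0:
            return stem + repl
    return w


def _step3(w: str) -> str:
    hit = _longest_rule(w, _STEP3)
    if hit is not None:
        suffix, repl = hit
        stem = w[: len(w) - len(suffix)]
        if _measure(stem) > 0:
            return stem + repl
    return w


def _step4(w: str) -> str:
    hit = _longest_rule(w, [(s, "") for s in _STEP4])
    if hit is not None:
        suffix, _ = hit
        stem = w[: len(w) - len(suffix)]
        if _measure(stem) > 1:
            if suffix == "ion" and (not stem or stem[-1] not in "st"):
                return w
            return stem
    return w


def _step5a(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return w


def _step5b(w: str) -> str:
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        return w[:-1]
    return w


def stem(word: str) -> str:
    """Return the Porter stem of ``word``.

    The input is lowercased first; words of length <= 2 are returned
    unchanged (after lowercasing), matching the canonical implementation.
    """
    w = word.lower()
    if len(w) <= 2:
        return w
    for step in (_step1a, _step1b, _step1c, _step2, _step3, _step4,
                 _step5a, _step5b):
        w = step(w)
    return w
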