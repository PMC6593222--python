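"""Independently coded Porter-stemmer reference for cross-validation.

A synthetic stand-in for an external reference stemmer: written from the
published algorithm in a deliberately different style (declarative rule
tables over a consonant/vowel form string, where the production code is
procedural), so that agreement between the two is evidence both transcribe
the algorithm correctly rather than sharing a bug by construction.
Implements the author's canonical revision (the same two step-2 amendments
the production code documents).
"""

from __future__ import annotations


def _cv_form(word: str) -> str:
    """Translate to a 'c'/'v' string; y is a vowel after a consonant."""
    form = []
    for i, ch in enumerate(word):
        if ch in "aeiou":
            form.append("v")
        elif ch == "y" and i > 0 and form[i - 1] == "c":
            form.append("v")
        else:
            form.append("c")
    return "".join(form)


def _measure(stem: str) -> int:
    form = _cv_form(stem)
    collapsed = []
    for ch in form:
        if not collapsed or collapsed[-1] != ch:
            collapsed.append(ch)
    return "".join(collapsed).count("vc")


def _has_vowel(stem: str) -> bool:
    return "v" in _cv_form(stem)


def _double_consonant(word: str) -> bool:
    return (len(word) >= 2 and word[-1] == word[-2]
            and _cv_form(word)[-1] == "c")


def _cvc(word: str) -> bool:
    form = _cv_form(word)
    return (len(word) >= 3 and form[-3:] == "cvc"
            and word[-1] not in "wxy")


def _apply_table(word, rules):
    """First matching suffix wins; rule = (suffix, repl, condition)."""
    for suffix, repl, condition in rules:
        if word.endswith(suffix):
            stem = word[:len(word) - len(suffix)]
            if condition is None or condition(stem):
                return stem + repl
            return word
    return word


_m_gt_0 = lambda s: _measure(s) > 0          # noqa: E731
_m_gt_1 = lambda s: _measure(s) > 1          # noqa: E731

_STEP2_RULES = [
    (a, b, _m_gt_0) for a, b in [
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
        ("anci", "ance"), ("izer", "ize"), ("bli", "ble"), ("alli", "al"),
        ("entli", "ent"), ("ousli", "ous"), ("eli", "e"),
        ("ization", "ize"), ("ation", "ate"), ("ator", "ate"),
        ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"),
        ("biliti", "ble"), ("logi", "log"),
    ]
]
_STEP2_RULES.sort(key=lambda r: -len(r[0]))

_STEP3_RULES = sorted(
    [(a, b, _m_gt_0) for a, b in [
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    ]],
    key=lambda r: -len(r[0]))

_STEP4_RULES = sorted(
    [("ion", "", lambda s: _measure(s) > 1 and s[-1:] in ("s", "t"))]
    + [(suf, "", _m_gt_1) for suf in [
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    ]],
    key=lambda r: -len(r[0]))


def _step1(word: str) -> str:
    word = _apply_table(word, [
        ("sses", "ss", None), ("ies", "i", None),
        ("ss", "ss", None), ("s", "", None),
    ])
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            word = word[:-1]
    else:
        trimmed = None
        if word.endswith("ed") and _has_vowel(word[:-2]):
            trimmed = word[:-2]
        elif word.endswith("ing") and _has_vowel(word[:-3]):
            trimmed = word[:-3]
        if trimmed is not None:
            if trimmed.endswith(("at", "bl", "iz")):
                word = trimmed + "e"
            elif (_double_consonant(trimmed)
                    and trimmed[-1] not in ("l", "s", "z")):
                word = trimmed[:-1]
            elif _measure(trimmed) == 1 and _cvc(trimmed):
                word = trimmed + "e"
            else:
                word = trimmed
    if word.endswith("y") and _has_vowel(word[:-1]):
        word = word[:-1] + "i"
    return word


def _step5(word: str) -> str:
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            word = stem
    if word.endswith("ll") and _measure(word) > 1:
        word = word[:-1]
    return word


def reference_stem(word: str) -> str:
    w = word.lower()
    if len(w) <= 2:
        return w
    w = _step1(w)
    w = _apply_table(w, _STEP2_RULES)
    w = _apply_table(w, _STEP3_RULES)
    w = _apply_table(w, _STEP4_RULES)
    return _step5(w)
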