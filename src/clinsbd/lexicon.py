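"""Word-list lexicons: the abbreviation-free medical dictionary (MDDict) and
the closed-class dictionary (CCDict).

MDDict plays two roles: exact lookups (is ``L_norm`` a full dictionary word,
hence probably not an abbreviation?) and prefix-match counting (ad-hoc
abbreviations are truncations, i.e. prefixes, of dictionary entries).
CCDict holds non-capitalized German function words whose capitalization
reliably signals a sentence start.
"""

from __future__ import annotations

import bisect
import warnings
from typing import Iterable, Sequence

__all__ = ["Lexicon", "build_mddict", "build_ccdict", "read_word_list"]


def _fold(word: str) -> str:
    # first character case-sensitive (German nouns are capitalized, and
    # truncations preserve the initial capital), the rest case-folded
    return word[:1] + word[1:].lower() if word else word


class Lexicon:
    """A word set with exact membership and indexed prefix-count queries."""

    def __init__(self, entries: Iterable[str] = (), role: str = "MDDict"):
        self.role = role
        self.entries: set[str] = {e for e in entries if e}
        self._lower = {e.lower() for e in self.entries}
        # sorted fold-keys back an O(log n) prefix count
        self._folded = sorted(_fold(e) for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def contains(self, word: str, case_insensitive: bool = False) -> bool:
        if case_insensitive:
            return word.lower() in self._lower
        return word in self.entries

    def prefix_count(self, prefix: str) -> int:
        """Number of entries having ``prefix`` as a prefix (exact matches
        included); case-sensitive on the first character only."""
        if not prefix:
            return 0
        key = _fold(prefix)
        lo = bisect.bisect_left(self._folded, key)
        hi = bisect.bisect_left(self._folded, key + "￿")
        return hi - lo

    def substring_match_count(self, l_norm_with_period: str) -> int:
        """Sum of prefix matches over the period-separated subwords of
        ``L_norm.`` = ``subword_1.subword_2...subword_n.``.

        Motivated by ad-hoc abbreviations being proper substrings (here:
        prefixes) of the shortened original word, e.g. "exulz." of
        "exulzerierend".  Empty subwords contribute 0.
        """
        return sum(
            self.prefix_count(sub) for sub in l_norm_with_period.split(".") if sub
        )


def build_mddict(
    word_sources: Iterable[Iterable[str]],
    abbreviation_lists: Iterable[Iterable[str]] = (),
) -> Lexicon:
    """Union the word sources into an abbreviation-free dictionary.

    Tokens ending with a period are discarded outright; every abbreviation,
    after stripping terminal periods, is removed from the result, so that no
    MDDict entry equals a known abbreviation's period-free form.
    """
    words: set[str] = set()
    for src in word_sources:
        for w in src:
            w = w.strip()
            if w and not w.endswith("."):
                words.add(w)
    stripped = set()
    for lst in abbreviation_lists:
        for a in lst:
            a = a.strip().rstrip(".")
            if a:
                stripped.add(a)
    words -= stripped
    if not words:
        warnings.warn("build_mddict produced an empty lexicon", stacklevel=2)
    return Lexicon(words, role="MDDict")


def build_ccdict(closed_class_words: Iterable[str]) -> Lexicon:
    return Lexicon((w.strip() for w in closed_class_words if w.strip()), role="CCDict")


def read_word_list(path) -> list[str]:
    """One word per line, UTF-8; '#' starts a comment, blank lines ignored."""
    words = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                words.append(line)
    return words
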