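"""Synthetic clinical-narrative corpus generator.

Real dermatology discharge summaries cannot be redistributed, so this
module fabricates German-looking telegram-style text that reproduces the
statistical structure the period-disambiguation classifiers rely on:

* lexicalized abbreviations that always end in a period ("St.p.", "ca."),
* ad-hoc abbreviations formed by truncating a long dictionary word
  ("Tumordurchm." from "Tumordurchmesser"),
* ordinals ("3.") and dates ("3.5.2014"),
* acronyms, ICD-style codes ("(C43.5)") and decimal numbers ("2,42"),
* capitalized sentence starts, with double-newline paragraph breaks and
  single-newline contamination inside sentences,
* double-role periods where an abbreviation also ends the sentence.

Gold labels are assigned while the text is being built, never re-derived
from the finished string by rules, so the generator and the site extractor
cannot share a bug silently.  All randomness flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .lexicon import Lexicon, build_ccdict, build_mddict
from .text import PeriodSite

__all__ = [
    "GeneratorConfig",
    "DEFAULT_ABBREV_INVENTORY",
    "CLOSED_CLASS_WORDS",
    "generate_lexicons",
    "generate_corpus",
]

# lexicalized short forms with Zipf-ish sampling weights; all end in "."
DEFAULT_ABBREV_INVENTORY: Tuple[Tuple[str, float], ...] = (
    ("St.p.", 10), ("ca.", 9), ("Pat.", 8), ("o.B.", 7), ("Z.n.", 6),
    ("li.", 6), ("re.", 6), ("bds.", 5), ("max.", 4), ("bzw.", 4),
    ("Amb.", 3), ("unauff.", 3), ("sek.", 3), ("Lab.", 2), ("inkl.", 2),
    ("evtl.", 2), ("ggf.", 2), ("n.", 1), ("etc.", 1),
)

CLOSED_CLASS_WORDS: Tuple[str, ...] = (
    "der", "die", "das", "den", "dem", "des", "ein", "eine", "einer",
    "eines", "einem", "und", "oder", "aber", "ist", "sind", "war", "waren",
    "wird", "wurde", "wurden", "werden", "kann", "können", "muss", "soll",
    "hat", "haben", "hatte", "bei", "mit", "ohne", "nach", "vor", "unter",
    "über", "durch", "für", "von", "zu", "zum", "zur", "im", "am", "an",
    "auf", "in", "als", "wie", "kein", "keine", "sich", "es", "er", "sie",
    "wir", "auch", "noch", "nicht", "sowie", "bis",
)

_NOUN_STEMS = (
    "Tumor", "Melanom", "Haut", "Zell", "Gewebe", "Knoten", "Leber",
    "Lymph", "Befund", "Exzision", "Narbe", "Pigment", "Basal", "Spindel",
    "Lungen", "Rippen", "Nieren", "Milz", "Magen", "Darm", "Wund", "Rand",
    "Schnitt", "Operations", "Therapie", "Kontroll", "Verlaufs", "Regionen",
    "Struktur", "Sono", "Histo", "Diagnose", "Infiltrat", "Epithel",
    "Drüsen", "Gefäß", "Muskel", "Knochen", "Integument", "Leisten",
)

_NOUN_SUFFIXES = (
    "durchmesser", "resektion", "veränderung", "entfernung", "untersuchung",
    "beurteilung", "erkrankung", "behandlung", "kontrolle", "befundung",
    "gewebe", "region", "struktur", "zeichnung", "bildung", "anteile",
    "ränder", "knoten", "exzision", "biopsie",
)

_ADJ_STEMS = (
    "exulzerierend", "knotig", "superfiziell", "pigmentiert", "unauffällig",
    "regelrecht", "vergrößert", "chronisch", "akut", "maligne", "benigne",
    "narbig", "entzündlich", "oberflächlich", "verschieblich", "sekundär",
    "spreitend", "druckdolent", "reizlos", "randständig",
)

_ADJ_ENDINGS = ("", "e", "es", "er", "en")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic corpus.

    Per-slot probabilities decide what fills each mid-sentence token slot;
    their sum must not exceed 1, the remainder being ordinary words.
    ``double_role_rate`` is the probability that a sentence ends with an
    abbreviation instead of a period-terminated full word.
    """

    n_sentences: int = 1500
    abbrev_inventory: Tuple[Tuple[str, float], ...] = DEFAULT_ABBREV_INVENTORY
    p_abbrev: float = 0.10
    p_adhoc: float = 0.05
    p_ordinal: float = 0.04
    p_acronym: float = 0.04
    newline_rate: float = 0.15
    paragraph_rate: float = 0.30
    double_role_rate: float = 0.10
    min_words: int = 5
    max_words: int = 11
    context_len: int = 60
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_abbrev": self.p_abbrev,
            "p_adhoc": self.p_adhoc,
            "p_ordinal": self.p_ordinal,
            "p_acronym": self.p_acronym,
            "newline_rate": self.newline_rate,
            "paragraph_rate": self.paragraph_rate,
            "double_role_rate": self.double_role_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        slot_sum = self.p_abbrev + self.p_adhoc + self.p_ordinal + self.p_acronym
        if slot_sum > 1.0:
            raise ValueError(f"per-slot probabilities sum to {slot_sum} > 1")
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be positive")
        if not 2 <= self.min_words <= self.max_words:
            raise ValueError("need 2 <= min_words <= max_words")


def generate_lexicons(
    seed: int = 0,
    abbrev_inventory: Sequence[Tuple[str, float]] = DEFAULT_ABBREV_INVENTORY,
) -> Tuple[Lexicon, Lexicon]:
    """Build a synthetic MDDict/CCDict pair.

    MDDict entries are German-like single-word compounds (stem + suffix) and
    inflected adjectives, so that ad-hoc truncations are proper prefixes of
    dictionary entries; known abbreviations are stripped of their periods and
    removed, keeping the dictionary abbreviation-free.  The construction is
    deterministic; ``seed`` is accepted for interface symmetry with
    :func:`generate_corpus`.
    """
    nouns = set(_NOUN_STEMS)
    for stem in _NOUN_STEMS:
        for suf in _NOUN_SUFFIXES:
            nouns.add(stem + suf)
    adjectives = {stem + end for stem in _ADJ_STEMS for end in _ADJ_ENDINGS}
    mddict = build_mddict(
        [nouns, adjectives], [[form for form, _ in abbrev_inventory]]
    )
    ccdict = build_ccdict(CLOSED_CLASS_WORDS)
    return mddict, ccdict


def _word_pools(mddict: Lexicon):
    nouns = sorted(e for e in mddict.entries if e[:1].isupper())
    adjectives = sorted(e for e in mddict.entries if e[:1].islower())
    return nouns, adjectives


def _pick(rng: np.random.Generator, pool: Sequence[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _adhoc_truncation(rng, mddict: Lexicon, long_words: Sequence[str]) -> str:
    """Truncate a long dictionary word to a prefix that is not itself a
    dictionary entry, and append a period."""
    for _ in range(20):
        word = _pick(rng, long_words)
        cut = int(rng.integers(4, min(8, len(word) - 1)))
        prefix = word[:cut]
        if not mddict.contains(prefix, case_insensitive=True):
            return prefix + "."
    return word[:4] + "."  # pragma: no cover - practically unreachable


def _acronym_like(rng) -> str:
    kind = rng.random()
    if kind < 0.6:  # acronym: no terminal period, never a site
        letters = "ABCDEFGHIKLMNOPRSTUVWZ"
        k = int(rng.integers(2, 5))
        return "".join(letters[int(rng.integers(len(letters)))] for _ in range(k))
    if kind < 0.8:  # ICD-style code in parentheses; period is token internal
        return f"(C{int(rng.integers(10, 99))}.{int(rng.integers(0, 10))})"
    # decimal number with comma separator (German)
    return f"{int(rng.integers(1, 20))},{int(rng.integers(10, 100))}"


def generate_corpus(
    cfg: GeneratorConfig,
    mddict: Optional[Lexicon] = None,
    ccdict: Optional[Lexicon] = None,
) -> Tuple[str, list[PeriodSite]]:
    """Generate a labeled corpus under ``cfg``.

    Returns the raw text (newlines included) and one gold
    :class:`PeriodSite` per planted terminal-period token, with
    ``is_abbrev``/``is_sentence_end`` labels and contexts filled in.
    """
    cfg.validate()
    if mddict is None or ccdict is None:
        mddict, ccdict = generate_lexicons(cfg.seed, cfg.abbrev_inventory)
    rng = np.random.default_rng(cfg.seed)
    nouns, adjectives = _word_pools(mddict)
    cc_words = sorted(ccdict.entries)
    long_words = [w for w in nouns + adjectives if len(w) >= 9]
    forms = [f for f, _ in cfg.abbrev_inventory]
    weights = np.array([w for _, w in cfg.abbrev_inventory], dtype=float)
    weights = weights / weights.sum() if len(weights) else weights

    def lexicalized() -> str:
        return forms[int(rng.choice(len(forms), p=weights))]

    # plan the token stream; gold = (token_index, is_abbrev, is_sentence_end)
    tokens: list[str] = []
    seps: list[str] = []  # separator *after* each token
    gold_plan: list[tuple[int, bool, bool]] = []

    for _ in range(cfg.n_sentences):
        n_slots = int(rng.integers(cfg.min_words, cfg.max_words + 1))
        sent_start = len(tokens)
        # capitalized sentence start: function word or noun
        if rng.random() < 0.5:
            starter = _pick(rng, cc_words).capitalize()
        else:
            starter = _pick(rng, nouns)
        tokens.append(starter)
        seps.append(" ")
        for _ in range(n_slots - 2):
            u = rng.random()
            if u < cfg.p_abbrev and forms:
                tokens.append(lexicalized())
                gold_plan.append((len(tokens) - 1, True, False))
            elif u < cfg.p_abbrev + cfg.p_adhoc:
                tokens.append(_adhoc_truncation(rng, mddict, long_words))
                gold_plan.append((len(tokens) - 1, True, False))
            elif u < cfg.p_abbrev + cfg.p_adhoc + cfg.p_ordinal:
                if rng.random() < 0.5:  # ordinal: a site and an abbreviation
                    tokens.append(f"{int(rng.integers(1, 32))}.")
                    gold_plan.append((len(tokens) - 1, True, False))
                else:  # full date: token-internal periods only
                    tokens.append(
                        f"{int(rng.integers(1, 29))}."
                        f"{int(rng.integers(1, 13))}."
                        f"{int(rng.integers(2007, 2015))}"
                    )
            elif u < cfg.p_abbrev + cfg.p_adhoc + cfg.p_ordinal + cfg.p_acronym:
                tokens.append(_acronym_like(rng))
            else:
                v = rng.random()
                if v < 0.4:
                    tokens.append(_pick(rng, nouns))
                elif v < 0.7:
                    tokens.append(_pick(rng, adjectives))
                else:
                    tokens.append(_pick(rng, cc_words))
            seps.append(" ")
        # final token: double-role abbreviation or period-terminated word
        if forms and cfg.p_abbrev > 0 and rng.random() < cfg.double_role_rate:
            tokens.append(lexicalized())
            gold_plan.append((len(tokens) - 1, True, True))
        else:
            pool = nouns if rng.random() < 0.6 else adjectives
            tokens.append(_pick(rng, pool) + ".")
            gold_plan.append((len(tokens) - 1, False, True))
        seps.append("\n\n" if rng.random() < cfg.paragraph_rate else " ")
        # single-newline contamination inside the sentence
        if cfg.newline_rate > 0 and rng.random() < cfg.newline_rate:
            n_gaps = len(tokens) - 1 - sent_start
            if n_gaps > 0:
                gap = sent_start + int(rng.integers(n_gaps))
                seps[gap] = "\n"

    # assemble text and char offsets
    starts = np.empty(len(tokens), dtype=int)
    pieces = []
    pos = 0
    for i, (tok, sep) in enumerate(zip(tokens, seps)):
        starts[i] = pos
        pieces.append(tok)
        pos += len(tok)
        if i < len(tokens) - 1:
            pieces.append(sep)
            pos += len(sep)
    text = "".join(pieces)

    sites: list[PeriodSite] = []
    for idx, is_abbrev, is_sent in gold_plan:
        tok = tokens[idx]
        ppos = int(starts[idx]) + len(tok) - 1
        nxt = tokens[idx + 1] if idx + 1 < len(tokens) else ""
        nl = seps[idx].count("\n") if idx < len(tokens) - 1 else 0
        sites.append(
            PeriodSite(
                left_token=tok,
                right_token=nxt,
                left_context=text[max(0, ppos - cfg.context_len) : ppos],
                right_context=text[ppos + 1 : ppos + 1 + cfg.context_len],
                delimiter_newline_count=nl,
                is_abbrev=bool(is_abbrev),
                is_sentence_end=bool(is_sent),
                position=ppos,
            )
        )
    return text, sites
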