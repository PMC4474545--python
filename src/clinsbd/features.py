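"""Feature assembly for the two period-disambiguation tasks.

Abbreviation detection draws on six switchable feature sets computed on the
normalized left token ``L_norm``::

    rules        3   internal period / contains digit / all upper case
    statistical  5   the four contingency counts and loglambda
    scaling      63  all non-empty compositions of S1..S6
    dictionary   1   L_norm (period-free) found in MDDict
    length       8   length, borders b1..b3, above-border flags, mu - length
    wordtype     |V| one-hot of the digit-masked L_norm

Sentence-boundary detection uses seven sets, largely mirror images computed
on the right token ``R`` / ``R_norm``, plus the prediction of a trained
abbreviation model::

    language     2   capitalized closed-class R_norm / R_norm in MDDict
    rules        4   period in R, digit, all upper, capitalization of R_norm
    textformat   3   no / single / double newline before R (one-hot)
    length       8   as above, on R_norm
    rc_wordtype  |V| one-hot of the digit-masked R_norm
    wordtype     |V| one-hot of the digit-masked L_norm
    abbreviation 1   abbreviation-model prediction on the identical site

Word-type vocabularies are frozen on the training sites; unseen types at
prediction time yield an all-zero block.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .lexicon import Lexicon
from .stats import (
    CountTable,
    LengthStats,
    abbreviation_length_stats,
    combo_name,
    log_lambda,
    scaled_feature,
    scaling_combos,
    word_length,
)
from .text import PeriodSite, normalize_left, normalize_right

__all__ = [
    "ABBREV_SETS",
    "SENTENCE_SETS",
    "mask_digits",
    "word_type",
    "contains_digit",
    "all_upper",
    "is_capitalized",
    "AbbreviationFeaturizer",
    "SentenceFeaturizer",
    "abbrev_features",
    "sentence_features",
]

# stepwise evaluation order of the feature sets
ABBREV_SETS = ("rules", "statistical", "scaling", "dictionary", "length", "wordtype")
SENTENCE_SETS = (
    "language",
    "rules",
    "textformat",
    "length",
    "rc_wordtype",
    "wordtype",
    "abbreviation",
)

_DIGIT_RUN = re.compile(r"\d+")


def mask_digits(s: str) -> str:
    """Collapse each maximal run of digits to 'd' ("C43.5" -> "Cd.d")."""
    return _DIGIT_RUN.sub("d", s)


def word_type(token_norm: str) -> str:
    return mask_digits(token_norm)


def contains_digit(s: str) -> bool:
    return any(c.isdigit() for c in s)


def all_upper(s: str) -> bool:
    """True for words consisting of uppercase letters only ("TE"); strings
    with digits or punctuation ("C43.5") and pure digit strings are not."""
    return bool(s) and all(c.isalpha() and c.isupper() for c in s)


def is_capitalized(s: str) -> bool:
    return bool(s) and s[:1].isupper()


def _length_block(token: str, stats: LengthStats) -> list[float]:
    lt = float(word_length(token))
    return [
        lt,
        stats.b1,
        stats.b2,
        stats.b3,
        float(lt > stats.b1),
        float(lt > stats.b2),
        float(lt > stats.b3),
        stats.mu - lt,
    ]


def _length_names(suffix: str = "") -> list[str]:
    return [
        f"LT{suffix}",
        f"LT_border_b1{suffix}",
        f"LT_border_b2{suffix}",
        f"LT_border_b3{suffix}",
        f"gt_b1{suffix}",
        f"gt_b2{suffix}",
        f"gt_b3{suffix}",
        f"Mean_minus_LT{suffix}",
    ]


def _validate_sets(sets, allowed, kind):
    bad = [s for s in sets if s not in allowed]
    if bad:
        raise ValueError(f"unknown {kind} feature set(s) {bad}; allowed: {allowed}")
    if not sets:
        raise ValueError(f"at least one {kind} feature set must be enabled")
    # keep canonical order regardless of how the caller listed them
    return tuple(s for s in allowed if s in sets)


class AbbreviationFeaturizer(TransformerMixin, BaseEstimator):
    """Turn period sites into the abbreviation-detection feature matrix.

    Parameters
    ----------
    feature_sets : subset of :data:`ABBREV_SETS`
    mddict : medical-domain lexicon (needed by 'dictionary' and the S6
        scaling function)
    count_table : corpus collocation counts (needed by 'statistical',
        'scaling' and 'length')
    alpha : significance level of the length-statistic type filter
    """

    def __init__(
        self,
        feature_sets: Sequence[str] = ABBREV_SETS,
        mddict: Optional[Lexicon] = None,
        count_table: Optional[CountTable] = None,
        alpha: float = 0.01,
    ):
        self.feature_sets = feature_sets
        self.mddict = mddict
        self.count_table = count_table
        self.alpha = alpha

    def _check_resources(self, sets):
        needs_table = {"statistical", "scaling", "length"} & set(sets)
        if needs_table and (self.count_table is None or self.count_table.total == 0):
            raise ValueError(
                f"feature sets {sorted(needs_table)} need a non-empty count_table"
            )
        needs_dict = {"dictionary", "scaling"} & set(sets)
        if needs_dict and self.mddict is None:
            raise ValueError(f"feature sets {sorted(needs_dict)} need mddict")

    def fit(self, sites: Sequence[PeriodSite], y=None):
        sets = _validate_sets(self.feature_sets, ABBREV_SETS, "abbreviation")
        self._check_resources(sets)
        self.sets_ = sets
        if {"length"} & set(sets):
            self.length_stats_ = abbreviation_length_stats(self.count_table, self.alpha)
        else:
            self.length_stats_ = None
        if "wordtype" in sets:
            self.vocab_ = sorted(
                {word_type(normalize_left(s.left_token)) for s in sites}
            )
            self._vocab_index = {t: i for i, t in enumerate(self.vocab_)}
        else:
            self.vocab_ = []
            self._vocab_index = {}
        self._combos = scaling_combos()
        names: list[str] = []
        for name in sets:
            if name == "rules":
                names += ["Contains_period_inside", "Contains_digit", "All_upper"]
            elif name == "statistical":
                names += ["C_L_dot", "C_notL_dot", "C_L_nodot", "C_notL_nodot", "loglambda"]
            elif name == "scaling":
                names += [combo_name(c) for c in self._combos]
            elif name == "dictionary":
                names += ["in_MDDict"]
            elif name == "length":
                names += _length_names()
            elif name == "wordtype":
                names += [f"WT={t}" for t in self.vocab_]
        self.feature_names_ = names
        return self

    def transform(self, sites: Sequence[PeriodSite]) -> np.ndarray:
        if not hasattr(self, "sets_"):
            raise RuntimeError("featurizer is not fitted")
        X = np.zeros((len(sites), len(self.feature_names_)), dtype=float)
        for i, site in enumerate(sites):
            l_full = normalize_left(site.left_token)  # keeps terminal period
            l_stripped = l_full.rstrip(".")
            col = 0
            for name in self.sets_:
                if name == "rules":
                    X[i, col] = float("." in l_stripped)
                    X[i, col + 1] = float(contains_digit(l_stripped))
                    X[i, col + 2] = float(all_upper(l_stripped))
                    col += 3
                elif name == "statistical":
                    t = self.count_table.contingency(l_stripped)
                    X[i, col] = t.c_l_dot
                    X[i, col + 1] = t.c_notl_dot
                    X[i, col + 2] = t.c_l_nodot
                    X[i, col + 3] = t.c_notl_nodot
                    X[i, col + 4] = log_lambda(t)
                    col += 5
                elif name == "scaling":
                    t = self.count_table.contingency(l_stripped)
                    ll = log_lambda(t)
                    for j, combo in enumerate(self._combos):
                        X[i, col + j] = scaled_feature(
                            combo, ll, l_stripped, t, self.mddict
                        )
                    col += len(self._combos)
                elif name == "dictionary":
                    X[i, col] = float(
                        self.mddict.contains(l_stripped, case_insensitive=True)
                    )
                    col += 1
                elif name == "length":
                    X[i, col : col + 8] = _length_block(l_stripped, self.length_stats_)
                    col += 8
                elif name == "wordtype":
                    j = self._vocab_index.get(word_type(l_full))
                    if j is not None:
                        X[i, col + j] = 1.0
                    col += len(self.vocab_)
        return X


class SentenceFeaturizer(TransformerMixin, BaseEstimator):
    """Turn period sites into the sentence-detection feature matrix.

    ``abbrev_model`` must be a fitted abbreviation classifier exposing
    ``predict(sites)`` when the 'abbreviation' set is enabled.  The
    closed-class feature fires when R_norm is capitalized *and* its
    lowercase form is a closed-class word (a capitalized function word is a
    strong sentence-start cue in German); set ``ccdict_plain_membership``
    for plain, capitalization-free membership instead.
    """

    def __init__(
        self,
        feature_sets: Sequence[str] = SENTENCE_SETS,
        mddict: Optional[Lexicon] = None,
        ccdict: Optional[Lexicon] = None,
        count_table: Optional[CountTable] = None,
        abbrev_model=None,
        alpha: float = 0.01,
        ccdict_plain_membership: bool = False,
    ):
        self.feature_sets = feature_sets
        self.mddict = mddict
        self.ccdict = ccdict
        self.count_table = count_table
        self.abbrev_model = abbrev_model
        self.alpha = alpha
        self.ccdict_plain_membership = ccdict_plain_membership

    def fit(self, sites: Sequence[PeriodSite], y=None):
        sets = _validate_sets(self.feature_sets, SENTENCE_SETS, "sentence")
        if "language" in sets and (self.mddict is None or self.ccdict is None):
            raise ValueError("the 'language' set needs both mddict and ccdict")
        if "length" in sets and (self.count_table is None or self.count_table.total == 0):
            raise ValueError("the 'length' set needs a non-empty count_table")
        if "abbreviation" in sets and self.abbrev_model is None:
            raise ValueError("the 'abbreviation' set needs a fitted abbrev_model")
        self.sets_ = sets
        if "length" in sets:
            self.length_stats_ = abbreviation_length_stats(self.count_table, self.alpha)
        else:
            self.length_stats_ = None
        self.l_vocab_, self.r_vocab_ = [], []
        if "wordtype" in sets:
            self.l_vocab_ = sorted(
                {word_type(normalize_left(s.left_token)) for s in sites}
            )
        if "rc_wordtype" in sets:
            self.r_vocab_ = sorted(
                {word_type(normalize_right(s.right_token)) for s in sites}
            )
        self._l_index = {t: i for i, t in enumerate(self.l_vocab_)}
        self._r_index = {t: i for i, t in enumerate(self.r_vocab_)}
        names: list[str] = []
        for name in sets:
            if name == "language":
                names += ["in_CCDict", "in_MDDict_R"]
            elif name == "rules":
                names += [
                    "Contains_period_R",
                    "Contains_digit_R",
                    "All_upper_R",
                    "Capitalization",
                ]
            elif name == "textformat":
                names += ["No_newline", "Single_newline", "Double_newline"]
            elif name == "length":
                names += _length_names("_R")
            elif name == "rc_wordtype":
                names += [f"RC={t}" for t in self.r_vocab_]
            elif name == "wordtype":
                names += [f"WT={t}" for t in self.l_vocab_]
            elif name == "abbreviation":
                names += ["Abbreviation"]
        self.feature_names_ = names
        return self

    def transform(self, sites: Sequence[PeriodSite]) -> np.ndarray:
        if not hasattr(self, "sets_"):
            raise RuntimeError("featurizer is not fitted")
        X = np.zeros((len(sites), len(self.feature_names_)), dtype=float)
        abbrev_pred = None
        if "abbreviation" in self.sets_:
            abbrev_pred = np.asarray(self.abbrev_model.predict(sites), dtype=float)
        for i, site in enumerate(sites):
            r_norm = normalize_right(site.right_token)
            col = 0
            for name in self.sets_:
                if name == "language":
                    if self.ccdict_plain_membership:
                        cc = self.ccdict.contains(r_norm, case_insensitive=True)
                    else:
                        cc = is_capitalized(r_norm) and self.ccdict.contains(
                            r_norm.lower()
                        )
                    X[i, col] = float(cc)
                    X[i, col + 1] = float(
                        self.mddict.contains(r_norm, case_insensitive=True)
                    )
                    col += 2
                elif name == "rules":
                    X[i, col] = float("." in site.right_token)
                    X[i, col + 1] = float(contains_digit(r_norm))
                    X[i, col + 2] = float(all_upper(r_norm))
                    X[i, col + 3] = float(is_capitalized(r_norm))
                    col += 4
                elif name == "textformat":
                    nl = site.delimiter_newline_count
                    X[i, col] = float(nl == 0)
                    X[i, col + 1] = float(nl == 1)
                    X[i, col + 2] = float(nl >= 2)
                    col += 3
                elif name == "length":
                    X[i, col : col + 8] = _length_block(r_norm, self.length_stats_)
                    col += 8
                elif name == "rc_wordtype":
                    j = self._r_index.get(word_type(r_norm))
                    if j is not None:
                        X[i, col + j] = 1.0
                    col += len(self.r_vocab_)
                elif name == "wordtype":
                    j = self._l_index.get(word_type(normalize_left(site.left_token)))
                    if j is not None:
                        X[i, col + j] = 1.0
                    col += len(self.l_vocab_)
                elif name == "abbreviation":
                    X[i, col] = abbrev_pred[i]
                    col += 1
        return X


def abbrev_features(site, count_table, mddict, feature_sets=ABBREV_SETS, alpha=0.01):
    """Feature vector of one site as an ordered name -> value mapping.

    Thin single-site wrapper over :class:`AbbreviationFeaturizer`; the
    word-type vocabulary is frozen on the one given site.
    """
    fz = AbbreviationFeaturizer(
        feature_sets=feature_sets, mddict=mddict, count_table=count_table, alpha=alpha
    ).fit([site])
    row = fz.transform([site])[0]
    return dict(zip(fz.feature_names_, row))


def sentence_features(
    site,
    count_table,
    mddict,
    ccdict,
    abbrev_model=None,
    feature_sets=SENTENCE_SETS,
    alpha=0.01,
):
    """Single-site wrapper over :class:`SentenceFeaturizer`."""
    fz = SentenceFeaturizer(
        feature_sets=feature_sets,
        mddict=mddict,
        ccdict=ccdict,
        count_table=count_table,
        abbrev_model=abbrev_model,
        alpha=alpha,
    ).fit([site])
    row = fz.transform([site])[0]
    return dict(zip(fz.feature_names_, row))
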