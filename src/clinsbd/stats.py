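"""Corpus collocation statistics for abbreviation evidence.

Centre piece is Dunning's log-likelihood ratio ``loglambda`` measuring the
association between a word type and a following period, computed from the
2x2 contingency table

    =====  ============   =============
            L_norm         not L_norm
    =====  ============   =============
    .       C(L, .)        C(~L, .)
    ~.      C(L, ~.)       C(~L, ~.)
    =====  ============   =============

plus six scaling functions S1..S6 that sharpen the raw statistic with
period-collocation ratios, word length, internal periods and dictionary
prefix matches.  All 63 non-empty subsets of {S1..S6}, applied in ascending
order, form one feature each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import chi2

from .lexicon import Lexicon
from .text import Token, normalize_left

__all__ = [
    "Contingency",
    "CountTable",
    "LengthStats",
    "count_collocations",
    "log_lambda",
    "word_length",
    "scaling_factor",
    "scaled_feature",
    "scaling_combos",
    "combo_name",
    "abbreviation_length_stats",
]

# z quantiles for the right-tailed borders b1 < b2 < b3
_BORDER_Z = (1.645, 1.960, 2.576)

# exponent clamp keeping S1 finite for extreme period/no-period ratios
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class Contingency:
    """Counts C(L,.), C(L,~.), C(~L,.), C(~L,~.) for one word type."""

    c_l_dot: float
    c_l_nodot: float
    c_notl_dot: float
    c_notl_nodot: float

    @property
    def total(self) -> float:
        return self.c_l_dot + self.c_l_nodot + self.c_notl_dot + self.c_notl_nodot


class CountTable:
    """Per-type counts of period-final vs. period-free occurrences.

    The type key is the normalized left token with its terminal period
    stripped, so "ca." and "ca" fall onto the same type.
    """

    def __init__(self) -> None:
        self.counts: dict[str, list[int]] = {}  # type -> [c_dot, c_nodot]
        self.total_dot = 0
        self.total_nodot = 0

    @property
    def total(self) -> int:
        return self.total_dot + self.total_nodot

    def add(self, type_key: str, with_period: bool, n: int = 1) -> None:
        if not type_key:
            return
        cell = self.counts.setdefault(type_key, [0, 0])
        if with_period:
            cell[0] += n
            self.total_dot += n
        else:
            cell[1] += n
            self.total_nodot += n

    def c_dot(self, type_key: str) -> int:
        return self.counts.get(type_key, (0, 0))[0]

    def c_nodot(self, type_key: str) -> int:
        return self.counts.get(type_key, (0, 0))[1]

    def contingency(self, type_key: str) -> Contingency:
        c_dot, c_nodot = self.counts.get(type_key, (0, 0))
        return Contingency(
            c_l_dot=c_dot,
            c_l_nodot=c_nodot,
            c_notl_dot=self.total_dot - c_dot,
            c_notl_nodot=self.total_nodot - c_nodot,
        )

    def to_rows(self) -> list[tuple[str, int, int]]:
        return [(t, c[0], c[1]) for t, c in sorted(self.counts.items())]

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("type\tc_dot\tc_nodot\n")
            for t, a, b in self.to_rows():
                fh.write(f"{t}\t{a}\t{b}\n")

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, int, int]]) -> "CountTable":
        table = cls()
        for t, a, b in rows:
            table.add(t, True, int(a))
            table.add(t, False, int(b))
        return table


@dataclass(frozen=True)
class LengthStats:
    """Mean/SD of abbreviation lengths (non-period characters) and the three
    right-tailed borders b1 = mu + 1.645 sigma, b2 = mu + 1.960 sigma,
    b3 = mu + 2.576 sigma."""

    mu: float
    sigma: float

    @property
    def b1(self) -> float:
        return self.mu + _BORDER_Z[0] * self.sigma

    @property
    def b2(self) -> float:
        return self.mu + _BORDER_Z[1] * self.sigma

    @property
    def b3(self) -> float:
        return self.mu + _BORDER_Z[2] * self.sigma

    def to_dict(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma}


def count_collocations(tokens: Sequence[Token]) -> CountTable:
    """Build the frequency count map over a tokenized corpus.

    Each token contributes once, under its normalized type key, to
    C(type, .) if its surface ends with a period, else to C(type, ~.).
    Tokens whose normalization is empty (pure punctuation) are skipped.
    """
    table = CountTable()
    for tok in tokens:
        with_period = tok.surface.endswith(".")
        key = normalize_left(tok.surface).rstrip(".")
        table.add(key, with_period)
    return table


def log_lambda(t: Contingency) -> float:
    """Dunning's likelihood-ratio statistic -2 log(L(H0)/L(HA)) for the
    2x2 table, H0 being "a period is independent of the preceding word".

    Equals the G statistic and is computed in its entropy form,
    ``2 * sum O_ij ln(O_ij / E_ij)`` with expected counts from the table
    margins and the 0 * log 0 = 0 convention; always >= 0, and 0 exactly
    when the two rows have identical period proportions.
    """
    if t.total <= 0:
        raise ValueError("log_lambda requires a non-empty contingency table")
    obs = (
        (t.c_l_dot, t.c_l_nodot),
        (t.c_notl_dot, t.c_notl_nodot),
    )
    row = tuple(sum(r) for r in obs)
    col = tuple(sum(c) for c in zip(*obs))
    n = t.total
    g = 0.0
    for i in range(2):
        for j in range(2):
            o = obs[i][j]
            if o > 0:
                g += o * math.log(o * n / (row[i] * col[j]))
    return max(2.0 * g, 0.0)  # clip tiny negative round-off


def word_length(token: str) -> int:
    """Length as the count of all non-period characters, so that internal
    periods ("St.p." -> 3) have no punishing effect."""
    return sum(1 for c in token if c != ".")


def scaling_factor(
    k: int,
    loglam: float,
    l_norm: str,
    t: Contingency,
    lex: Lexicon | None = None,
) -> float:
    """Apply the k-th scaling function (k in 1..6) to a running value.

    ``l_norm`` is the normalized left token *without* its terminal period;
    periods still present in it are internal ones.  S1..S5 multiply the
    running value by their factor, S6 adds the MDDict prefix-match count
    N(L_norm.).
    """
    c_dot, c_nodot = t.c_l_dot, t.c_l_nodot
    if k == 1:
        # enhances loglambda when the period-final count dominates; a zero
        # period-free count is floored at 1 to keep the exponent finite
        expo = min(c_dot / max(c_nodot, 1), _EXP_CLAMP)
        return loglam * math.exp(expo)
    if k == 2:
        denom = c_dot + c_nodot
        return loglam * ((c_dot - c_nodot) / denom) if denom else 0.0
    if k == 3:
        return loglam * math.exp(-word_length(l_norm))
    if k == 4:
        return loglam * (l_norm.count(".") + 1)
    if k == 5:
        wl = max(word_length(l_norm), 1)
        return loglam * wl ** (-c_nodot)
    if k == 6:
        if lex is None:
            raise ValueError("S6 requires the MDDict lexicon")
        return loglam + lex.substring_match_count(l_norm + ".")
    raise ValueError(f"scaling index must be 1..6, got {k}")


def scaled_feature(
    combo: Iterable[int],
    loglam: float,
    l_norm: str,
    t: Contingency,
    lex: Lexicon | None = None,
) -> float:
    """Sequentially compose the scaling functions of ``combo`` in ascending
    index order, starting from ``loglam``."""
    ks = sorted(set(combo))
    if not ks:
        raise ValueError("combo must be a non-empty subset of {1..6}")
    value = loglam
    for k in ks:
        value = scaling_factor(k, value, l_norm, t, lex)
    return value


def scaling_combos() -> list[tuple[int, ...]]:
    """The 63 non-empty subsets of {1..6}, ordered by size then lexicon."""
    combos = []
    for mask in range(1, 64):
        combos.append(tuple(k for k in range(1, 7) if mask & (1 << (k - 1))))
    combos.sort(key=lambda c: (len(c), c))
    return combos


def combo_name(combo: Iterable[int]) -> str:
    return "_".join(f"S{k}" for k in sorted(combo))


def abbreviation_length_stats(table: CountTable, alpha: float = 0.01) -> LengthStats:
    """Descriptive length statistic of corpus abbreviation types.

    A type is taken as an abbreviation when its period collocation is
    significant (loglambda above the chi-squared(1) critical value at
    ``alpha``) and C(type, .) > C(type, ~.).  Mean and population SD of
    ``word_length`` over the selected types fill the stats.
    """
    crit = chi2.ppf(1.0 - alpha, df=1)
    lengths = []
    for type_key, (c_dot, c_nodot) in table.counts.items():
        if c_dot <= c_nodot:
            continue
        if log_lambda(table.contingency(type_key)) > crit:
            lengths.append(word_length(type_key))
    if not lengths:
        raise ValueError(
            "no significantly period-collocated types found; "
            "use a larger corpus or relax alpha"
        )
    n = len(lengths)
    mu = sum(lengths) / n
    sigma = math.sqrt(sum((x - mu) ** 2 for x in lengths) / n)
    return LengthStats(mu=mu, sigma=sigma)
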