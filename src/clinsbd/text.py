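"""Tokenization and period-site extraction for clinical narratives.

The classification unit throughout this package is the *period site*
``L. R``: a whitespace-delimited token ``L.`` ending in a period, followed
by the next token ``R``.  Both classifiers (abbreviation detection and
sentence-boundary detection) operate on such sites.  Periods enclosed
between two alphanumeric characters ("C43.5", "sek.knot.SSM") are token
internal and never form sites of their own.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

__all__ = [
    "Token",
    "PeriodSite",
    "NormalizedPair",
    "tokenize",
    "extract_period_sites",
    "normalize_left",
    "normalize_right",
    "normalize_site",
    "read_snippets",
    "write_snippets",
]

_WS_CHUNK = re.compile(r"[^ \t\n\r\f\v]+")
_PERIOD_RUN = re.compile(r"\.{2,}")


@dataclass
class Token:
    """A whitespace-delimited token.

    ``leading_newlines`` counts the newline characters in the whitespace
    run immediately preceding the token; it feeds the text-formatting
    features of the sentence classifier.  ``start``/``end`` are character
    offsets into the source text (``end`` exclusive).
    """

    surface: str
    leading_newlines: int = 0
    start: int = -1
    end: int = -1

    def has_alnum(self) -> bool:
        return any(c.isalnum() for c in self.surface)


@dataclass
class PeriodSite:
    """One candidate period with its local context and optional gold labels."""

    left_token: str
    right_token: str = ""
    left_context: str = ""
    right_context: str = ""
    delimiter_newline_count: int = 0
    is_abbrev: Optional[bool] = None
    is_sentence_end: Optional[bool] = None
    position: int = -1  # char offset of the period in the source text

    def __post_init__(self) -> None:
        if not self.left_token.endswith("."):
            raise ValueError(f"left_token must end with '.': {self.left_token!r}")


@dataclass(frozen=True)
class NormalizedPair:
    """Normalized forms of a site: ``l_norm`` keeps (merged) periods, ``r_norm``
    keeps only letters and digits."""

    l_norm: str
    r_norm: str


def tokenize(text: str) -> list[Token]:
    """Whitespace tokenization with newline bookkeeping and punctuation merge.

    Tokens are maximal runs of non-whitespace characters.  Newline runs are
    recorded on the following token's ``leading_newlines``.  A token that
    contains no alphanumeric character at all is merged into the preceding
    token (joined by a single space) in one left-to-right pass; a purely
    non-alphanumeric first token stays standalone.
    """
    out: list[Token] = []
    prev_end = 0
    for m in _WS_CHUNK.finditer(text):
        gap = text[prev_end : m.start()]
        tok = Token(
            surface=m.group(),
            leading_newlines=gap.count("\n"),
            start=m.start(),
            end=m.end(),
        )
        prev_end = m.end()
        if out and not tok.has_alnum():
            prev = out[-1]
            prev.surface = prev.surface + " " + tok.surface
            prev.end = tok.end
        else:
            out.append(tok)
    return out


def extract_period_sites(
    tokens: Sequence[Token], text: str = "", context_len: int = 60
) -> list[PeriodSite]:
    """One :class:`PeriodSite` per token whose surface ends with a period.

    After whitespace tokenization a token-final period is always followed by
    whitespace or the end of text, so every such token qualifies; token
    internal periods (alphanumeric on both sides) never create sites.
    Context strings are raw character slices of ``text`` around the period,
    truncated at text boundaries; pass the original text to fill them.
    """
    sites: list[PeriodSite] = []
    for i, tok in enumerate(tokens):
        if not tok.surface.endswith("."):
            continue
        nxt = tokens[i + 1] if i + 1 < len(tokens) else None
        pos = tok.end - 1 if tok.end >= 0 else -1
        if text and pos >= 0:
            left_ctx = text[max(0, pos - context_len) : pos]
            right_ctx = text[pos + 1 : pos + 1 + context_len]
        else:
            left_ctx = right_ctx = ""
        sites.append(
            PeriodSite(
                left_token=tok.surface,
                right_token=nxt.surface if nxt else "",
                left_context=left_ctx,
                right_context=right_ctx,
                delimiter_newline_count=nxt.leading_newlines if nxt else 0,
                position=pos,
            )
        )
    return sites


def normalize_left(left_token: str) -> str:
    """Normalize ``L.``: drop every character that is not a letter, digit or
    period, then collapse adjacent periods.  Idempotent."""
    kept = "".join(c for c in left_token if c.isalnum() or c == ".")
    return _PERIOD_RUN.sub(".", kept)


def normalize_right(right_token: str) -> str:
    """Normalize ``R``: keep letters and digits only (word content).  Idempotent."""
    return "".join(c for c in right_token if c.isalnum())


def normalize_site(site: PeriodSite) -> NormalizedPair:
    return NormalizedPair(
        l_norm=normalize_left(site.left_token),
        r_norm=normalize_right(site.right_token),
    )


# ---------------------------------------------------------------------------
# Snippet TSV interchange format

_SNIPPET_COLUMNS = (
    "left_context",
    "left_token",
    "right_token",
    "right_context",
    "newline_count",
    "is_abbrev",
    "is_sentence_end",
)


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace("\n", "\\n").replace("\t", "\\t")


def _unescape(s: str) -> str:
    out = io.StringIO()
    it = iter(range(len(s)))
    i = 0
    while i < len(s):
        c = s[i]
        if c == "\\" and i + 1 < len(s):
            nxt = s[i + 1]
            if nxt == "n":
                out.write("\n")
                i += 2
                continue
            if nxt == "t":
                out.write("\t")
                i += 2
                continue
            if nxt == "\\":
                out.write("\\")
                i += 2
                continue
        out.write(c)
        i += 1
    return out.getvalue()


def _label_str(v: Optional[bool]) -> str:
    return "NA" if v is None else str(int(v))


def _label_parse(s: str) -> Optional[bool]:
    s = s.strip()
    if s in ("", "NA"):
        return None
    return bool(int(s))


def write_snippets(sites: Iterable[PeriodSite], path) -> None:
    """Write sites as tab-separated snippets (UTF-8, header row, literal
    newlines/tabs in contexts escaped)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE, quotechar=None)
        w.writerow(_SNIPPET_COLUMNS)
        for s in sites:
            w.writerow(
                [
                    _escape(s.left_context),
                    _escape(s.left_token),
                    _escape(s.right_token),
                    _escape(s.right_context),
                    s.delimiter_newline_count,
                    _label_str(s.is_abbrev),
                    _label_str(s.is_sentence_end),
                ]
            )


def read_snippets(path) -> list[PeriodSite]:
    with open(path, encoding="utf-8", newline="") as fh:
        r = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE, quotechar=None)
        header = next(r)
        if tuple(header) != _SNIPPET_COLUMNS:
            raise ValueError(f"unexpected snippet header: {header}")
        sites = []
        for row in r:
            if not row:
                continue
            lc, lt, rt, rc, nl, ab, se = row
            sites.append(
                PeriodSite(
                    left_token=_unescape(lt),
                    right_token=_unescape(rt),
                    left_context=_unescape(lc),
                    right_context=_unescape(rc),
                    delimiter_newline_count=int(nl),
                    is_abbrev=_label_parse(ab),
                    is_sentence_end=_label_parse(se),
                )
            )
    return sites
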