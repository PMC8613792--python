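"""Locale-aware numeric parsing.

Survey and statistics-office tables in this domain mix two decimal styles,
sometimes within a single table: the point style ("925,988.57") and the
comma style ("$ 1.657,29", common in Indonesian sources). Readers take an
explicit ``locale`` flag per file; ``"auto"`` applies a per-token heuristic
for mixed tables.
"""

from __future__ import annotations

import re

from .errors import InputError

_CLEAN = re.compile(r"[$%\s ]")

LOCALES = ("point", "comma", "auto")


def parse_number(text: str | float | int, locale: str = "point") -> float:
    """Parse a numeric token under the given decimal convention.

    Parameters
    ----------
    text:
        The token; currency symbols, percent signs and whitespace are ignored.
        Numeric inputs pass through unchanged.
    locale:
        ``"point"`` (decimal point, comma thousands), ``"comma"`` (decimal
        comma, point thousands) or ``"auto"`` (infer per token: the rightmost
        of ``.``/``,`` is taken as the decimal mark when both occur; a single
        separator followed by exactly three digits is read as thousands).
    """
    if isinstance(text, (int, float)):
        return float(text)
    if locale not in LOCALES:
        raise InputError(f"unknown locale {locale!r}; expected one of {LOCALES}")
    s = _CLEAN.sub("", str(text))
    if not s:
        raise InputError(f"empty numeric token {text!r}")
    neg = s.startswith("-")
    if neg or s.startswith("+"):
        s = s[1:]
    if not re.fullmatch(r"[\d.,]+", s):
        raise InputError(f"cannot parse number from {text!r}")

    if locale == "comma":
        s = s.replace(".", "").replace(",", ".")
    elif locale == "point":
        s = s.replace(",", "")
    else:
        s = _auto_normalize(s)
    try:
        value = float(s)
    except ValueError as exc:  # e.g. "1.2.3" after normalization
        raise InputError(f"cannot parse number from {text!r}") from exc
    return -value if neg else value


def _auto_normalize(s: str) -> str:
    has_dot, has_comma = "." in s, "," in s
    if has_dot and has_comma:
        # rightmost separator is the decimal mark
        if s.rfind(".") > s.rfind(","):
            return s.replace(",", "")
        return s.replace(".", "").replace(",", ".")
    sep = "." if has_dot else "," if has_comma else None
    if sep is None:
        return s
    head, _, tail = s.rpartition(sep)
    if s.count(sep) > 1 or (len(tail) == 3 and head and len(head.replace(sep, "")) > 0):
        # repeated separator, or exactly three trailing digits: thousands grouping
        return s.replace(sep, "")
    return s.replace(sep, ".")
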