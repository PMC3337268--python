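"""Typed parsing of heterogeneous toxicity indicator strings.

Chronic-study records encode the same indicator — survival rate — in several
string dialects: a plain ratio of surviving to tested animals (``'10/10'``,
``'16/17'``) or a ratio qualified by an observation window in study weeks
(``'0/5 (weeks 27-30)'``). Qualitative observations arrive as comma-joined
phrases such as ``'MORTALITY, INCREASED'``. Parsing these into typed records
is what makes values from different studies comparable; strings outside the
grammar are reported as errors so callers can carry them verbatim (flagged)
instead of dropping them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ValueDomainError, ValueSyntaxError

_RATIO_RE = re.compile(
    r"""^\s*(\d+)\s*/\s*(\d+)\s*
        (?:\(\s*weeks\s+(\d+)\s*-\s*(\d+)\s*\)\s*)?$""",
    re.IGNORECASE | re.VERBOSE,
)

DIRECTIONS = ("INCREASED", "DECREASED", "UNCHANGED")

_DIRECTION_SYNONYMS = {
    "INCREASED": "INCREASED",
    "INCREASE": "INCREASED",
    "ELEVATED": "INCREASED",
    "DECREASED": "DECREASED",
    "DECREASE": "DECREASED",
    "REDUCED": "DECREASED",
    "UNCHANGED": "UNCHANGED",
    "NO CHANGE": "UNCHANGED",
    "NOT CHANGED": "UNCHANGED",
}


@dataclass(frozen=True)
class RatioObservation:
    """Survivors over tested animals, optionally within a week window."""

    numerator: int
    denominator: int
    period_start_week: int | None = None
    period_end_week: int | None = None

    @property
    def has_period(self) -> bool:
        return self.period_start_week is not None

    def __str__(self) -> str:
        base = f"{self.numerator}/{self.denominator}"
        if self.has_period:
            base += f" (weeks {self.period_start_week}-{self.period_end_week})"
        return base


@dataclass(frozen=True)
class QualitativeEffect:
    """An indicator token plus a direction from a closed set."""

    indicator: str
    direction: str

    def __str__(self) -> str:
        return f"{self.indicator}, {self.direction}"


def parse_ratio(text: str) -> RatioObservation:
    """Parse ``INT "/" INT ["(weeks" INT "-" INT ")"]`` with loose whitespace.

    Syntax failures raise :class:`ValueSyntaxError`; a matching string with
    impossible values (more survivors than tested, inverted week range, zero
    tested animals) raises :class:`ValueDomainError` — the two are distinct
    because domain errors are data problems, not format dialects.
    """
    m = _RATIO_RE.match(text)
    if not m:
        raise ValueSyntaxError(text)
    num, den = int(m.group(1)), int(m.group(2))
    start = int(m.group(3)) if m.group(3) is not None else None
    end = int(m.group(4)) if m.group(4) is not None else None
    if den == 0:
        raise ValueDomainError(text, "zero tested animals")
    if num > den:
        raise ValueDomainError(text, f"{num} survivors among {den} tested")
    if start is not None and (start == 0 or end == 0):
        raise ValueDomainError(text, "study weeks are counted from 1")
    if start is not None and start > end:
        raise ValueDomainError(text, f"week range {start}-{end} is inverted")
    return RatioObservation(num, den, start, end)


def format_ratio(obs: RatioObservation) -> str:
    return str(obs)


def parse_effect(text: str) -> QualitativeEffect:
    """Parse ``'<INDICATOR>, <DIRECTION>'`` (split on the last comma).

    The direction slot is upper-cased and mapped through a small synonym
    table onto {INCREASED, DECREASED, UNCHANGED}.
    """
    if "," not in text:
        raise ValueSyntaxError(text, "expected '<indicator>, <direction>'")
    indicator, _, direction = text.rpartition(",")
    indicator = indicator.strip().upper()
    direction = direction.strip().upper()
    if not indicator:
        raise ValueSyntaxError(text, "empty indicator")
    mapped = _DIRECTION_SYNONYMS.get(direction)
    if mapped is None:
        raise ValueSyntaxError(text, f"unknown direction {direction!r}")
    return QualitativeEffect(indicator, mapped)


def format_effect(effect: QualitativeEffect) -> str:
    return str(effect)
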