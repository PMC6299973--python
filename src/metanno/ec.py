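"""Enzyme Commission (EC) number parsing and canonical representation.

EC numbers are four-level identifiers ``class.subclass.sub-subclass.serial``
naming a catalytic activity (e.g. ``2.7.1.2`` for glucokinase).  Annotation
tools frequently emit *partial* ECs with trailing positions replaced by a
dash (``1.2.3.-`` or even ``1.2.-.-``); these identify only a family of
activities and are excluded from set-level analyses downstream.

Comparison is exact: two ECs are equal iff all four positions match.  No
hierarchy-aware matching is performed, and deprecated/transferred numbers
are treated as literal strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

__all__ = ["ECNumber", "ECParseError", "parse_ec", "extract_ecs_from_function"]

#: Highest top-level EC class. Class 7 (translocases) was introduced by the
#: Enzyme Commission in 2018; a strict 1..6 mode is available for fidelity
#: with older snapshots.
MAX_EC_CLASS = 7


class ECParseError(ValueError):
    """Raised when a string cannot be interpreted as an EC number."""


@dataclass(frozen=True, order=True)
class ECNumber:
    """A parsed, validated EC number; partial if trailing fields are absent.

    Absent fields must be suffix-contiguous: if ``subclass`` is absent so are
    ``subsubclass`` and ``serial``.  ``is_partial`` is true iff ``serial`` is
    absent.
    """

    ec_class: int
    subclass: Optional[int] = None
    subsubclass: Optional[int] = None
    serial: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.ec_class <= MAX_EC_CLASS:
            raise ECParseError(f"EC class must be in 1..{MAX_EC_CLASS}: {self.ec_class}")
        fields = (self.subclass, self.subsubclass, self.serial)
        seen_absent = False
        for value in fields:
            if value is None:
                seen_absent = True
            elif seen_absent:
                raise ECParseError(f"non-trailing absent field in EC number: {self}")
            elif value <= 0:
                raise ECParseError(f"EC fields must be positive integers: {value}")

    @property
    def is_partial(self) -> bool:
        return self.serial is None

    def truncated(self) -> "ECNumber":
        """Partial form of this EC with the serial removed (``1.2.3.-``)."""
        return ECNumber(self.ec_class, self.subclass, self.subsubclass, None)

    def __str__(self) -> str:
        parts = [str(self.ec_class)]
        for value in (self.subclass, self.subsubclass, self.serial):
            parts.append("-" if value is None else str(value))
        return ".".join(parts)


_EC_PREFIX = re.compile(r"^\s*(?:EC[:\s]*)?", re.IGNORECASE)
# Embedded tokens in free-text function strings look like "(EC 2.7.1.2)".
_EMBEDDED = re.compile(r"\(\s*EC[:\s]\s*([0-9]+(?:\.(?:[0-9]+|-)){3})\s*\)", re.IGNORECASE)


def parse_ec(text: str, strict_classes: bool = False) -> ECNumber:
    """Parse ``text`` into an :class:`ECNumber`.

    Accepts bare (``1.1.1.1``), prefixed (``EC 1.1.1.1``, ``ec:1.1.1.1``) and
    partial (``1.2.3.-``, ``1.2.-.-``) forms; tolerant of surrounding
    whitespace.

    Parameters
    ----------
    text:
        The candidate EC string.
    strict_classes:
        Restrict the top-level class to 1..6 (pre-translocase nomenclature).

    Raises
    ------
    ECParseError
        On wrong field count, a non-integer field other than a trailing
        dash, or a class outside the accepted range — the message names the
        offending text.
    """
    if not text or not text.strip():
        raise ECParseError("empty EC number string")
    body = _EC_PREFIX.sub("", text.strip(), count=1).strip()
    fields = body.split(".")
    if len(fields) != 4:
        raise ECParseError(f"expected 4 dot-separated fields, got {len(fields)}: {text!r}")
    values: list[Optional[int]] = []
    for field in fields:
        field = field.strip()
        if field == "-":
            values.append(None)
        elif field.isdigit():
            values.append(int(field))
        else:
            raise ECParseError(f"non-integer EC field {field!r} in {text!r}")
    if values[0] is None:
        raise ECParseError(f"EC class may not be absent: {text!r}")
    try:
        ec = ECNumber(values[0], values[1], values[2], values[3])
    except ECParseError as exc:
        raise ECParseError(f"{exc} (while parsing {text!r})") from None
    if strict_classes and ec.ec_class > 6:
        raise ECParseError(f"EC class {ec.ec_class} outside strict 1..6 range: {text!r}")
    return ec


def extract_ecs_from_function(function_text: str, strict_classes: bool = False) -> list[ECNumber]:
    """Extract all ``(EC x.x.x.x)`` tokens embedded in a function string.

    Returns the parsed ECs in order of first appearance, deduplicated.
    Tokens whose class falls outside the accepted range are skipped rather
    than raising: free text is not trusted to be well formed.
    """
    seen: dict[ECNumber, None] = {}
    for match in _EMBEDDED.finditer(function_text or ""):
        try:
            ec = parse_ec(match.group(1), strict_classes=strict_classes)
        except ECParseError:
            continue
        seen.setdefault(ec, None)
    return list(seen)
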