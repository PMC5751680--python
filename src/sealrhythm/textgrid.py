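"""Praat TextGrid reading, writing and call selection.

Praat stores interval annotations as "TextGrid" objects in two text
dialects: the verbose *long* form (``xmin = 0.5``, one attribute per line)
and the *short* form (bare values, one per line). Both carry the same
ordered structure: file-level ``xmin``/``xmax``, a tier count, and per tier
a class (``"IntervalTier"`` or ``"TextTier"``), a name, bounds and the
labelled intervals or points. Praat writes UTF-8 or UTF-16 (the latter for
non-ASCII labels); both are accepted here. The binary ``.TextGrid``
variant is rejected with a clear error.

Times are seconds from recording start; intervals are treated half-open
``[onset, offset)`` for containment, matching Praat's convention.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "CallAnnotation",
    "AnnotationTier",
    "TextGridParseError",
    "parse_textgrid",
    "read_textgrid",
    "write_textgrid",
    "select_calls",
]


class TextGridParseError(ValueError):
    """Malformed TextGrid content; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class CallAnnotation:
    """One labelled interval on an annotation tier.

    ``label`` is the annotation category (e.g. ``"MAC"``, ``"other"``, or
    ``""`` for silence); ``onset``/``offset`` are seconds.
    """

    label: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if not self.onset < self.offset:
            raise ValueError(
                f"onset must precede offset, got [{self.onset}, {self.offset}]"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def contains(self, t: float) -> bool:
        """Half-open containment: onset <= t < offset."""
        return self.onset <= t < self.offset


@dataclass
class AnnotationTier:
    """An ordered, non-overlapping interval tier."""

    name: str
    xmin: float
    xmax: float
    intervals: list[CallAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.xmin < self.xmax:
            raise ValueError(f"tier bounds invalid: [{self.xmin}, {self.xmax}]")
        prev_off = None
        for iv in self.intervals:
            if iv.onset < self.xmin - 1e-9 or iv.offset > self.xmax + 1e-9:
                raise ValueError(
                    f"interval [{iv.onset}, {iv.offset}] outside tier "
                    f"bounds [{self.xmin}, {self.xmax}]"
                )
            if prev_off is not None and iv.onset < prev_off - 1e-9:
                raise ValueError(
                    f"intervals overlap or are unsorted at onset {iv.onset}"
                )
            prev_off = iv.offset


# ---------------------------------------------------------------------------
# parsing

_QUOTED = re.compile(r'"((?:[^"]|"")*)"')


def _decode(content: bytes | str) -> str:
    if isinstance(content, str):
        return content.lstrip("﻿")
    if content[:2] in (b"\xff\xfe", b"\xfe\xff"):
        return content.decode("utf-16")
    if content[:3] == b"\xef\xbb\xbf":
        return content.decode("utf-8-sig")
    if b"ooBinaryFile" in content[:32]:
        raise TextGridParseError(
            "binary TextGrid not supported; re-save as text in Praat"
        )
    try:
        return content.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise TextGridParseError(
            "content is neither UTF-8 nor BOM-marked UTF-16 text"
        ) from exc


class _Tokens:
    """Sequential value extractor shared by both text dialects.

    In the long dialect every value sits on its own line after ``=`` (or is
    the ``<exists>`` flag); structural lines (``item [1]:``) carry no value
    and are skipped. In the short dialect every non-blank line is a value.
    """

    def __init__(self, text: str, short: bool):
        self.lines = text.splitlines()
        self.short = short
        self.pos = 0

    def _next_raw(self) -> tuple[str, int]:
        while self.pos < len(self.lines):
            lineno = self.pos + 1
            line = self.lines[self.pos].strip()
            self.pos += 1
            if not line:
                continue
            if self.short:
                return line, lineno
            if "<exists>" in line:
                return "<exists>", lineno
            if "=" in line:
                return line.split("=", 1)[1].strip(), lineno
            if line.endswith(":") or line.endswith("]:"):
                continue  # structural: item []:, intervals [3]:
            return line, lineno
        raise TextGridParseError("unexpected end of file", len(self.lines))

    def number(self, what: str) -> tuple[float, int]:
        raw, lineno = self._next_raw()
        try:
            return float(raw), lineno
        except ValueError:
            raise TextGridParseError(
                f"expected numeric {what}, got {raw!r}", lineno
            ) from None

    def string(self, what: str) -> tuple[str, int]:
        raw, lineno = self._next_raw()
        m = _QUOTED.search(raw)
        if m is None:
            raise TextGridParseError(
                f"expected quoted {what}, got {raw!r}", lineno
            )
        return m.group(1).replace('""', '"'), lineno

    def flag(self) -> tuple[bool, int]:
        raw, lineno = self._next_raw()
        return "<exists>" in raw or raw == "1", lineno


def parse_textgrid(content: bytes | str) -> list[AnnotationTier]:
    """Parse a Praat TextGrid (long or short text dialect).

    Returns all interval tiers in file order. Point tiers (``TextTier``)
    are consumed but dropped with a logged warning. Raises
    :class:`TextGridParseError` naming the offending line on malformed
    input.
    """
    text = _decode(content)
    lines = text.splitlines()
    if not lines or "ooTextFile" not in lines[0]:
        raise TextGridParseError('missing \'File type = "ooTextFile"\' header', 1)
    if len(lines) < 2 or "TextGrid" not in lines[1]:
        raise TextGridParseError('missing \'Object class = "TextGrid"\' header', 2)

    body = "\n".join(lines[2:])
    # long dialect re-states attribute names; short dialect has bare values
    short = not re.search(r"^\s*xmin\s*=", body, re.MULTILINE)
    toks = _Tokens(body, short=short)
    toks.number("file xmin")
    toks.number("file xmax")
    has_tiers, _ = toks.flag()
    n_tiers_f, lineno = toks.number("tier count")
    n_tiers = int(n_tiers_f)
    if not has_tiers or n_tiers == 0:
        return []

    tiers: list[AnnotationTier] = []
    for _ in range(n_tiers):
        klass, kl_line = toks.string("tier class")
        name, _ = toks.string("tier name")
        txmin, _ = toks.number("tier xmin")
        txmax, _ = toks.number("tier xmax")
        n_items = int(toks.number("item count")[0])
        if klass == "IntervalTier":
            intervals = []
            for _ in range(n_items):
                ivmin, l1 = toks.number("interval xmin")
                ivmax, l2 = toks.number("interval xmax")
                label, _ = toks.string("interval text")
                if not ivmin < ivmax:
                    raise TextGridParseError(
                        f"interval with offset <= onset: [{ivmin}, {ivmax}]", l2
                    )
                intervals.append(CallAnnotation(label, ivmin, ivmax))
            try:
                tiers.append(AnnotationTier(name, txmin, txmax, intervals))
            except ValueError as exc:
                raise TextGridParseError(str(exc), kl_line) from None
        elif klass == "TextTier":
            logger.warning("ignoring point tier %r (%d points)", name, n_items)
            for _ in range(n_items):
                toks.number("point time")
                toks.string("point mark")
        else:
            raise TextGridParseError(f"unknown tier class {klass!r}", kl_line)
    return tiers


def read_textgrid(path: str | Path) -> list[AnnotationTier]:
    """Read a TextGrid file, auto-detecting UTF-8/UTF-16 encoding."""
    return parse_textgrid(Path(path).read_bytes())


# ---------------------------------------------------------------------------
# writing


def _fmt(x: float) -> str:
    # repr round-trips exactly, so parse(write(T)) == T
    return repr(float(x))


def _quote(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def write_textgrid(tiers: Sequence[AnnotationTier]) -> str:
    """Serialize tiers to the long text dialect readable by Praat.

    Gaps between annotated intervals are filled with empty-label intervals
    so that the tier tiles ``[xmin, xmax]``, as Praat requires.
    """
    for t in tiers:
        t.validate()
    xmin = min((t.xmin for t in tiers), default=0.0)
    xmax = max((t.xmax for t in tiers), default=1.0)
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {_fmt(xmin)}",
        f"xmax = {_fmt(xmax)}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for ti, tier in enumerate(tiers, 1):
        filled = _fill_gaps(tier)
        out += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f"        name = {_quote(tier.name)}",
            f"        xmin = {_fmt(tier.xmin)}",
            f"        xmax = {_fmt(tier.xmax)}",
            f"        intervals: size = {len(filled)}",
        ]
        for ii, iv in enumerate(filled, 1):
            out += [
                f"        intervals [{ii}]:",
                f"            xmin = {_fmt(iv.onset)}",
                f"            xmax = {_fmt(iv.offset)}",
                f"            text = {_quote(iv.label)}",
            ]
    return "\n".join(out) + "\n"


def _fill_gaps(tier: AnnotationTier) -> list[CallAnnotation]:
    filled: list[CallAnnotation] = []
    cursor = tier.xmin
    for iv in tier.intervals:
        if iv.onset > cursor + 1e-12:
            filled.append(CallAnnotation("", cursor, iv.onset))
        filled.append(iv)
        cursor = iv.offset
    if cursor < tier.xmax - 1e-12:
        filled.append(CallAnnotation("", cursor, tier.xmax))
    if not filled:
        filled.append(CallAnnotation("", tier.xmin, tier.xmax))
    return filled


# ---------------------------------------------------------------------------
# call selection


def select_calls(
    tier: AnnotationTier,
    retain_labels: Iterable[str],
    *,
    strip: bool = True,
) -> list[CallAnnotation]:
    """Return the tier's intervals whose label is in ``retain_labels``.

    Matching is exact and case-sensitive; with ``strip=True`` (default)
    labels are whitespace-stripped before comparison, tolerating stray
    spaces from manual annotation. Temporal order is preserved. Silence
    (empty label) is only retained if explicitly listed.
    """
    retain = set(retain_labels)
    if not retain:
        raise ValueError("retain_labels must be non-empty")
    if strip:
        retain = {r.strip() for r in retain}

    def norm(label: str) -> str:
        return label.strip() if strip else label

    return [iv for iv in tier.intervals if norm(iv.label) in retain]
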