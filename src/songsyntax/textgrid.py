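"""Reader for PRAAT TextGrid annotation files (text format).

Supports interval tiers in both text dialects PRAAT writes:

* the *long* form, with ``key = value`` lines and ``item []`` / ``intervals``
  headers;
* the *short* form, with the same values as bare lines in fixed order.

Point tiers are ignored.  Only what the annotation workflow needs is
implemented: locating an interval tier by name and returning its labelled
intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .types import ParseError, TierNotFoundError

_QUOTED = re.compile(r'"((?:[^"]|"")*)"')
_KEYVAL = re.compile(r'^\s*([A-Za-z_][A-Za-z0-9_ \[\]]*?)\s*=\s*(.*?)\s*$')


@dataclass(frozen=True)
class Interval:
    xmin: float
    xmax: float
    text: str


@dataclass(frozen=True)
class IntervalTier:
    name: str
    xmin: float
    xmax: float
    intervals: tuple[Interval, ...]


def _unquote(raw: str) -> str:
    raw = raw.strip()
    m = _QUOTED.match(raw)
    if m is None:
        raise ParseError(f"expected quoted string, got {raw!r}")
    return m.group(1).replace('""', '"')


def read_textgrid(path: str | Path) -> list[IntervalTier]:
    """Parse a TextGrid file and return its interval tiers in file order."""
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2 or "ooTextFile" not in lines[0] or "TextGrid" not in lines[1]:
        raise ParseError(f"{path}: not a text-format TextGrid file")
    body = lines[2:]
    # the long form spells out 'key = value'; the short form has bare values
    is_long = any(_KEYVAL.match(ln) for ln in body[:4])
    try:
        return _parse_long(body) if is_long else _parse_short(body)
    except (IndexError, ValueError) as exc:  # truncated file or bad number
        raise ParseError(f"{path}: malformed TextGrid ({exc})") from exc


def _parse_long(lines: list[str]) -> list[IntervalTier]:
    # flatten to a value stream keyed by attribute name; structure is implied
    # by the order class/name/xmin/xmax/text appear in
    tiers: list[IntervalTier] = []
    cls = name = None
    tier_bounds: list[float] = []
    cur: list[Interval] = []
    ixmin = ixmax = None

    def flush_tier() -> None:
        nonlocal cls, name, cur, tier_bounds
        if cls == "IntervalTier" and name is not None:
            tiers.append(
                IntervalTier(name, tier_bounds[0], tier_bounds[1], tuple(cur))
            )
        cls = name = None
        tier_bounds = []
        cur = []

    in_tier = False
    for ln in lines:
        m = _KEYVAL.match(ln)
        if m is None:
            continue
        key = m.group(1).split("[")[0].strip()
        val = m.group(2)
        if key == "class":
            flush_tier()
            cls = _unquote(val)
            in_tier = True
        elif key == "name":
            name = _unquote(val)
        elif key == "xmin":
            x = float(val)
            if not in_tier:
                continue
            if len(tier_bounds) < 1:
                tier_bounds.append(x)
            else:
                ixmin = x
        elif key == "xmax":
            x = float(val)
            if not in_tier:
                continue
            if len(tier_bounds) < 2:
                tier_bounds.append(x)
            else:
                ixmax = x
        elif key in ("text", "mark"):
            if cls == "IntervalTier" and ixmin is not None and ixmax is not None:
                cur.append(Interval(ixmin, ixmax, _unquote(val)))
            ixmin = ixmax = None
    flush_tier()
    return tiers


def _parse_short(lines: list[str]) -> list[IntervalTier]:
    it = iter(lines)
    next(it)  # file xmin
    next(it)  # file xmax
    exists = next(it).strip()
    if exists not in ("<exists>", "1"):
        raise ParseError("short TextGrid: missing <exists> flag")
    n_tiers = int(next(it))
    tiers: list[IntervalTier] = []
    for _ in range(n_tiers):
        cls = _unquote(next(it))
        name = _unquote(next(it))
        xmin = float(next(it))
        xmax = float(next(it))
        n = int(next(it))
        if cls == "IntervalTier":
            ivs = []
            for _ in range(n):
                a = float(next(it))
                b = float(next(it))
                t = _unquote(next(it))
                ivs.append(Interval(a, b, t))
            tiers.append(IntervalTier(name, xmin, xmax, tuple(ivs)))
        else:  # TextTier (points): number + mark per point, skipped
            for _ in range(n):
                next(it)
                next(it)
    return tiers


def get_interval_tier(path: str | Path, tier_name: str) -> IntervalTier:
    """The named interval tier, or :class:`TierNotFoundError`."""
    tiers = read_textgrid(path)
    for tier in tiers:
        if tier.name == tier_name:
            return tier
    available = ", ".join(repr(t.name) for t in tiers) or "none"
    raise TierNotFoundError(
        f"{path}: no interval tier named {tier_name!r} (available: {available})"
    )
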