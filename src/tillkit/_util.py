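"""Small numeric helpers used across reporting modules."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of the printed tables).

    Python's built-in ``round`` uses banker's rounding, which would render a
    density of e.g. 558.5 kb as "1/558 kb"; screen reports conventionally round
    half up in magnitude.
    """
    scale = 10.0 ** ndigits
    scaled = x * scale
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / scale


def fmt_percent(x: float | None, ndigits: int = 1) -> str:
    """Render a percentage to fixed decimals, '-' for undefined."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "-"
    return f"{round_half_away(x, ndigits):.{ndigits}f}"


def parse_int(cell: str | int | float, *, context: str = "") -> int:
    """Parse an integer cell, tolerating thousands separators ('3,885')."""
    from .errors import ParseError

    if isinstance(cell, (int,)):
        return int(cell)
    text = str(cell).strip().replace(",", "")
    try:
        return int(text)
    except ValueError as exc:
        raise ParseError(f"non-numeric cell {cell!r}{' at ' + context if context else ''}") from exc
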