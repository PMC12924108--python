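"""Shared month-index convention.

Every module indexes time as integer months elapsed since January of a
configured start year (0-based).  June of the start year is index 5; the
index crosses calendar-year boundaries freely, which keeps distributed-lag
arithmetic to plain integer subtraction.
"""

from __future__ import annotations

import calendar


def month_index(year: int, month: int, start_year: int) -> int:
    """Months since January of ``start_year`` (0-based)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return (year - start_year) * 12 + (month - 1)


def year_month(index: int, start_year: int) -> tuple[int, int]:
    """Inverse of :func:`month_index`."""
    y, m = divmod(index, 12)
    return start_year + y, m + 1


def days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(year, month)[1]


def june_index(year: int, start_year: int) -> int:
    """Month index of June in ``year`` (annual population anchor)."""
    return month_index(year, 6, start_year)
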