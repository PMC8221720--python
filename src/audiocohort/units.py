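"""Day/month conventions used throughout the package.

Clinical rules in hearing-aid supply data mix month-denominated quantities
(6-month battery supply, 12-month acceptable gap, 24-month evaluation time)
with day-denominated ones (180-day fitting window, 14-180-day survey window).
To make every rule exact and testable, all dates are integer days from a
cohort epoch and month-denominated constants are converted once, with

    days(m) = round(m * 365.25 / 12)

so 6 months = 183 days, 12 months = 365 days, 18 months = 548 days and
24 months = 730 days. All four derived constants are configurable downstream.
"""

from __future__ import annotations

import datetime

#: Calendar origin of day 0 for synthetic cohorts (start of the order window).
EPOCH = datetime.date(2012, 4, 1)

DAYS_PER_YEAR = 365.25


def months_to_days(months: float) -> int:
    """Convert a month-denominated duration to integer days."""
    return int(round(months * DAYS_PER_YEAR / 12.0))


def days_to_months(days: int) -> int:
    """Smallest whole number of months whose day equivalent is >= ``days``.

    Inverse of :func:`months_to_days` on the convention's grid: if ``days``
    equals ``months_to_days(m)`` for an integer ``m``, that ``m`` is returned.
    """
    m = 0
    while months_to_days(m) < days:
        m += 1
    return m


def day_to_date(day: int) -> datetime.date:
    return EPOCH + datetime.timedelta(days=int(day))


def date_to_day(date: datetime.date) -> int:
    return (date - EPOCH).days
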