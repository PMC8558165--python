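"""Calendar-month date arithmetic shared by the phase and window logic.

All observation windows in this package are defined in calendar months
(an "initial year" runs from the diagnosis date to the same day of the
month twelve months later), so month arithmetic — not fixed 365-day
offsets — is used throughout. Month-end overflow clamps to the last day
of the target month (Jan 31 + 1 month = Feb 28/29), the convention of
``dateutil.relativedelta``.
"""

from __future__ import annotations

import datetime as dt

from dateutil.relativedelta import relativedelta


def add_months(d: dt.date, months: int) -> dt.date:
    """Shift ``d`` by a signed number of calendar months."""
    return d + relativedelta(months=months)


def years_between(start: dt.date, end: dt.date) -> float:
    """Length of ``[start, end)`` in years (365.25-day years).

    Used only to convert window lengths into exposure time for event
    intensities; phase boundaries themselves are calendar-month exact.
    """
    return (end - start).days / 365.25


def parse_date(value) -> dt.date | None:
    """Parse an ISO-8601 date; empty/NaN values map to None.

    Month-only values (``YYYY-MM``) are imputed to day 15, the midpoint
    convention for registry records with incomplete diagnosis dates.
    """
    if value is None:
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    s = str(value).strip()
    if not s or s.lower() in {"nan", "nat", "none"}:
        return None
    parts = s.split("-")
    if len(parts) == 2:  # month-only registry date
        return dt.date(int(parts[0]), int(parts[1]), 15)
    return dt.date.fromisoformat(s)
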