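"""Small calendar helpers shared across modules."""

from __future__ import annotations

from datetime import date

import pandas as pd


def as_date(value) -> date:
    """Coerce a pandas Timestamp / ISO string / date to datetime.date."""
    if isinstance(value, date) and not isinstance(value, pd.Timestamp):
        return value
    return pd.Timestamp(value).date()


def completed_years(birth: date, when: date) -> int:
    """Age in completed years at ``when`` for someone born on ``birth``."""
    years = when.year - birth.year
    if (when.month, when.day) < (birth.month, birth.day):
        years -= 1
    return years


def add_calendar_years(d: date, years: int) -> date:
    """Same day-of-month ``years`` later; 29 Feb maps to 28 Feb."""
    try:
        return d.replace(year=d.year + years)
    except ValueError:
        return d.replace(year=d.year + years, day=28)
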