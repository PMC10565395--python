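"""Study-wide configuration: monitoring window, local-time convention, seasons.

Daily statistics (presence, residency, bouts) are sensitive to where the day
boundary falls.  All "local day" and "local hour" computations in the package
go through :class:`StudyConfig`, which carries a fixed UTC offset (default
-3 h, Argentina) applied to the raw detection timestamps.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

__all__ = ["StudyConfig", "study_duration_days"]

_ALL_MONTHS = frozenset(range(1, 13))


@dataclass(frozen=True)
class StudyConfig:
    """Monitoring window and time conventions for one telemetry study.

    Parameters
    ----------
    study_start, study_end : datetime.date
        First and last monitored local days (both monitored; the scalar
        study *duration* is the exclusive difference ``end - start``).
    local_utc_offset : float
        Hours added to raw (UTC) timestamps to obtain local time.
    high_season_months, low_season_months : frozenset of int
        Calendar months defining the high/low abundance seasons.  Together
        they must partition 1..12.
    """

    study_start: dt.date
    study_end: dt.date
    local_utc_offset: float = -3.0
    high_season_months: frozenset = frozenset({10, 11, 12, 1, 2})
    low_season_months: frozenset = frozenset({3, 4, 5, 6, 7, 8, 9})
    timestamps_are_utc: bool = True

    def __post_init__(self) -> None:
        if self.study_end < self.study_start:
            raise ValueError(
                f"study_end {self.study_end} precedes study_start {self.study_start}"
            )
        hi = frozenset(self.high_season_months)
        lo = frozenset(self.low_season_months)
        if (hi | lo) != _ALL_MONTHS or (hi & lo):
            raise ValueError("high/low season months must partition months 1..12")
        object.__setattr__(self, "high_season_months", hi)
        object.__setattr__(self, "low_season_months", lo)

    # -- local-time helpers -------------------------------------------------

    @property
    def utc_offset(self) -> dt.timedelta:
        return dt.timedelta(hours=self.local_utc_offset)

    def to_local(self, timestamps):
        """Shift a pandas datetime Series/Index to local clock time."""
        if not self.timestamps_are_utc:
            return timestamps
        return timestamps + self.utc_offset

    def local_day(self, timestamps):
        """Local calendar day of each timestamp (normalized datetime64)."""
        return self.to_local(timestamps).dt.normalize()

    def local_hour(self, timestamps):
        """Integer local hour-of-day in 0..23."""
        return self.to_local(timestamps).dt.hour

    def season_of_month(self, month: int) -> str:
        return "high" if month in self.high_season_months else "low"

    def days(self):
        """All local days of the study window, inclusive of both endpoints."""
        import pandas as pd

        return pd.date_range(self.study_start, self.study_end, freq="D")

    @property
    def duration_days(self) -> int:
        return study_duration_days(self)


def study_duration_days(config: StudyConfig) -> int:
    """Scalar study duration in whole days, ``study_end - study_start``.

    The difference is exclusive (a window from a date to itself has
    duration 0): the 2019-11-01 to 2021-03-12 window has duration 497 days,
    which is the denominator of the minimum residency index.
    """
    if config.study_end < config.study_start:
        raise ValueError("study_end precedes study_start")
    return (config.study_end - config.study_start).days
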