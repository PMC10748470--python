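"""Photoschedules and Zeitgeber time.

A photoschedule describes the light regime an individual experiences inside
its incubator: a standard 12:12 light:dark cycle (``LD``), the reversed cycle
(``DL``), or constant darkness (``DD``).  Zeitgeber time (ZT) is measured in
hours since lights-on, so ZT0 is the start of the (subjective) light phase
and ZT12 the start of the (subjective) dark phase under a 12:12 cycle.

Two wrinkles matter downstream:

* An entrainment protocol may switch LD -> DL mid-experiment ("photoperiod
  reversal") at ZT0 of ``reversal_day``.  From that instant the schedule's
  lights-on moves 12 h and ZT is referenced to the *new* lights-on, so the
  dark phase of the reversed schedule again spans ZT12-ZT24.
* Under DD there are no light transitions; "subjective" light and dark
  phases are carried over from the schedule the animal was entrained to
  before release into constant darkness (``lights_on`` stores that carried
  anchor).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

__all__ = ["Photoschedule"]

_REGIMES = ("LD", "DL", "DD")


@dataclass(frozen=True)
class Photoschedule:
    """Light regime with a fixed 24-h cycle.

    Parameters
    ----------
    regime:
        ``"LD"`` (12 h light then 12 h dark), ``"DL"`` (reversed) or ``"DD"``
        (constant darkness).
    lights_on:
        Clock hour in ``[0, 24)`` of lights-on.  Under DD this is the
        *subjective* lights-on carried from the prior entraining schedule.
    cycle_h:
        Zeitgeber cycle length; fixed at 24 h.
    reversal_day:
        If set (LD only), the day index at whose ZT0 the incubator switches
        to the reversed (DL) schedule.
    temperature_c:
        Temperature tag in degC; metadata only, no effect on timing.
    start:
        Day-0 reference datetime (the start of the recording).  Required to
        resolve ``reversal_day``; by convention experiments start at
        lights-on (ZT0).
    """

    regime: str
    lights_on: float = 6.0
    cycle_h: float = 24.0
    reversal_day: int | None = None
    temperature_c: float | None = None
    start: datetime | None = None

    def __post_init__(self) -> None:
        if self.regime not in _REGIMES:
            raise ValueError(f"regime must be one of {_REGIMES}, got {self.regime!r}")
        if not 0.0 <= self.lights_on < 24.0:
            raise ValueError(f"lights_on must be in [0, 24), got {self.lights_on}")
        if self.cycle_h != 24.0:
            raise ValueError("cycle_h is fixed at 24 h")
        if self.reversal_day is not None:
            if self.regime != "LD":
                raise ValueError("reversal_day is only valid for an LD->DL transition")
            if self.start is None:
                raise ValueError("a schedule with reversal_day needs a start datetime")
            if self.reversal_day < 1:
                raise ValueError("reversal_day must be >= 1")

    # ------------------------------------------------------------------ #

    @property
    def reversal_datetime(self) -> datetime | None:
        """Wall-clock instant of the LD->DL switch (ZT0 of ``reversal_day``)."""
        if self.reversal_day is None:
            return None
        day0 = self.start.replace(hour=0, minute=0, second=0, microsecond=0)
        base = day0 + timedelta(hours=self.lights_on)
        if base < self.start:  # recording started after that day's lights-on
            base += timedelta(days=1)
        return base + timedelta(days=self.reversal_day - self._day_offset())

    def _day_offset(self) -> int:
        # day 0 is the day the recording starts; lights-on of day 0 is the
        # first lights-on at or after `start` minus full days already elapsed
        return 0

    def regime_at(self, when: datetime) -> str:
        """Regime active at ``when`` (resolves a programmed reversal)."""
        rev = self.reversal_datetime
        if rev is not None and when >= rev:
            return "DL"
        return self.regime

    def lights_on_at(self, when: datetime) -> float:
        """Clock hour of (subjective) lights-on for the regime active at ``when``."""
        rev = self.reversal_datetime
        if rev is not None and when >= rev:
            return (self.lights_on + 12.0) % 24.0
        return self.lights_on

    def zt(self, when: datetime) -> float:
        """Zeitgeber time (h) of ``when`` under the regime active then."""
        clock_h = when.hour + when.minute / 60.0 + when.second / 3600.0
        return (clock_h - self.lights_on_at(when)) % 24.0

    def is_light(self, when: datetime) -> bool:
        """True if the lights are physically on at ``when`` (always False in DD)."""
        if self.regime == "DD":
            return False
        return self.zt(when) < 12.0

    def is_subjective_light(self, when: datetime) -> bool:
        """True during the (subjective) light phase: ZT in [0, 12)."""
        return self.zt(when) < 12.0

    # ------------------------ vectorized helpers ---------------------- #

    def minute_zt(self, start: datetime, n_minutes: int) -> np.ndarray:
        """ZT (h) of each of ``n_minutes`` consecutive minutes from ``start``."""
        clock0 = start.hour + start.minute / 60.0 + start.second / 3600.0
        clock = clock0 + np.arange(n_minutes) / 60.0
        zt = (clock - self.lights_on) % 24.0
        cut = self._reversal_minute(start)
        if cut is not None and cut < n_minutes:
            zt[max(cut, 0):] = (clock[max(cut, 0):] - (self.lights_on + 12.0)) % 24.0
        return zt

    def minute_is_dark(self, start: datetime, n_minutes: int) -> np.ndarray:
        """Per-minute dark-phase flags; DD uses the carried subjective phases."""
        return self.minute_zt(start, n_minutes) >= 12.0

    def _reversal_minute(self, start: datetime) -> int | None:
        rev = self.reversal_datetime
        if rev is None:
            return None
        return int(np.ceil((rev - start).total_seconds() / 60.0))
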