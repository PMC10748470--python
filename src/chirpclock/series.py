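"""Per-minute singing time series.

The behavioural unit of the whole pipeline is one value per elapsed minute:
1 if the individual sang at least once during that minute, 0 otherwise
(fractional values in [0, 1] appear only after averaging across individuals).
Gaps (equipment failure) and trimmed spans (acclimation, transients) are
*masked*, never deleted, so every series stays aligned to wall-clock time
and to Zeitgeber time.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .photoschedule import Photoschedule

__all__ = ["SingingSeries", "GroundTruthSeries"]

MINUTES_PER_DAY = 1440


@dataclass
class SingingSeries:
    """Minute-resolution singing series anchored to clock time.

    ``values`` holds one number per elapsed minute in ``[0, 1]``; ``mask``
    flags minutes excluded from every aggregate (True = missing/trimmed).
    """

    start: datetime
    values: np.ndarray
    schedule: Photoschedule
    id: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.mask is None:
            self.mask = np.zeros(self.values.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if self.mask.size != self.values.size:
            raise ValueError("mask and values must have the same length")
        finite = self.values[~self.mask]
        if finite.size and (np.nanmin(finite) < 0 or np.nanmax(finite) > 1):
            raise ValueError("singing values must lie in [0, 1]")

    # ------------------------------------------------------------------ #

    @property
    def n_minutes(self) -> int:
        return self.values.size

    @property
    def n_days(self) -> int:
        """Number of (possibly partial) calendar days covered."""
        return int(np.ceil(self.n_minutes / MINUTES_PER_DAY))

    def minute_datetimes(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_minutes, freq="min")

    def zt(self) -> np.ndarray:
        """Zeitgeber time (h) of each minute under the active regime."""
        return self.schedule.minute_zt(self.start, self.n_minutes)

    def is_dark(self) -> np.ndarray:
        """Dark-phase flag per minute (subjective phases under DD)."""
        return self.schedule.minute_is_dark(self.start, self.n_minutes)

    def day_index(self) -> np.ndarray:
        """Calendar day index per minute, counted from the series start."""
        return np.arange(self.n_minutes) // MINUTES_PER_DAY

    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def copy(self) -> "SingingSeries":
        return SingingSeries(
            start=self.start,
            values=self.values.copy(),
            schedule=self.schedule,
            id=self.id,
            mask=self.mask.copy(),
        )

    # --------------------------- I/O ---------------------------------- #

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.id,
                "datetime": self.minute_datetimes(),
                "minute_index": np.arange(self.n_minutes),
                "zt": np.round(self.zt(), 6),
                "value": self.values,
                "masked": self.mask.astype(int),
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, schedule: Photoschedule, id: str = ""
    ) -> "SingingSeries":
        frame = frame.sort_values("minute_index")
        start = pd.Timestamp(frame["datetime"].iloc[0]).to_pydatetime()
        mask = (
            frame["masked"].to_numpy(dtype=bool)
            if "masked" in frame
            else np.zeros(len(frame), dtype=bool)
        )
        return cls(
            start=start,
            values=frame["value"].to_numpy(dtype=float),
            schedule=schedule,
            id=id or (str(frame["id"].iloc[0]) if "id" in frame else ""),
            mask=mask,
        )


class GroundTruthSeries(SingingSeries):
    """Binary per-minute ground truth emitted by the simulator."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values[~self.mask]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("ground-truth values must be binary")
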