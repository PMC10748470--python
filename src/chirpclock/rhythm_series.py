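"""From clip predictions to per-minute rhythm series and their summaries.

Clips are 60 s, so classifier output maps 1:1 onto minutes.  All exclusions
— recording gaps, the 72-h acclimation trim, the 4 post-reversal transient
days — are masks over an intact minute grid, which keeps every series
aligned to Zeitgeber time (the original study retained gap-affected
individuals for the same reason).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd

from .photoschedule import Photoschedule
from .series import MINUTES_PER_DAY, SingingSeries

__all__ = [
    "Actogram",
    "binarize_scores",
    "trim_days",
    "singing_effort",
    "phase_activity_fraction",
    "average_group",
    "build_actogram",
    "polar_profile",
]


def binarize_scores(
    predictions: pd.DataFrame,
    schedule: Photoschedule,
    id: str = "",
    t_col: str = "t_start",
    value_col: str = "prediction",
) -> SingingSeries:
    """Assemble per-clip predictions into a per-minute series.

    The minute grid spans the first to the last predicted clip; minutes with
    no clip (equipment gaps) are masked and excluded from every aggregate.
    """
    if len(predictions) == 0:
        warnings.warn("empty prediction set: returning an empty series", stacklevel=2)
        start = schedule.start or datetime(1970, 1, 1)
        return SingingSeries(start=start, values=np.array([]), schedule=schedule, id=id)
    t = pd.to_datetime(predictions[t_col]).dt.floor("min")
    start = t.min().to_pydatetime()
    offsets = ((t - t.min()).dt.total_seconds() // 60).astype(int).to_numpy()
    n = int(offsets.max()) + 1
    values = np.zeros(n)
    mask = np.ones(n, dtype=bool)
    values[offsets] = predictions[value_col].to_numpy(dtype=float)
    mask[offsets] = False
    return SingingSeries(start=start, values=values, schedule=schedule, id=id, mask=mask)


def trim_days(
    series: SingingSeries,
    drop_start_h: float = 72.0,
    reversal_day: int | None = None,
    drop_post_reversal_d: int = 4,
) -> SingingSeries:
    """Mask the acclimation span and the post-reversal transient days.

    The first ``drop_start_h`` hours are masked (acclimation to the
    incubator), and — when the schedule has a programmed reversal — the
    ``drop_post_reversal_d`` days following it (transient cycles).  Masking
    preserves datetime alignment; nothing is deleted.
    """
    out = series.copy()
    n_drop = int(drop_start_h * 60)
    if n_drop >= out.n_minutes:
        raise ValueError(
            f"series of {out.n_minutes} min is shorter than the "
            f"{drop_start_h}-h acclimation trim"
        )
    out.mask[:n_drop] = True
    if reversal_day is None:
        reversal_day = series.schedule.reversal_day
    if reversal_day is not None:
        a = reversal_day * MINUTES_PER_DAY
        b = (reversal_day + drop_post_reversal_d) * MINUTES_PER_DAY
        out.mask[a:b] = True
    return out


def _day_has_data(series: SingingSeries) -> tuple[np.ndarray, np.ndarray]:
    days = series.day_index()
    ok = series.unmasked()
    day_ids = np.unique(days[ok])
    return days, day_ids


def singing_effort(series: SingingSeries) -> float:
    """Average hours per day containing at least one song per minute.

    Computed as total unmasked singing minutes divided by (60 x number of
    days with any unmasked data), so effort x days x 60 conserves the total
    singing-minute count exactly for a binary series.
    """
    days, day_ids = _day_has_data(series)
    if day_ids.size == 0:
        raise ValueError("no unmasked day: singing effort undefined")
    total = series.values[series.unmasked()].sum()
    return float(total / (60.0 * day_ids.size))


def phase_activity_fraction(
    series: SingingSeries, threshold: float = 1.0
) -> tuple[float, float]:
    """Fractions of dark-phase and light-phase minutes with singing.

    A minute counts when its value is >= ``threshold`` (for a binary
    individual series the default counts exact 1s).  Under DD the
    subjective phases carried from the prior schedule are used.
    """
    ok = series.unmasked()
    dark = series.is_dark()
    singing = series.values >= threshold

    def _frac(sel: np.ndarray) -> float:
        n = np.count_nonzero(sel & ok)
        return float(np.count_nonzero(sel & ok & singing) / n) if n else float("nan")

    return _frac(dark), _frac(~dark)


def average_group(series_list: list[SingingSeries], id: str = "") -> SingingSeries:
    """Per-minute mean across individuals with unmasked data at that minute."""
    if not series_list:
        raise ValueError("need at least one series")
    first = series_list[0]
    for s in series_list[1:]:
        if s.start != first.start or s.n_minutes != first.n_minutes:
            raise ValueError("group members must share an identical time base")
    if len(series_list) == 1:
        out = first.copy()
        out.id = id or out.id
        return out
    values = np.stack([s.values for s in series_list])
    ok = np.stack([s.unmasked() for s in series_list])
    count = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, (values * ok).sum(axis=0) / np.maximum(count, 1), 0.0)
    return SingingSeries(
        start=first.start,
        values=mean,
        schedule=first.schedule,
        id=id or "+".join(s.id for s in series_list if s.id),
        mask=count == 0,
    )


@dataclass
class Actogram:
    """Double-plotted actogram: row *d* shows days *d* and *d + 1* over 48 h."""

    matrix: np.ndarray  # (rows, 2880), NaN where masked/absent
    start: datetime
    bin_min: int = 1

    def double_plot_identity(self) -> bool:
        """Row d's right half equals row d+1's left half (NaN-tolerant)."""
        half = self.matrix.shape[1] // 2
        for d in range(self.matrix.shape[0] - 1):
            a, b = self.matrix[d, half:], self.matrix[d + 1, :half]
            both = ~(np.isnan(a) | np.isnan(b))
            if not np.array_equal(a[both], b[both]) or not np.array_equal(
                np.isnan(a), np.isnan(b)
            ):
                return False
        return True


def build_actogram(series: SingingSeries) -> Actogram:
    """Fold a series into the conventional double-plotted day x 48-h raster."""
    n_days = series.n_days
    padded = np.full(n_days * MINUTES_PER_DAY, np.nan)
    padded[: series.n_minutes] = np.where(series.mask, np.nan, series.values)
    daily = padded.reshape(n_days, MINUTES_PER_DAY)
    rows = max(n_days - 1, 1)
    matrix = np.full((rows, 2 * MINUTES_PER_DAY), np.nan)
    for d in range(rows):
        matrix[d, :MINUTES_PER_DAY] = daily[d]
        if d + 1 < n_days:
            matrix[d, MINUTES_PER_DAY:] = daily[d + 1]
    return Actogram(matrix=matrix, start=series.start)


def polar_profile(
    series: SingingSeries, bin_min: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Mean singing value per ZT bin, wrapped over all days.

    Returns ``(bin_edges_zt, profile)`` with ``24 * 60 / bin_min`` bins
    (left edges, in ZT hours); empty bins are NaN.
    """
    n_bins = (24 * 60) // bin_min
    zt = series.zt()
    ok = series.unmasked()
    bins = np.minimum((zt * 60 / bin_min + 1e-6).astype(int), n_bins - 1)
    sums = np.bincount(bins[ok], weights=series.values[ok], minlength=n_bins)
    counts = np.bincount(bins[ok], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins) * bin_min / 60.0
    return edges, profile
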