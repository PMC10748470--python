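"""Circadian statistics: periods, phase markers, circular summaries, shifts.

Period estimation uses the classic normalized Lomb-Scargle periodogram,
which handles the irregular sampling left by masked minutes and supports an
analytic significance test: under the white-noise null each normalized
power is exponentially distributed, so with ``M`` independent frequencies
the alpha-level threshold is ``z* = -ln(1 - (1 - alpha)^(1/M))``.

Phase markers follow the standard actimetry rule: for each Zeitgeber day,
*peak* is the maximum of the (binned, smoothed) activity profile, and
*onset*/*offset* are where activity crosses 20% of that peak before and
after it (linear interpolation between bins, circular search up to 24 h).
Onset takes the *last* upward crossing before the peak so that sporadic
pre-onset chirps do not drag it early.

Phases are circular quantities; dispersion across days or individuals is
the angular variance ``V_m = 1 - R``, with ``R`` the mean resultant length
(0 = perfectly concentrated, 1 = uniform on the 24-h circle).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .series import SingingSeries

__all__ = [
    "Periodogram",
    "PhaseMarkers",
    "CircularSummary",
    "PhaseShiftResult",
    "ls_power",
    "lomb_scargle",
    "ls_significance_threshold",
    "phase_markers",
    "circular_mean",
    "mean_resultant_length",
    "angular_variance",
    "summarize_phases",
    "phase_shift",
    "period_summary",
    "permutation_period_test",
]


# --------------------------------------------------------------------------- #
# Lomb-Scargle
# --------------------------------------------------------------------------- #


def ls_power(t: np.ndarray, y: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """Classic normalized Lomb-Scargle power at the given periods.

    ``t`` and ``periods`` share one unit (hours here).  The data are
    centered and the power normalized by the sample variance (ddof=1), so a
    pure-noise power is asymptotically Exp(1)-distributed.  An all-constant
    series returns zero power everywhere.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    periods = np.asarray(periods, dtype=float)
    y = y - y.mean()
    var = y.var(ddof=1) if y.size > 1 else 0.0
    if var <= 0.0:
        return np.zeros(periods.size)
    power = np.empty(periods.size)
    for i, p in enumerate(periods):
        w = 2.0 * np.pi / p
        tau = np.arctan2(np.sum(np.sin(2 * w * t)), np.sum(np.cos(2 * w * t))) / (2 * w)
        c = np.cos(w * (t - tau))
        s = np.sin(w * (t - tau))
        power[i] = ((y @ c) ** 2 / (c @ c) + (y @ s) ** 2 / (s @ s)) / (2.0 * var)
    return power


def ls_significance_threshold(
    alpha: float = 0.05,
    M: int | None = None,
    span_h: float | None = None,
    period_range: tuple[float, float] | None = None,
) -> float:
    """Power threshold ``z*`` for rhythmicity at level ``alpha``.

    ``z* = -ln(1 - (1 - alpha)^(1/M))`` where ``M`` is the number of
    independent frequencies tested.  When ``M`` is not given it is
    estimated as the count of independent Fourier frequencies in the tested
    range, ``round(span * (1/p_min - 1/p_max))`` (a Horne-Baliunas-style
    estimate restricted to the search band), never less than 1.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if M is None:
        if span_h is None or period_range is None:
            raise ValueError("provide M or (span_h, period_range)")
        p_lo, p_hi = sorted(period_range)
        M = max(1, int(round(span_h * (1.0 / p_lo - 1.0 / p_hi))))
    if M < 1:
        raise ValueError("M must be >= 1")
    return float(-np.log1p(-((1.0 - alpha) ** (1.0 / M))))


@dataclass
class Periodogram:
    """Normalized LS power over a period grid with its significance cutoff."""

    period_h: np.ndarray
    power: np.ndarray
    alpha: float
    threshold: float
    M: int
    id: str = ""

    @property
    def best_period(self) -> float:
        """Period of maximal power (the accepted estimate when rhythmic)."""
        return float(self.period_h[int(np.argmax(self.power))])

    @property
    def peak_power(self) -> float:
        return float(self.power.max())

    @property
    def is_rhythmic(self) -> bool:
        return bool(np.any(self.power > self.threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period_h": self.period_h,
                "power": self.power,
                "threshold": self.threshold,
                "significant": self.power > self.threshold,
            }
        )


def lomb_scargle(
    series: SingingSeries,
    period_range: tuple[float, float] = (18.0, 30.0),
    step_h: float = 0.02,
    alpha: float = 0.05,
) -> Periodogram:
    """LS periodogram of a (possibly masked) per-minute series.

    The period grid is uniform in period with ``step_h`` spacing (default
    0.02 h, well under the 0.05-h accuracy wanted near 24 h).  Requires at
    least three cycles of unmasked data at the longest candidate period.
    """
    ok = series.unmasked()
    t = np.arange(series.n_minutes)[ok] / 60.0
    y = series.values[ok]
    p_lo, p_hi = sorted(period_range)
    if t.size == 0 or (t.max() - t.min()) < 3.0 * p_hi:
        raise ValueError(
            f"need >= 3 cycles ({3 * p_hi:.0f} h) of unmasked data, "
            f"have {0.0 if t.size == 0 else t.max() - t.min():.0f} h"
        )
    periods = np.arange(p_lo, p_hi + step_h / 2, step_h)
    power = ls_power(t, y, periods)
    thr = ls_significance_threshold(
        alpha=alpha, span_h=float(t.max() - t.min()), period_range=(p_lo, p_hi)
    )
    M = max(1, int(round((t.max() - t.min()) * (1.0 / p_lo - 1.0 / p_hi))))
    return Periodogram(
        period_h=periods, power=power, alpha=alpha, threshold=thr, M=M, id=series.id
    )


# --------------------------------------------------------------------------- #
# phase markers
# --------------------------------------------------------------------------- #


@dataclass
class PhaseMarkers:
    """Per-day onset/peak/offset (ZT h); NaN where not confidently estimable."""

    table: pd.DataFrame  # columns: day, onset_zt, peak_zt, offset_zt, peak_value
    bin_min: int
    smooth_window_bins: int

    def defined(self, marker: str) -> np.ndarray:
        col = self.table[f"{marker}_zt"]
        return col[col.notna()].to_numpy()


def _zt_day_index(zt: np.ndarray) -> np.ndarray:
    """Day counter incremented at each ZT0 wrap."""
    wraps = np.zeros(zt.size, dtype=int)
    if zt.size > 1:
        wraps[1:] = np.diff(zt) < -18.0
    return np.cumsum(wraps)


def _circular_smooth(profile: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return profile
    if window % 2 == 0:
        raise ValueError("smooth_window_bins must be odd")
    kernel = np.ones(window) / window
    ext = np.concatenate([profile[-(window // 2):], profile, profile[: window // 2]])
    return np.convolve(ext, kernel, mode="valid")


def _day_markers(
    pos: np.ndarray, prof: np.ndarray, bin_h: float, min_peak: float
) -> tuple[float, float, float, float]:
    n = prof.size
    idx = int(np.argmax(prof))
    peak_val = float(prof[idx])
    if peak_val <= min_peak:
        return np.nan, np.nan, np.nan, peak_val
    thr = 0.2 * peak_val
    onset = offset = np.nan
    # last upward crossing before the peak, circular, <= 24 h back
    for k in range(1, n):
        prev, cur = (idx - k) % n, (idx - k + 1) % n
        if prof[prev] < thr <= prof[cur]:
            frac = (thr - prof[prev]) / (prof[cur] - prof[prev])
            onset = (pos[prev] + frac * bin_h) % 24.0
            break
    # first downward crossing after the peak
    for k in range(1, n):
        cur, nxt = (idx + k - 1) % n, (idx + k) % n
        if prof[cur] >= thr > prof[nxt]:
            frac = (prof[cur] - thr) / (prof[cur] - prof[nxt])
            offset = (pos[cur] + frac * bin_h) % 24.0
            break
    return onset, float(pos[idx]), offset, peak_val


def phase_markers(
    series: SingingSeries,
    bin_min: int = 30,
    smooth_window_bins: int = 3,
    min_peak: float = 0.0,
    align: str = "center",
) -> PhaseMarkers:
    """Daily onset/peak/offset by the 20%-of-peak rule.

    Each ZT day's activity is binned to ``bin_min`` minutes, circularly
    smoothed by a centered moving average over ``smooth_window_bins`` bins,
    and scanned for the peak and its 20% crossings.  Days without full bin
    coverage, or whose peak does not exceed ``min_peak``, get NaN markers —
    missing, never fabricated.

    ``align`` places each bin's value at its center (default; unbiased for
    binned averages) or at its left edge (``"left"``; appropriate when the
    series already holds profile samples, e.g. minute-resolution shapes).
    """
    if (24 * 60) % bin_min:
        raise ValueError("bin_min must divide 1440")
    if align not in ("center", "left"):
        raise ValueError("align must be 'center' or 'left'")
    n_bins = (24 * 60) // bin_min
    bin_h = bin_min / 60.0
    zt = series.zt()
    day = _zt_day_index(zt)
    ok = series.unmasked()
    # epsilon guards against fp jitter in zt pushing minute samples into the
    # neighboring bin
    bins = np.minimum((zt * 60 / bin_min + 1e-6).astype(int), n_bins - 1)
    pos = np.arange(n_bins) * bin_h + (bin_h / 2.0 if align == "center" else 0.0)

    rows = []
    for d in np.unique(day):
        sel = (day == d) & ok
        counts = np.bincount(bins[sel], minlength=n_bins)
        if np.any(counts == 0):  # partial or gappy day: not confidently estimable
            rows.append((int(d), np.nan, np.nan, np.nan, np.nan))
            continue
        sums = np.bincount(bins[sel], weights=series.values[sel], minlength=n_bins)
        prof = _circular_smooth(sums / counts, smooth_window_bins)
        onset, peak, offset, peak_val = _day_markers(pos, prof, bin_h, min_peak)
        rows.append((int(d), onset, peak, offset, peak_val))
    table = pd.DataFrame(
        rows, columns=["day", "onset_zt", "peak_zt", "offset_zt", "peak_value"]
    )
    return PhaseMarkers(table=table, bin_min=bin_min, smooth_window_bins=smooth_window_bins)


# --------------------------------------------------------------------------- #
# circular statistics
# --------------------------------------------------------------------------- #


def _to_angles(hours: np.ndarray, period: float = 24.0) -> np.ndarray:
    return np.asarray(hours, dtype=float) * 2.0 * np.pi / period


def circular_mean(hours: Sequence[float], period: float = 24.0) -> float:
    """Circular mean of clock hours, mapped back to ``[0, period)``."""
    a = _to_angles(hours, period)
    if a.size == 0:
        raise ValueError("circular mean of an empty set")
    mean_angle = np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))
    return float((mean_angle * period / (2.0 * np.pi)) % period)


def mean_resultant_length(hours: Sequence[float], period: float = 24.0) -> float:
    a = _to_angles(hours, period)
    if a.size == 0:
        raise ValueError("resultant of an empty set")
    return float(np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a))))


def angular_variance(hours: Sequence[float], period: float = 24.0) -> float:
    """``V_m = 1 - R``: 0 for identical phases, 1 for balanced (uniform) ones."""
    return 1.0 - mean_resultant_length(hours, period)


@dataclass
class CircularSummary:
    mean_h: float
    R: float
    V_m: float
    n: int


def summarize_phases(hours: Sequence[float], period: float = 24.0) -> CircularSummary:
    hours = np.asarray([h for h in np.asarray(hours, dtype=float) if np.isfinite(h)])
    R = mean_resultant_length(hours, period)
    return CircularSummary(
        mean_h=circular_mean(hours, period), R=R, V_m=1.0 - R, n=hours.size
    )


def _wrap_half(x: float, period: float = 24.0) -> float:
    """Wrap a circular difference into ``(-period/2, period/2]``."""
    w = (x + period / 2.0) % period - period / 2.0
    return period / 2.0 if w == -period / 2.0 else w


@dataclass
class PhaseShiftResult:
    shift_h: float  # advance > 0, delay < 0 (shortest arc)
    p_value: float
    pre: CircularSummary
    post: CircularSummary
    n_permutations: int


def phase_shift(
    pre_hours: Sequence[float],
    post_hours: Sequence[float],
    n_permutations: int = 10000,
    seed: int = 0,
) -> PhaseShiftResult:
    """Signed phase shift between two marker samples, with a permutation test.

    The shift is the shortest-arc circular difference between the two
    circular means, each in its own regime's ZT frame; positive = phase
    advance (the post-regime marker occurs earlier).  The permutation test
    shuffles regime labels over the pooled day-level markers.
    """
    pre = np.asarray([h for h in np.asarray(pre_hours, float) if np.isfinite(h)])
    post = np.asarray([h for h in np.asarray(post_hours, float) if np.isfinite(h)])
    if pre.size == 0 or post.size == 0:
        raise ValueError("need at least one defined marker per side")
    shift = _wrap_half(circular_mean(pre) - circular_mean(post))

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([pre, post])
    n_pre = pre.size
    observed = abs(shift)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = abs(_wrap_half(circular_mean(perm[:n_pre]) - circular_mean(perm[n_pre:])))
        if stat >= observed - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PhaseShiftResult(
        shift_h=float(shift),
        p_value=float(p),
        pre=summarize_phases(pre),
        post=summarize_phases(post),
        n_permutations=n_permutations,
    )


# --------------------------------------------------------------------------- #
# group period summaries
# --------------------------------------------------------------------------- #


def period_summary(periods_by_group: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-group mean +/- SE of best periods, plus a pooled row."""
    rows = []
    pooled: list[float] = []
    for group, vals in periods_by_group.items():
        v = np.asarray(list(vals), dtype=float)
        pooled.extend(v)
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append({"group": str(group), "n": v.size, "mean_h": float(v.mean()), "se_h": se})
    v = np.asarray(pooled)
    rows.append(
        {
            "group": "pooled",
            "n": v.size,
            "mean_h": float(v.mean()),
            "se_h": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def permutation_period_test(
    periods_by_group: Mapping[str, Sequence[float]],
    n_permutations: int = 2000,
    seed: int = 0,
) -> float:
    """Permutation p-value for equality of group period distributions.

    Statistic: weighted between-group sum of squares of group means.
    Labels are shuffled over the pooled periods.
    """
    groups = [np.asarray(list(v), dtype=float) for v in periods_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)

    def stat(values: np.ndarray) -> float:
        grand = values.mean()
        total, i = 0.0, 0
        for n in sizes:
            total += n * (values[i : i + n].mean() - grand) ** 2
            i += n
        return total

    observed = stat(pooled)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if stat(rng.permutation(pooled)) >= observed - 1e-12:
            hits += 1
    return float((hits + 1) / (n_permutations + 1))
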