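"""Synthetic cricket song: circadian singing schedules, audio clips, protocols.

Every downstream stage of the pipeline (ingestion, feature extraction,
classification, rhythm and circadian analysis) is validated against data
whose generating parameters are known.  This module produces that data at
three levels:

1. :func:`simulate_series` — per-minute binary ground truth singing driven by
   a parametric circadian oscillator: a nocturnal singing window anchored to
   Zeitgeber time under entrained regimes (LD/DL), drifting at
   ``period_h − 24`` h per cycle under constant darkness, and re-entraining
   over a configurable transient after a programmed photoperiod reversal.
2. :func:`synthesize_clip` — 60-s audio clips of *Teleogryllus oceanicus*-like
   calling song (a 4-5 kHz carrier shaped into a long chirp followed by a
   train of short chirps) embedded at a configurable SNR in incubator-like
   background (broadband Gaussian noise plus a narrowband hum).
3. :func:`simulate_experiment` — the three experimental protocols: reversed
   photoperiod at constant temperature, constant darkness at three
   temperatures, and an LD schedule reversed to DL at ZT0 of day 9.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical inputs give identical outputs,
including byte-identical CSV files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .photoschedule import Photoschedule
from .series import GroundTruthSeries, MINUTES_PER_DAY

__all__ = [
    "SongScheduleParams",
    "ChirpParams",
    "ExperimentProtocol",
    "GroupSpec",
    "SimulatedExperiment",
    "simulate_series",
    "synthesize_clip",
    "simulate_experiment",
    "experiment_1",
    "experiment_2",
    "experiment_3",
]

logger = logging.getLogger(__name__)

SAMPLE_RATE = 44100


# --------------------------------------------------------------------------- #
# parameters
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SongScheduleParams:
    """Parameters of one individual's circadian singing schedule.

    The singing window ``[onset_zt, offset_zt)`` is circular on the 24-h ZT
    scale.  Inside the window a minute contains song with probability
    ``p_sing`` (optionally shaped by a smooth bump profile), outside with
    probability ``p_noise_sing``.  ``period_h`` is the free-running period
    expressed under DD (entrained regimes follow the Zeitgeber exactly).

    Defaults reproduce the observed study conditions: window ZT 13.06-23.91,
    ``p_sing = 0.75`` so that the expected dark-phase singing fraction is
    ~0.68, and 1% sporadic singing in the light phase.
    """

    period_h: float = 24.0
    onset_zt: float = 13.06
    offset_zt: float = 23.91
    p_sing: float = 0.75
    p_noise_sing: float = 0.01
    seed: int = 0
    profile: str = "boxcar"  # "boxcar" | "bump"
    transient_days: int = 4
    onset_zt_post: float | None = None  # window after LD->DL reversal
    offset_zt_post: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_noise_sing <= self.p_sing <= 1.0:
            raise ValueError("need 0 <= p_noise_sing <= p_sing <= 1")
        if not 18.0 <= self.period_h <= 30.0:
            raise ValueError("period_h must lie in [18, 30] h")
        for name, val in (("onset_zt", self.onset_zt), ("offset_zt", self.offset_zt)):
            if not 0.0 <= val <= 24.0:
                raise ValueError(f"{name} must lie in [0, 24], got {val}")
        if self.profile not in ("boxcar", "bump"):
            raise ValueError("profile must be 'boxcar' or 'bump'")
        if self.transient_days < 1:
            raise ValueError("transient_days must be >= 1")


@dataclass(frozen=True)
class ChirpParams:
    """Acoustic parameters of synthesized calling song and background.

    ``snr_db`` is the RMS of the chirp carrier relative to the broadband
    noise RMS, in dB.  ``amplitude`` is a master linear gain applied to the
    finished clip (signal and noise alike), so clip RMS scales linearly with
    it.  The hum component models narrowband electromagnetic/fan noise.
    """

    dominant_freq_hz: float = 4500.0
    long_chirp_s: float = 0.45
    n_short_chirps: int = 4
    short_chirp_s: float = 0.15
    gap_s: float = 0.12
    amplitude: float = 0.8
    snr_db: float = 15.0
    hum_freq_hz: float = 50.0
    sample_rate: int = SAMPLE_RATE
    noise_rms: float = 0.03
    hum_rms: float = 0.01
    pulse_rate_hz: float = 25.0
    bouts_per_min: float = 6.0

    def __post_init__(self) -> None:
        if not 3000.0 <= self.dominant_freq_hz <= 6000.0:
            raise ValueError("dominant_freq_hz must lie in [3000, 6000] Hz")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.sample_rate != SAMPLE_RATE:
            raise ValueError(f"sample_rate is fixed at {SAMPLE_RATE} Hz")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")


# --------------------------------------------------------------------------- #
# per-minute ground truth
# --------------------------------------------------------------------------- #


def _window_width(onset: float, offset: float) -> float:
    width = (offset - onset) % 24.0
    if width == 0.0 and offset != onset:
        width = 24.0
    return width


def simulate_series(
    params: SongScheduleParams,
    sched: Photoschedule,
    days: int,
    seed: int | None = None,
    individual_id: str = "",
    start: datetime | None = None,
) -> GroundTruthSeries:
    """Draw a binary per-minute ground-truth singing series.

    Under LD/DL the singing window is anchored to the active regime's ZT; a
    programmed reversal re-anchors it to the new lights-off after a linear
    per-day phase delay spread over ``params.transient_days`` days.  Under DD
    the circadian phase advances 24 h per ``period_h`` wall hours, so the
    window drifts by ``period_h − 24`` h per cycle.

    Reproducible: the same ``(params, sched, days, seed)`` always return the
    same series.  ``seed`` overrides ``params.seed`` when given.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if start is None:
        start = sched.start
    if start is None:
        raise ValueError("need a start datetime (on the schedule or explicit)")

    n = days * MINUTES_PER_DAY
    rng = np.random.default_rng(params.seed if seed is None else seed)

    onset = np.full(n, params.onset_zt)
    offset = np.full(n, params.offset_zt)

    if sched.regime == "DD":
        zt0 = sched.zt(start)
        t_h = np.arange(n) / 60.0
        phase = (zt0 + t_h * 24.0 / params.period_h) % 24.0
    else:
        phase = sched.minute_zt(start, n)
        cut = sched._reversal_minute(start)
        if cut is not None and cut < n:
            post = np.arange(n) >= max(cut, 0)
            # transient re-entrainment: the window starts 12 h early in the
            # new ZT frame (i.e. at its old wall-clock position) and delays
            # linearly day by day until aligned
            k = (np.arange(n) - cut) // MINUTES_PER_DAY
            shift = 12.0 * np.clip(1.0 - k / params.transient_days, 0.0, 1.0)
            phase = np.where(post, (phase + shift) % 24.0, phase)
            if params.onset_zt_post is not None:
                onset = np.where(post, params.onset_zt_post, onset)
            if params.offset_zt_post is not None:
                offset = np.where(post, params.offset_zt_post, offset)

    width_pre = _window_width(params.onset_zt, params.offset_zt)
    width_post = _window_width(
        params.onset_zt_post if params.onset_zt_post is not None else params.onset_zt,
        params.offset_zt_post if params.offset_zt_post is not None else params.offset_zt,
    )
    width_arr = np.where(onset == params.onset_zt, width_pre, width_post)
    rel = (phase - onset) % 24.0
    inside = rel < width_arr

    if params.profile == "boxcar":
        shape = 1.0
    else:  # smooth raised-cosine bump peaking at the window centre
        with np.errstate(invalid="ignore", divide="ignore"):
            shape = 0.5 * (1.0 - np.cos(2.0 * np.pi * rel / np.maximum(width_arr, 1e-9)))
    p = np.where(inside, params.p_sing * shape, params.p_noise_sing)

    values = (rng.random(n) < p).astype(float)
    return GroundTruthSeries(
        start=start, values=values, schedule=sched, id=individual_id
    )


# --------------------------------------------------------------------------- #
# audio synthesis
# --------------------------------------------------------------------------- #


def _chirp_env(n_on: int, sr: int, edge_s: float = 0.005) -> np.ndarray:
    """Unit envelope with raised-cosine on/off edges."""
    env = np.ones(n_on)
    n_edge = min(int(edge_s * sr), n_on // 2)
    if n_edge > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_edge) / n_edge))
        env[:n_edge] = ramp
        env[-n_edge:] = ramp[::-1]
    return env


def _bout_waveform(chirp: ChirpParams, rng: np.random.Generator) -> np.ndarray:
    """One song bout: long chirp, then a train of short chirps; unit peak."""
    sr = chirp.sample_rate
    segs: list[np.ndarray] = []
    gap = np.zeros(int(chirp.gap_s * sr))
    durations = [chirp.long_chirp_s] + [chirp.short_chirp_s] * chirp.n_short_chirps
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    for i, dur in enumerate(durations):
        n_on = max(int(dur * sr), 1)
        t = np.arange(n_on) / sr
        carrier = np.sin(2.0 * np.pi * chirp.dominant_freq_hz * t + phase0)
        # syllable-like amplitude modulation within the chirp
        am = 0.7 + 0.3 * np.cos(2.0 * np.pi * chirp.pulse_rate_hz * t)
        segs.append(_chirp_env(n_on, sr) * am * carrier)
        if i < len(durations) - 1:
            segs.append(gap)
    return np.concatenate(segs)


def synthesize_clip(
    state: int,
    chirp: ChirpParams | None = None,
    duration_s: float = 60.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize one mono audio clip at 44.1 kHz.

    ``state=1`` embeds at least one song bout at random offsets over the
    background; ``state=0`` returns background (noise + hum) only.  Samples
    are float in [-1, 1], ``duration_s * sample_rate`` of them.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    chirp = chirp or ChirpParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    sr = chirp.sample_rate
    n = int(round(duration_s * sr))

    x = np.zeros(n)
    if chirp.noise_rms > 0:
        x += chirp.noise_rms * rng.standard_normal(n)
    if chirp.hum_rms > 0:
        t = np.arange(n) / sr
        x += (
            np.sqrt(2.0)
            * chirp.hum_rms
            * np.sin(2.0 * np.pi * chirp.hum_freq_hz * t + rng.uniform(0, 2 * np.pi))
        )

    if state:
        ref_rms = chirp.noise_rms if chirp.noise_rms > 0 else 0.05
        peak = np.sqrt(2.0) * ref_rms * 10.0 ** (chirp.snr_db / 20.0)
        n_bouts = max(1, int(rng.poisson(chirp.bouts_per_min * duration_s / 60.0)))
        for _ in range(n_bouts):
            bout = peak * _bout_waveform(chirp, rng)
            if bout.size >= n:
                x[:n] += bout[:n]
                continue
            at = int(rng.integers(0, n - bout.size))
            x[at : at + bout.size] += bout

    x *= chirp.amplitude
    np.clip(x, -1.0, 1.0, out=x)
    return x


# --------------------------------------------------------------------------- #
# experiment protocols
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group: regime template, temperature tag, group size."""

    regime: str  # "LD", "DL", "DD" ("LD" with a reversal day models LD->DL)
    temperature_c: float
    n: int
    reversal_day: int | None = None


@dataclass(frozen=True)
class ExperimentProtocol:
    """A full recording protocol plus per-individual parameter distributions.

    Individual schedule parameters are drawn once per cricket: window bounds
    ~ Normal(onset/offset mean, sd), singing probability ~ Normal truncated
    to [0.3, 0.95], and (under DD) free-running period ~ Normal(period mean,
    sd) truncated to [24.2, 26.0].
    """

    name: str
    groups: tuple[GroupSpec, ...]
    days: int
    rearing_lights_on: float = 6.0
    start: datetime = datetime(2022, 6, 1, 6, 0)
    onset_mean: float = 13.06
    onset_sd: float = 0.8
    offset_mean: float = 23.91
    offset_sd: float = 0.8
    p_sing_mean: float = 0.75
    p_sing_sd: float = 0.10
    p_noise_sing: float = 0.01
    period_mean: float = 24.0
    period_sd: float = 0.0
    profile: str = "boxcar"
    dl_advance_onset_h: float = 0.0  # post-reversal window advance (earlier)
    dl_advance_offset_h: float = 0.0

    @property
    def n_individuals(self) -> int:
        return sum(g.n for g in self.groups)


def experiment_1(days: int = 8, n: int = 4) -> ExperimentProtocol:
    """Reversed photoperiod (DL) at 25 degC: nocturnality and entrained period."""
    return ExperimentProtocol(
        name="experiment_1",
        groups=(GroupSpec(regime="DL", temperature_c=25.0, n=n),),
        days=days,
    )


def experiment_2(
    days: int = 8, n_by_temp: dict[float, int] | None = None, period_mean: float = 25.1
) -> ExperimentProtocol:
    """Constant darkness at 22/25/28 degC: free run and temperature compensation."""
    n_by_temp = n_by_temp or {22.0: 5, 25.0: 4, 28.0: 5}
    return ExperimentProtocol(
        name="experiment_2",
        groups=tuple(
            GroupSpec(regime="DD", temperature_c=t, n=n) for t, n in n_by_temp.items()
        ),
        days=days,
        period_mean=period_mean,
        period_sd=0.25,
    )


def experiment_3(
    days_ld: int = 9, days_dl: int = 8, n_by_temp: dict[float, int] | None = None
) -> ExperimentProtocol:
    """LD then photoperiod reversal to DL at ZT0 of day ``days_ld``.

    The post-reversal window sits ~1 h (onset) / ~2 h (offset) earlier in the
    new ZT frame, emulating the phase advance observed upon reversal.
    """
    n_by_temp = n_by_temp or {22.0: 8, 25.0: 6, 28.0: 8}
    return ExperimentProtocol(
        name="experiment_3",
        groups=tuple(
            GroupSpec(regime="LD", temperature_c=t, n=n, reversal_day=days_ld)
            for t, n in n_by_temp.items()
        ),
        days=days_ld + days_dl,
        dl_advance_onset_h=0.97,
        dl_advance_offset_h=2.08,
    )


@dataclass
class SimulatedExperiment:
    """In-memory result of :func:`simulate_experiment`."""

    protocol: ExperimentProtocol
    series: list[GroundTruthSeries]
    params: dict[str, SongScheduleParams]
    metadata: pd.DataFrame
    truth: pd.DataFrame
    clip_labels: pd.DataFrame | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def _individual_schedule(
    proto: ExperimentProtocol, group: GroupSpec
) -> Photoschedule:
    if group.regime == "DD":
        # subjective phases carried over from rearing
        return Photoschedule(
            "DD",
            lights_on=proto.rearing_lights_on,
            temperature_c=group.temperature_c,
            start=proto.start,
        )
    if group.regime == "DL":
        lights_on = (proto.rearing_lights_on + 12.0) % 24.0
        start = proto.start.replace(hour=int(lights_on), minute=0)
        return Photoschedule(
            "DL", lights_on=lights_on, temperature_c=group.temperature_c, start=start
        )
    return Photoschedule(
        "LD",
        lights_on=proto.rearing_lights_on,
        temperature_c=group.temperature_c,
        reversal_day=group.reversal_day,
        start=proto.start,
    )


def _draw_params(
    proto: ExperimentProtocol, group: GroupSpec, rng: np.random.Generator, seed: int
) -> SongScheduleParams:
    onset = float(np.clip(rng.normal(proto.onset_mean, proto.onset_sd), 12.0, 16.0))
    offset = float(np.clip(rng.normal(proto.offset_mean, proto.offset_sd), 20.0, 24.0))
    p_sing = float(np.clip(rng.normal(proto.p_sing_mean, proto.p_sing_sd), 0.3, 0.95))
    if group.regime == "DD" and proto.period_sd >= 0:
        period = float(np.clip(rng.normal(proto.period_mean, proto.period_sd), 24.2, 26.0))
    else:
        period = 24.0
    kwargs: dict = {}
    if group.reversal_day is not None:
        kwargs["onset_zt_post"] = (onset - proto.dl_advance_onset_h) % 24.0
        kwargs["offset_zt_post"] = (offset - proto.dl_advance_offset_h) % 24.0
    return SongScheduleParams(
        period_h=period,
        onset_zt=onset,
        offset_zt=offset,
        p_sing=p_sing,
        p_noise_sing=proto.p_noise_sing,
        seed=seed,
        profile=proto.profile,
        **kwargs,
    )


def simulate_experiment(
    protocol: ExperimentProtocol,
    out_dir: str | Path | None = None,
    seed: int = 0,
    series_only: bool = True,
    clips_per_individual: int = 12,
    chirp: ChirpParams | None = None,
) -> SimulatedExperiment:
    """Run a protocol for every individual and (optionally) write files.

    Series-only mode (the default) emits the per-minute ground-truth CSV and
    a metadata CSV; audio mode additionally synthesizes a bounded number of
    labeled 60-s WAV clips per individual (half singing, half background,
    where available) for classifier work.  Full-experiment audio is out of
    desk scale by design.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(protocol.n_individuals)

    series: list[GroundTruthSeries] = []
    params: dict[str, SongScheduleParams] = {}
    meta_rows: list[dict] = []
    idx = 0
    for g_i, group in enumerate(protocol.groups):
        sched = _individual_schedule(protocol, group)
        for _ in range(group.n):
            child = children[idx]
            rng = np.random.default_rng(child)
            ind_seed = int(child.generate_state(1)[0] % (2**31))
            cid = f"c{idx + 1:02d}"
            p = _draw_params(protocol, group, rng, ind_seed)
            s = simulate_series(p, sched, protocol.days, individual_id=cid)
            series.append(s)
            params[cid] = p
            incubator = "panasonic" if idx % 2 == 0 else "leec"
            segments = [(sched.regime, sched.lights_on, s.start)]
            rev = sched.reversal_datetime
            if rev is not None:
                segments.append(("DL", (sched.lights_on + 12.0) % 24.0, rev))
            for regime, lights_on, seg_start in segments:
                meta_rows.append(
                    {
                        "file": "truth.csv",
                        "individual_id": cid,
                        "start_datetime": seg_start.isoformat(),
                        "regime": regime,
                        "lights_on": lights_on,
                        "temperature_c": group.temperature_c,
                        "incubator": incubator,
                    }
                )
            idx += 1

    truth = pd.concat([s.to_frame() for s in series], ignore_index=True)
    truth = truth.rename(columns={"id": "individual_id", "value": "singing"})
    truth["singing"] = truth["singing"].astype(int)
    truth = truth[["individual_id", "datetime", "minute_index", "singing"]]
    metadata = pd.DataFrame(meta_rows)

    clip_labels: pd.DataFrame | None = None
    paths: dict[str, Path] = {}
    result = SimulatedExperiment(
        protocol=protocol,
        series=series,
        params=params,
        metadata=metadata,
        truth=truth,
        paths=paths,
    )

    if not series_only:
        clip_labels = _emit_clips(
            result, children, clips_per_individual, chirp or ChirpParams(), out_dir
        )
        result.clip_labels = clip_labels

    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            paths["truth"] = out / "truth.csv"
            truth.to_csv(paths["truth"], index=False)
            paths["metadata"] = out / "metadata.csv"
            metadata.to_csv(paths["metadata"], index=False)
            if clip_labels is not None:
                paths["clip_labels"] = out / "clips.csv"
                clip_labels.to_csv(paths["clip_labels"], index=False)
        except OSError as exc:
            raise OSError(f"cannot write experiment output to {out}: {exc}") from exc

    return result


def _emit_clips(
    result: SimulatedExperiment,
    children: list[np.random.SeedSequence],
    clips_per_individual: int,
    chirp: ChirpParams,
    out_dir: str | Path | None,
) -> pd.DataFrame:
    """Sample labeled minutes and synthesize their WAV clips (audio mode)."""
    rows: list[dict] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, (s, child) in enumerate(zip(result.series, children)):
        rng = np.random.default_rng(child.spawn(1)[0])
        sing_idx = np.flatnonzero(s.values == 1)
        bg_idx = np.flatnonzero(s.values == 0)
        n_half = clips_per_individual // 2
        take_sing = rng.choice(sing_idx, size=min(n_half, sing_idx.size), replace=False)
        n_bg = clips_per_individual - take_sing.size
        take_bg = rng.choice(bg_idx, size=min(n_bg, bg_idx.size), replace=False)
        minutes = np.sort(np.concatenate([take_sing, take_bg]))
        for m in minutes:
            state = int(s.values[m])
            fname = f"{s.id}_min{m:06d}.wav"
            t_start = s.start + timedelta(minutes=int(m))
            if out is not None:
                x = synthesize_clip(state, chirp, 60.0, rng=rng)
                wavfile.write(out / fname, chirp.sample_rate, (x * 32767).astype(np.int16))
            rows.append(
                {
                    "file": fname,
                    "individual_id": s.id,
                    "start_datetime": t_start.isoformat(),
                    "minute_index": int(m),
                    "singing": state,
                    "regime": s.schedule.regime_at(t_start),
                    "lights_on": s.schedule.lights_on_at(t_start),
                    "temperature_c": s.schedule.temperature_c,
                    "incubator": "panasonic" if i % 2 == 0 else "leec",
                }
            )
    return pd.DataFrame(rows)
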