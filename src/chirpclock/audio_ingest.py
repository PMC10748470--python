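"""WAV ingestion: read recordings, tile them into 60-s clips, join metadata.

Recordings are PCM WAV at 44.1 kHz; stereo is downmixed to mono by channel
mean.  A recording is scored per consecutive 60-s clip, so ingestion tiles
the file into half-open ``[t, t + 60 s)`` intervals anchored to the
recording's wall-clock start; a trailing partial clip is dropped (and
logged) so minute counts stay auditable.  Metadata rows link each file to
its individual, regime, temperature, and lights-on time, from which each
clip's Zeitgeber time follows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .photoschedule import Photoschedule

__all__ = [
    "Recording",
    "AudioClip",
    "read_recording",
    "segment_clips",
    "attach_metadata",
]

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_RATE = 44100
CLIP_SECONDS = 60


class AudioFormatError(ValueError):
    """Raised for unsupported or metadata-inconsistent audio files."""


@dataclass
class Recording:
    uri: str
    sample_rate: int
    channels: int
    start: datetime
    individual_id: str
    samples: np.ndarray  # mono, float in [-1, 1]

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class AudioClip:
    samples: np.ndarray
    t_start: datetime
    clip_index: int
    sample_rate: int = DEFAULT_SAMPLE_RATE
    duration_s: float = float(CLIP_SECONDS)
    individual_id: str = ""
    file: str = ""


def _to_float(x: np.ndarray) -> np.ndarray:
    if x.dtype == np.int16:
        return x.astype(np.float64) / 32768.0
    if x.dtype == np.int32:
        return x.astype(np.float64) / 2147483648.0
    if x.dtype == np.uint8:
        return (x.astype(np.float64) - 128.0) / 128.0
    if np.issubdtype(x.dtype, np.floating):
        return x.astype(np.float64)
    raise AudioFormatError(f"unsupported WAV sample format {x.dtype}")


def read_recording(
    path: str | Path,
    metadata_row: dict | pd.Series | None = None,
    expected_rate: int | None = DEFAULT_SAMPLE_RATE,
) -> Recording:
    """Read a PCM WAV file; stereo is downmixed to mono by channel mean.

    ``metadata_row`` supplies ``individual_id`` and ``start_datetime``;
    ``expected_rate`` (when not None) is checked against the file header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    rate, data = wavfile.read(path)
    if expected_rate is not None and rate != expected_rate:
        raise AudioFormatError(
            f"{path}: sample rate {rate} Hz does not match expected {expected_rate} Hz"
        )
    data = _to_float(np.asarray(data))
    channels = 1 if data.ndim == 1 else data.shape[1]
    if data.ndim > 1:
        data = data.mean(axis=1)

    individual_id = ""
    start = datetime(1970, 1, 1)
    if metadata_row is not None:
        row = dict(metadata_row)
        individual_id = str(row.get("individual_id", ""))
        if "start_datetime" in row:
            start = pd.Timestamp(row["start_datetime"]).to_pydatetime()
    return Recording(
        uri=str(path),
        sample_rate=int(rate),
        channels=channels,
        start=start,
        individual_id=individual_id,
        samples=data,
    )


def segment_clips(rec: Recording, clip_s: int = CLIP_SECONDS) -> list[AudioClip]:
    """Tile a recording into consecutive ``clip_s``-second clips.

    Returns ``floor(duration / clip_s)`` full clips; any trailing partial
    clip is dropped and logged.
    """
    if rec.samples.size == 0:
        raise ValueError(f"recording {rec.uri} is empty")
    n_per_clip = clip_s * rec.sample_rate
    n_full = rec.samples.size // n_per_clip
    remainder = rec.samples.size - n_full * n_per_clip
    if remainder:
        logger.warning(
            "%s: dropping trailing partial clip of %.2f s",
            rec.uri,
            remainder / rec.sample_rate,
        )
    clips = []
    for i in range(n_full):
        clips.append(
            AudioClip(
                samples=rec.samples[i * n_per_clip : (i + 1) * n_per_clip],
                t_start=rec.start + timedelta(seconds=i * clip_s),
                clip_index=i,
                sample_rate=rec.sample_rate,
                duration_s=float(clip_s),
                individual_id=rec.individual_id,
                file=rec.uri,
            )
        )
    return clips


def _schedule_from_row(row: pd.Series) -> Photoschedule:
    return Photoschedule(
        regime=str(row["regime"]),
        lights_on=float(row["lights_on"]),
        temperature_c=float(row["temperature_c"]) if "temperature_c" in row else None,
    )


def attach_metadata(clips: list[AudioClip], metadata: pd.DataFrame) -> pd.DataFrame:
    """Annotate clips with individual, regime, temperature, and ZT.

    Every clip's file basename must appear exactly once in ``metadata``; the
    clip's ZT is computed from the regime active at its start time
    (lights-on maps to ZT0).  Returns a clip manifest frame.
    """
    meta = metadata.copy()
    meta["basename"] = meta["file"].map(lambda f: Path(str(f)).name)
    dup = meta["basename"][meta["basename"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate metadata rows for file(s): {sorted(set(dup))}")
    by_file = meta.set_index("basename")

    rows = []
    for clip in clips:
        base = Path(clip.file).name
        if base not in by_file.index:
            raise ValueError(f"clip file {base!r} not found in metadata")
        row = by_file.loc[base]
        sched = _schedule_from_row(row)
        rows.append(
            {
                "file": base,
                "clip_index": clip.clip_index,
                "t_start": clip.t_start,
                "zt": sched.zt(clip.t_start),
                "individual_id": row["individual_id"],
                "regime": row["regime"],
                "temperature_c": row.get("temperature_c", np.nan),
            }
        )
    return pd.DataFrame(rows)
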