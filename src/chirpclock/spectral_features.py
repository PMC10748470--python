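"""Per-clip spectral descriptors of the 3-6 kHz cricket-song band.

The calling song of *T. oceanicus* carries its energy between roughly 4 and
5 kHz, so classification features describe the magnitude spectrum restricted
to a 3-6 kHz band (Welch-averaged, Hann window, 4096-sample frames with 50%
overlap by default) together with a handful of temporal-envelope measures.

Two catalogues are provided: a compact 5-feature default (band dominant
frequency, band-to-total energy ratio, normalized band spectral entropy,
band magnitude SD, envelope crest factor) and a full catalogue of 20
descriptors from which the default can be re-derived by iterative paring on
permutation importance (:func:`pare_features`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "DEFAULT_CATALOGUE",
    "FULL_CATALOGUE",
    "band_spectrum",
    "compute_features",
    "features_frame",
    "pare_features",
    "write_features",
    "read_features",
]

DEFAULT_CATALOGUE: tuple[str, ...] = (
    "dominant_freq_hz",
    "band_energy_ratio",
    "band_entropy",
    "band_mag_sd",
    "envelope_crest",
)

FULL_CATALOGUE: tuple[str, ...] = DEFAULT_CATALOGUE + (
    "band_mag_mean",
    "band_mag_median",
    "band_mag_skew",
    "band_mag_kurtosis",
    "band_mag_iqr",
    "band_mag_max",
    "band_flatness",
    "band_centroid_hz",
    "band_bandwidth_hz",
    "band_rolloff_hz",
    "envelope_mean",
    "envelope_sd",
    "envelope_peak_count",
    "zero_crossing_rate",
    "broadband_rms",
)

BAND_HZ = (3000.0, 6000.0)


def band_spectrum(
    samples: np.ndarray,
    sample_rate: int = 44100,
    fmin: float = BAND_HZ[0],
    fmax: float = BAND_HZ[1],
    frame_samples: int = 4096,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-averaged magnitude spectrum restricted to ``[fmin, fmax]``.

    Returns ``(freqs, magnitude)`` where magnitude is the square root of the
    Welch PSD estimate; frequency resolution is ``sample_rate/frame_samples``.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if fmax > sample_rate / 2:
        raise ValueError("fmax exceeds the Nyquist frequency")
    if samples.size < frame_samples:
        raise ValueError(
            f"clip of {samples.size} samples is shorter than one frame ({frame_samples})"
        )
    freqs, psd = signal.welch(
        samples,
        fs=sample_rate,
        window="hann",
        nperseg=frame_samples,
        noverlap=int(frame_samples * overlap),
    )
    in_band = (freqs >= fmin) & (freqs <= fmax)
    return freqs[in_band], np.sqrt(psd[in_band])


def _envelope(samples: np.ndarray, sample_rate: int, frame_s: float = 0.05) -> np.ndarray:
    n_frame = max(int(frame_s * sample_rate), 1)
    n = samples.size // n_frame
    if n == 0:
        return np.array([np.sqrt(np.mean(samples**2))])
    frames = samples[: n * n_frame].reshape(n, n_frame)
    return np.sqrt(np.mean(frames**2, axis=1))


def compute_features(
    samples: np.ndarray,
    sample_rate: int = 44100,
    catalogue: tuple[str, ...] = DEFAULT_CATALOGUE,
    fmin: float = BAND_HZ[0],
    fmax: float = BAND_HZ[1],
    frame_samples: int = 4096,
    overlap: float = 0.5,
) -> dict[str, float]:
    """Compute the requested descriptors for one clip.

    Silent clips never raise: spectral entropy and flatness default to 1
    (a maximally uninformative, uniform spectrum), the dominant frequency is
    NaN (flagged as undefined), and shape statistics default to 0.
    """
    unknown = set(catalogue) - set(FULL_CATALOGUE)
    if unknown:
        raise ValueError(f"unknown features requested: {sorted(unknown)}")
    if not catalogue:
        raise ValueError("catalogue must be non-empty")

    samples = np.asarray(samples, dtype=float).ravel()
    freqs_all, psd_all = signal.welch(
        samples,
        fs=sample_rate,
        window="hann",
        nperseg=frame_samples,
        noverlap=int(frame_samples * overlap),
    )
    in_band = (freqs_all >= fmin) & (freqs_all <= fmax)
    freqs = freqs_all[in_band]
    psd = psd_all[in_band]
    mag = np.sqrt(psd)
    total = psd_all.sum()
    band_total = psd.sum()
    silent = band_total <= 0.0

    env = _envelope(samples, sample_rate)
    env_rms = np.sqrt(np.mean(env**2))

    out: dict[str, float] = {}

    if not silent:
        p = psd / band_total
        entropy = float(-(p[p > 0] * np.log(p[p > 0])).sum() / np.log(p.size))
        gmean = float(np.exp(np.mean(np.log(psd[psd > 0])))) if np.all(psd > 0) else 0.0
        flatness = gmean / psd.mean() if psd.mean() > 0 else 1.0
        centroid = float((freqs * p).sum())
        bandwidth = float(np.sqrt(((freqs - centroid) ** 2 * p).sum()))
        cum = np.cumsum(p)
        rolloff = float(freqs[np.searchsorted(cum, 0.85)]) if cum[-1] >= 0.85 else float(freqs[-1])
        dominant = float(freqs[np.argmax(mag)])
        skew = float(stats.skew(mag))
        kurt = float(stats.kurtosis(mag))
    else:
        entropy, flatness = 1.0, 1.0
        centroid, bandwidth = (fmin + fmax) / 2.0, 0.0
        rolloff = fmin
        dominant = float("nan")
        skew = kurt = 0.0

    values = {
        "dominant_freq_hz": dominant,
        "band_energy_ratio": float(band_total / total) if total > 0 else 0.0,
        "band_entropy": entropy,
        "band_mag_sd": float(np.std(mag)),
        "envelope_crest": float(env.max() / env_rms) if env_rms > 0 else 0.0,
        "band_mag_mean": float(mag.mean()),
        "band_mag_median": float(np.median(mag)),
        "band_mag_skew": skew,
        "band_mag_kurtosis": kurt,
        "band_mag_iqr": float(np.subtract(*np.percentile(mag, [75, 25]))),
        "band_mag_max": float(mag.max()),
        "band_flatness": float(flatness),
        "band_centroid_hz": centroid,
        "band_bandwidth_hz": bandwidth,
        "band_rolloff_hz": rolloff,
        "envelope_mean": float(env.mean()),
        "envelope_sd": float(env.std()),
        "envelope_peak_count": float(
            signal.find_peaks(env, height=3.0 * np.median(env))[0].size
        )
        if np.median(env) > 0
        else 0.0,
        "zero_crossing_rate": float(
            np.count_nonzero(np.diff(np.signbit(samples))) / (samples.size / sample_rate)
        ),
        "broadband_rms": float(np.sqrt(np.mean(samples**2))),
    }
    for name in catalogue:
        out[name] = values[name]
    return out


def features_frame(
    clips,
    sample_rate: int = 44100,
    catalogue: tuple[str, ...] = DEFAULT_CATALOGUE,
    **kwargs,
) -> pd.DataFrame:
    """Feature table for an iterable of ``(clip_id, samples)`` pairs.

    Accepts a generator, so large clip corpora can be streamed without
    holding raw audio in memory.
    """
    rows = []
    for clip_id, samples in clips:
        row = {"clip_id": clip_id}
        row.update(compute_features(samples, sample_rate, catalogue, **kwargs))
        rows.append(row)
    return pd.DataFrame(rows)


def pare_features(
    X: pd.DataFrame,
    y: np.ndarray,
    n_keep: int = 5,
    seed: int = 0,
    n_trees: int = 200,
    n_repeats: int = 5,
) -> list[str]:
    """Iteratively pare the catalogue down to ``n_keep`` features.

    At each round a random forest is fit on the surviving features and the
    feature with the lowest permutation importance is dropped, replaying the
    iterative reduction of a large descriptor set to a compact one.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    if n_keep < 1 or n_keep > X.shape[1]:
        raise ValueError("n_keep must be in [1, n_features]")
    keep = list(X.columns)
    while len(keep) > n_keep:
        model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        model.fit(X[keep], y)
        imp = permutation_importance(
            model, X[keep], y, n_repeats=n_repeats, random_state=seed
        )
        keep.pop(int(np.argmin(imp.importances_mean)))
    return keep


def write_features(
    frame: pd.DataFrame, path: str | Path, band_hz: tuple[float, float] = BAND_HZ
) -> None:
    """Write a features CSV with the band bounds recorded in a header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# band_hz={band_hz[0]:g}-{band_hz[1]:g}\n")
        frame.to_csv(fh, index=False)


def read_features(path: str | Path) -> tuple[pd.DataFrame, tuple[float, float]]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    band = BAND_HZ
    if header.startswith("# band_hz="):
        lo, hi = header.removeprefix("# band_hz=").split("-")
        band = (float(lo), float(hi))
    frame = pd.read_csv(path, comment="#")
    return frame, band
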