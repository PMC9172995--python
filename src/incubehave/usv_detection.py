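"""Ultrasonic vocalization detection from spectrogram threshold rules.

Recordings sampled at 250 kHz are cut into non-overlapping 0.4-ms windows
and Fourier transformed.  A window is a vocalization candidate when any
power-spectral-density bin reaches the detection threshold (default
-75 dB/Hz relative to a configurable reference); contiguous candidate
windows form segments, and segments whose average PSD in the 0-50 kHz band
exceeds that in the 50-120 kHz band are rejected as low-frequency noise.
The absolute dB threshold depends on the recording chain's calibration, so
the reference power level is a configuration default, not a constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PsdFrames",
    "UsvSegment",
    "spectrogram",
    "detect_usv_segments",
    "usv_total_duration",
    "WINDOW_SECONDS",
]

WINDOW_SECONDS = 4e-4  # 0.4-ms non-overlapping analysis windows
LOW_BAND = (0.0, 50_000.0)
HIGH_BAND = (50_000.0, 120_000.0)
_PSD_FLOOR = 1e-30  # guards log of silent windows


@dataclass
class PsdFrames:
    """Windowed power spectral densities of one recording.

    ``psd_db`` has shape (n_windows, n_freq_bins) in dB/Hz relative to
    ``reference``; ``band_low_mean``/``band_high_mean`` are the per-window
    averages over 0-50 kHz and 50-120 kHz.
    """

    psd_db: np.ndarray
    freqs: np.ndarray
    start_times: np.ndarray
    window_seconds: float
    sample_rate: float
    band_low_mean: np.ndarray
    band_high_mean: np.ndarray


@dataclass(frozen=True)
class UsvSegment:
    start_time: float
    end_time: float
    n_windows: int

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


def spectrogram(
    waveform: np.ndarray,
    sample_rate: float,
    reference: float = 1.0,
    window: str = "rectangular",
) -> PsdFrames:
    """Non-overlapping 0.4-ms-window PSD frames of a waveform.

    ``sample_rate`` must put an integer number of samples in each 0.4-ms
    window (100 samples at 250 kHz).  PSD is the one-sided periodogram in
    power per Hz, expressed in dB relative to ``reference``; the default
    rectangular window can be replaced by ``"hann"``.
    """
    waveform = np.asarray(waveform, dtype=float)
    n_win_f = sample_rate * WINDOW_SECONDS
    n_win = int(round(n_win_f))
    if abs(n_win_f - n_win) > 1e-9 or n_win < 2:
        raise ValueError(
            f"sample rate {sample_rate} Hz does not give an integer number of "
            f"samples per {WINDOW_SECONDS * 1e3:.1f}-ms window"
        )
    if len(waveform) < n_win:
        raise ValueError("waveform shorter than one analysis window")
    n_frames = len(waveform) // n_win
    segments = waveform[: n_frames * n_win].reshape(n_frames, n_win)
    if window == "hann":
        taper = np.hanning(n_win)
    elif window == "rectangular":
        taper = np.ones(n_win)
    else:
        raise ValueError(f"unknown window {window!r}")
    scale = 1.0 / (sample_rate * np.sum(taper**2))
    spec = np.fft.rfft(segments * taper, axis=1)
    psd = (np.abs(spec) ** 2) * scale
    # one-sided density: double the interior bins
    psd[:, 1:-1] *= 2.0
    if n_win % 2:  # odd window: the last bin is not at Nyquist
        psd[:, -1] *= 2.0
    freqs = np.fft.rfftfreq(n_win, d=1.0 / sample_rate)
    psd_db = 10.0 * np.log10(np.maximum(psd / reference, _PSD_FLOOR))
    low = (freqs >= LOW_BAND[0]) & (freqs < LOW_BAND[1])
    high = (freqs >= HIGH_BAND[0]) & (freqs <= HIGH_BAND[1])
    return PsdFrames(
        psd_db=psd_db,
        freqs=freqs,
        start_times=np.arange(n_frames) * WINDOW_SECONDS,
        window_seconds=WINDOW_SECONDS,
        sample_rate=sample_rate,
        band_low_mean=psd_db[:, low].mean(axis=1),
        band_high_mean=psd_db[:, high].mean(axis=1),
    )


def detect_usv_segments(
    frames: PsdFrames,
    psd_threshold: float = -75.0,
    merge_gap_windows: int = 0,
    min_windows: int = 1,
) -> list[UsvSegment]:
    """Segment vocalizations by threshold and band comparison.

    A window is a candidate iff any PSD bin is at or above
    ``psd_threshold`` dB/Hz.  Maximal contiguous candidate runs (optionally
    bridging gaps of up to ``merge_gap_windows`` silent windows) become
    segments; a segment is discarded when its average 0-50 kHz PSD exceeds
    its average 50-120 kHz PSD, and when shorter than ``min_windows``.
    """
    candidate = (frames.psd_db >= psd_threshold).any(axis=1)
    segments: list[UsvSegment] = []
    idx = np.nonzero(candidate)[0]
    if len(idx) == 0:
        return segments
    breaks = np.nonzero(np.diff(idx) > 1 + merge_gap_windows)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])  # inclusive
    w = frames.window_seconds
    for s, e in zip(starts, ends):
        if e - s + 1 < min_windows:
            continue
        low = frames.band_low_mean[s : e + 1].mean()
        high = frames.band_high_mean[s : e + 1].mean()
        if low > high:
            continue  # low-frequency noise, not a vocalization
        segments.append(
            UsvSegment(
                start_time=float(frames.start_times[s]),
                end_time=float(frames.start_times[e] + w),
                n_windows=int(e - s + 1),
            )
        )
    return segments


def usv_total_duration(
    segments: list[UsvSegment], recording_duration: float
) -> tuple[float, float]:
    """Total vocalization time and its fraction of the recording.

    Segments must be non-overlapping and lie within the recording.
    """
    ordered = sorted(segments, key=lambda s: s.start_time)
    for a, b in zip(ordered, ordered[1:]):
        if a.end_time > b.start_time + 1e-12:
            raise ValueError("segments overlap")
    for s in ordered:
        if s.start_time < -1e-12 or s.end_time > recording_duration + 1e-9:
            raise ValueError("segment outside the recording")
    total = float(sum(s.duration for s in ordered))
    return total, total / recording_duration
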