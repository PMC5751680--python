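"""WAV reading and acoustic intensity contours.

The inter-peak interval of two calls is measured between their
maximum-intensity peaks, so the analysis needs (1) the recorded waveform
and (2) an intensity contour — windowed signal energy in dB as a function
of time — from which each call's peak is located.

Intensity follows the Praat convention: a frame's value is
``10*log10(<x^2>_w / p_ref^2)`` where ``<x^2>_w`` is the window-weighted
mean squared amplitude and ``p_ref = 2e-5`` (full-scale amplitude 1.0 thus
maps a unit sinusoid to ~91 dB). The default analysis window is a Kaiser
window (beta = 20, as Praat uses) of duration ``3.2 / min_pitch`` stepped
every ``0.8 / min_pitch`` — 32 ms and 8 ms at the default
``min_pitch = 100`` Hz. A Hann window is accepted as a configuration.
"""

from __future__ import annotations

import logging
import wave as _wave
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window

logger = logging.getLogger(__name__)

__all__ = [
    "Waveform",
    "IntensityContour",
    "AudioFormatError",
    "read_wav",
    "write_wav",
    "intensity_contour",
    "peak_in_interval",
]

P_REF = 2e-5  # reference pressure equivalent; amplitude 1.0 is full scale
SILENCE_FLOOR_DB = -300.0


class AudioFormatError(ValueError):
    """Unreadable or unsupported audio format."""


@dataclass
class Waveform:
    """Mono audio samples normalized to [-1, 1] at a given sample rate."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform must be mono (1-D samples)")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM WAV file into a normalized mono :class:`Waveform`.

    Supports 16- and 24-bit integer and 32-bit float PCM. Integer samples
    are scaled by the integer full-scale value; 24-bit data arrives from
    scipy left-justified in int32, so the divisor is 2^31 in both integer
    cases. Multi-channel input is downmixed by averaging, with a warning.
    """
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise AudioFormatError(f"cannot read {path}: {exc}") from exc
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 2**15
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2**31
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        raise AudioFormatError(f"unsupported sample format {data.dtype}")
    if samples.ndim == 2:
        logger.warning(
            "downmixing %d-channel audio to mono by averaging", samples.shape[1]
        )
        samples = samples.mean(axis=1)
    return Waveform(samples, float(rate))


def write_wav(
    path: str | Path, w: Waveform, *, bits: int = 24
) -> None:
    """Write a mono waveform as PCM WAV (16- or 24-bit integer).

    Samples are clipped to [-1, 1] and scaled to the integer full scale.
    """
    clipped = np.clip(w.samples, -1.0, 1.0)
    if bits == 16:
        wavfile.write(str(path), int(w.rate), (clipped * (2**15 - 1)).astype("<i2"))
        return
    if bits != 24:
        raise ValueError("bits must be 16 or 24")
    ints = np.round(clipped * (2**23 - 1)).astype("<i4")
    raw = ints.tobytes()
    # keep the low 3 of every 4 little-endian bytes -> packed 24-bit
    packed = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)[:, :3].tobytes()
    with _wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(3)
        fh.setframerate(int(w.rate))
        fh.writeframes(packed)


@dataclass
class IntensityContour:
    """Regularly sampled intensity values in dB.

    Frame ``i`` is centred at ``start_time + i * step`` seconds. Silent
    frames carry the configured floor value instead of -inf so arithmetic
    stays finite.
    """

    start_time: float
    step: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.step * np.arange(len(self.values))


def intensity_contour(
    w: Waveform,
    min_pitch: float = 100.0,
    time_step: float | None = None,
    *,
    window: str = "kaiser",
    floor_db: float = SILENCE_FLOOR_DB,
) -> IntensityContour:
    """Compute the windowed-energy intensity contour of a waveform.

    The analysis window spans ``3.2 / min_pitch`` seconds (long enough to
    average over pitch periods down to ``min_pitch``); frames step by
    ``time_step`` (default ``0.8 / min_pitch``). Each frame's value is the
    window-weighted mean squared amplitude in dB re ``P_REF``; all-zero
    windows get ``floor_db``.
    """
    if min_pitch <= 0:
        raise ValueError("min_pitch must be positive")
    if time_step is None:
        time_step = 0.8 / min_pitch
    win_dur = 3.2 / min_pitch
    n_win = int(round(win_dur * w.rate))
    if n_win < 2 or n_win > len(w.samples):
        raise ValueError(
            f"recording ({w.duration:.3f} s) shorter than one analysis "
            f"window ({win_dur:.3f} s); lower min_pitch or supply more audio"
        )
    if window == "kaiser":
        taps = get_window(("kaiser", 20.0), n_win, fftbins=False)
    elif window == "hann":
        taps = get_window("hann", n_win, fftbins=False)
    else:
        raise ValueError(f"unknown window {window!r}")
    taps = taps / taps.sum()

    half = n_win / 2 / w.rate
    n_frames = int(np.floor((w.duration - 2 * half) / time_step)) + 1
    if n_frames < 1:
        raise ValueError("recording too short for one intensity frame")
    sq = w.samples**2
    centers = half + time_step * np.arange(n_frames)
    starts = np.round(centers * w.rate - n_win / 2).astype(int)
    starts = np.clip(starts, 0, len(sq) - n_win)
    # frame-by-frame weighted energy; frame counts are small (< 1e6)
    ms = np.empty(n_frames)
    for i, s in enumerate(starts):
        ms[i] = taps @ sq[s : s + n_win]
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(ms / P_REF**2)
    db[~np.isfinite(db)] = floor_db
    db = np.maximum(db, floor_db)
    return IntensityContour(start_time=float(centers[0]), step=time_step, values=db)


def peak_in_interval(
    c: IntensityContour, onset: float, offset: float
) -> tuple[float, float]:
    """Locate the maximum-intensity peak inside ``[onset, offset)``.

    Returns ``(peak_time, peak_level_db)`` for the loudest contour frame
    whose centre lies in the half-open interval; ties go to the earliest
    frame. Raises if no frame centre falls inside the interval.
    """
    if not onset < offset:
        raise ValueError(f"onset must precede offset, got [{onset}, {offset}]")
    times = c.times
    mask = (times >= onset) & (times < offset)
    if not mask.any():
        raise ValueError(
            f"no intensity frame inside [{onset}, {offset}]; "
            "use a smaller time_step"
        )
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(c.values[idx])]  # argmax returns first max: earliest
    return float(times[best]), float(c.values[best])
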