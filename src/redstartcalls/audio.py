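"""Audio I/O, Raven-style selection tables, clip extraction and spectrograms.

Flight-call recordings arrive as mono RIFF WAV files (44.1 kHz; field
recordings are typically 24-bit PCM).  Calls inside longer recordings are
delimited by tab-separated selection tables in the dialect written by the
Raven sound-analysis software, and are clipped out with a few milliseconds of
padding.  Spectrograms use a 256-point FFT with 256-sample Hann windows
advancing 38 samples per frame; trailing samples that do not fill a window
are dropped rather than zero-padded.
"""

from __future__ import annotations

import wave as _wave
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile as _wavfile
from scipy.signal import get_window

__all__ = [
    "Waveform",
    "SelectionTable",
    "Spectrogram",
    "read_wav",
    "write_wav",
    "read_selection_table",
    "write_selection_table",
    "extract_clips",
    "compute_spectrogram",
    "NFFT",
    "WINDOW_LENGTH",
    "HOP",
]

#: STFT parameters used throughout: 256-point FFT, 256-sample Hann window,
#: 38-sample advance.
NFFT = 256
WINDOW_LENGTH = 256
HOP = 38

REQUIRED_SELECTION_COLUMNS = (
    "Selection",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
)


@dataclass
class Waveform:
    """A mono audio signal with its sample rate.

    Samples are dimensionless amplitudes, expected within [-1, 1].
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(
                f"Waveform requires a 1-D signal, got shape {self.samples.shape}; "
                "down-mix multi-channel audio before constructing a Waveform"
            )
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.sample_rate


@dataclass
class Spectrogram:
    """One-sided power spectrogram: frames x frequency bins, linear power."""

    power: np.ndarray  # (n_frames, n_bins)
    times: np.ndarray  # frame-center seconds
    freqs: np.ndarray  # bin-center Hz
    params: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]

    @property
    def n_bins(self) -> int:
        return self.power.shape[1]


class SelectionTable:
    """A Raven-style selection table: one row per selected sound.

    Wraps a DataFrame whose required columns are ``Selection``,
    ``Begin Time (s)``, ``End Time (s)``, ``Low Freq (Hz)`` and
    ``High Freq (Hz)`` (case-sensitive).  Any additional columns are carried
    as annotations and survive round-trips.
    """

    def __init__(self, frame: pd.DataFrame):
        for col in REQUIRED_SELECTION_COLUMNS:
            if col not in frame.columns:
                raise ValueError(f"selection table is missing required column {col!r}")
        frame = frame.copy()
        frame["Selection"] = frame["Selection"].astype(int)
        for col in REQUIRED_SELECTION_COLUMNS[1:]:
            frame[col] = pd.to_numeric(frame[col])
        if (frame["End Time (s)"] <= frame["Begin Time (s)"]).any():
            raise ValueError("selection table has rows with End Time <= Begin Time")
        if (frame["Low Freq (Hz)"] < 0).any() or (
            frame["High Freq (Hz)"] <= frame["Low Freq (Hz)"]
        ).any():
            raise ValueError("selection table frequency bounds invalid")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, SelectionTable) and self.frame.equals(other.frame)

    @property
    def annotation_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in REQUIRED_SELECTION_COLUMNS]

    def annotation(self, name: str) -> pd.Series:
        if name not in self.annotation_columns:
            raise KeyError(f"no annotation column {name!r}")
        return self.frame[name]


def read_wav(path) -> Waveform:
    """Read a mono WAV file, scaling integer encodings to [-1, 1].

    24-bit PCM is supported (scipy returns it as left-aligned int32).
    """
    try:
        sample_rate, data = _wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / truncated header
        raise IOError(f"could not read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise IOError(
            f"{path} has {data.shape[1]} channels; down-mix to mono before reading"
        )
    if data.dtype == np.int16:
        samples = data / 2.0**15
    elif data.dtype == np.int32:
        # covers 24-bit PCM, which scipy left-shifts into int32
        samples = data / 2.0**31
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return Waveform(samples=samples, sample_rate=int(sample_rate))


def write_wav(path, waveform: Waveform, bit_depth: str = "float32") -> None:
    """Write a mono WAV file.

    bit_depth 'float32' writes IEEE-float samples; '24bit' writes 24-bit
    integer PCM (the format of the original field recordings).
    """
    x = np.clip(waveform.samples, -1.0, 1.0)
    if bit_depth == "float32":
        _wavfile.write(path, waveform.sample_rate, x.astype(np.float32))
    elif bit_depth == "24bit":
        ints = np.round(x * (2**23 - 1)).astype(np.int64)
        raw = b"".join(int(v).to_bytes(3, "little", signed=True) for v in ints)
        with _wave.open(str(path), "wb") as w:
            w.setnchannels(1)
            w.setsampwidth(3)
            w.setframerate(waveform.sample_rate)
            w.writeframes(raw)
    else:
        raise ValueError(f"unsupported bit_depth {bit_depth!r}")


def read_selection_table(path) -> SelectionTable:
    """Parse a tab-separated Raven selection table."""
    try:
        frame = pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise IOError(f"could not parse selection table {path}: {exc}") from exc
    for col in REQUIRED_SELECTION_COLUMNS:
        if col not in frame.columns:
            raise ValueError(
                f"selection table {path} is missing required column {col!r}"
            )
    for col in REQUIRED_SELECTION_COLUMNS[1:]:
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(
                f"non-numeric value in column {col!r} at line {line} of {path}"
            )
    return SelectionTable(frame)


def write_selection_table(path, table: SelectionTable) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def extract_clips(
    waveform: Waveform, table: SelectionTable, pad_ms: float = 5.0
) -> list[Waveform]:
    """Cut each selection out of the recording with symmetric padding.

    The pad is converted to samples by rounding to the nearest sample
    (5 ms at 44.1 kHz -> 221 samples) and clamped at the file boundaries.
    """
    # nearest-sample, half away from zero: 220.5 -> 221
    pad = int(np.floor(pad_ms * 1e-3 * waveform.sample_rate + 0.5))
    n = waveform.n_samples
    clips = []
    for _, row in table.frame.iterrows():
        b = int(round(row["Begin Time (s)"] * waveform.sample_rate))
        e = int(round(row["End Time (s)"] * waveform.sample_rate))
        if e <= 0 or b >= n:
            raise ValueError(
                f"selection {int(row['Selection'])} lies entirely outside the recording"
            )
        lo = max(0, b - pad)
        hi = min(n, e + pad)
        clips.append(Waveform(waveform.samples[lo:hi], waveform.sample_rate))
    return clips


def compute_spectrogram(waveform: Waveform) -> Spectrogram:
    """Power spectrogram with the pinned parameters (256/256 Hann/38 hop).

    Frames that would extend past the end of the signal are dropped; the
    signal body is never zero-padded.  Power is the squared magnitude of the
    one-sided DFT of each Hann-windowed frame (no window-gain correction:
    downstream measurements are relative).
    """
    x = waveform.samples
    n = x.size
    if n < WINDOW_LENGTH:
        raise ValueError(
            f"clip of {n} samples is shorter than one {WINDOW_LENGTH}-sample "
            "analysis window; provide at least "
            f"{WINDOW_LENGTH / waveform.sample_rate * 1e3:.1f} ms of audio"
        )
    n_frames = (n - WINDOW_LENGTH) // HOP + 1
    window = get_window("hann", WINDOW_LENGTH, fftbins=True)
    idx = np.arange(WINDOW_LENGTH)[None, :] + HOP * np.arange(n_frames)[:, None]
    frames = x[idx] * window[None, :]
    spec = np.fft.rfft(frames, n=NFFT, axis=1)
    power = (spec.real**2 + spec.imag**2)
    times = (np.arange(n_frames) * HOP + (WINDOW_LENGTH - 1) / 2.0) / waveform.sample_rate
    freqs = np.fft.rfftfreq(NFFT, d=1.0 / waveform.sample_rate)
    return Spectrogram(
        power=power,
        times=times,
        freqs=freqs,
        params={
            "nfft": NFFT,
            "window": "hann",
            "window_length": WINDOW_LENGTH,
            "hop": HOP,
            "sample_rate": waveform.sample_rate,
        },
    )
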