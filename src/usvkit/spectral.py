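"""Short-time Fourier analysis for ultrasonic recordings.

The detector consumes a linear-magnitude spectrogram computed with a Hann
window of 1024 samples and 90% overlap.  At the default 250 kHz sampling
rate this gives a fractional hop of 102.4 samples; frame ``m`` starts at
sample ``round(m * hop)``, which is what reproduces 1211 frames for a
0.5 s analysis window.  Frequency band ``b`` covers the half-open interval
``[b*df, (b+1)*df)`` with ``df = fs / window_length``; only the bands below
the Nyquist bin (``0 .. window_length/2 - 1``) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AudioRecording",
    "StftParams",
    "Spectrogram",
    "SegmentTooShortError",
    "frame_count",
    "frame_starts",
    "stft_spectrogram",
    "band_indices",
    "read_wav",
    "write_wav",
    "export_spectrogram_csv",
]

DEFAULT_FS = 250_000.0
#: Avisoft-style pressure reference for dB conversion (dB re 20 µPa).
DEFAULT_AMPLITUDE_REFERENCE = 2e-5


class SegmentTooShortError(ValueError):
    """Raised when a segment is shorter than one analysis window."""


@dataclass(frozen=True)
class AudioRecording:
    """A mono pressure-sample sequence with its sampling rate."""

    samples: np.ndarray
    fs: float
    id: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioRecording requires a mono (1-D) signal")
        if samples.size < 1:
            raise ValueError("AudioRecording requires at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioRecording samples must be finite")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def slice(self, start_s: float, end_s: float) -> "AudioRecording":
        i0 = int(round(start_s * self.fs))
        i1 = min(int(round(end_s * self.fs)), self.samples.size)
        return AudioRecording(self.samples[i0:i1], self.fs, id=self.id)


@dataclass(frozen=True)
class StftParams:
    """Analysis parameters: 1024-sample Hann window at 90% overlap."""

    window_length: int = 1024
    overlap_fraction: float = 0.9
    window_shape: str = "hann"
    fs: float = DEFAULT_FS
    amplitude_reference: float = DEFAULT_AMPLITUDE_REFERENCE

    def __post_init__(self):
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def hop(self) -> float:
        """Hop size in samples; fractional (102.4 at the defaults)."""
        return self.window_length * (1.0 - self.overlap_fraction)

    @property
    def hop_s(self) -> float:
        return self.hop / self.fs

    @property
    def band_width(self) -> float:
        return self.fs / self.window_length


@dataclass
class Spectrogram:
    """Linear-magnitude time-frequency matrix, indexed [band, frame]."""

    A: np.ndarray
    frame_start_times: np.ndarray
    band_lo_freqs: np.ndarray
    params: StftParams = field(default_factory=StftParams)

    @property
    def n_bands(self) -> int:
        return self.A.shape[0]

    @property
    def n_frames(self) -> int:
        return self.A.shape[1]

    def band_slice(self, lo_band: int, hi_band: int) -> "Spectrogram":
        """Restrict to bands ``lo_band .. hi_band`` inclusive."""
        return Spectrogram(
            A=self.A[lo_band : hi_band + 1],
            frame_start_times=self.frame_start_times,
            band_lo_freqs=self.band_lo_freqs[lo_band : hi_band + 1],
            params=self.params,
        )


def frame_count(n_samples: int, window_length: int, hop: float) -> int:
    """Number of full analysis windows that fit into ``n_samples``.

    Frame ``m`` starts at sample ``round(m*hop)``; the count is
    ``floor((n_samples - window_length)/hop) + 1``.
    """
    if hop <= 0:
        raise ValueError("hop must be positive")
    if n_samples < window_length:
        raise SegmentTooShortError(
            f"segment too short: {n_samples} samples < window of {window_length}"
        )
    return int(np.floor((n_samples - window_length) / hop)) + 1


def frame_starts(n_samples: int, window_length: int, hop: float) -> np.ndarray:
    """Integer start sample of each frame (``round(m*hop)``)."""
    m = frame_count(n_samples, window_length, hop)
    starts = np.rint(np.arange(m) * hop).astype(np.int64)
    # rounding may push the last start past the valid range by one sample
    return np.minimum(starts, n_samples - window_length)


def _window(params: StftParams) -> np.ndarray:
    name = params.window_shape.lower()
    if name in ("hann", "hanning"):
        return np.hanning(params.window_length)
    from scipy.signal import get_window

    return get_window(name, params.window_length)


def stft_spectrogram(segment: AudioRecording, params: StftParams | None = None) -> Spectrogram:
    """Linear-magnitude spectrogram of one segment.

    ``A[b, t] = |FFT_b of the Hann-tapered frame t|``; bands
    ``0 .. window_length/2 - 1`` retained (the Nyquist bin is dropped so
    that band intervals tile ``[0, fs/2)`` exactly).
    """
    if params is None:
        params = StftParams(fs=segment.fs)
    x = segment.samples
    wl = params.window_length
    starts = frame_starts(x.size, wl, params.hop)
    frames = x[starts[:, None] + np.arange(wl)[None, :]]
    taper = _window(params)
    spec = np.abs(np.fft.rfft(frames * taper, axis=1))[:, : wl // 2]
    df = params.band_width
    return Spectrogram(
        A=spec.T.copy(),
        frame_start_times=starts / params.fs,
        band_lo_freqs=np.arange(wl // 2) * df,
        params=params,
    )


def band_indices(params: StftParams, lo: float, hi: float) -> np.ndarray:
    """Indices of all bands whose interval ``[b*df, (b+1)*df)`` intersects
    the closed range ``[lo, hi]``.

    The intersection convention (rather than band-centre containment) is
    what yields 136 bands for 35-68 kHz at the default geometry.
    """
    if not (0 <= lo < hi <= params.fs / 2):
        raise ValueError("require 0 <= lo < hi <= fs/2")
    df = params.band_width
    n_bands = params.window_length // 2
    b = np.arange(n_bands)
    mask = (b * df <= hi) & ((b + 1) * df > lo)
    idx = b[mask]
    if idx.size == 0:
        raise ValueError(f"no bands in range [{lo}, {hi}] Hz")
    return idx


# ---------------------------------------------------------------------------
# WAV I/O (mono PCM16 / float32)

def read_wav(path, id: str | None = None) -> AudioRecording:
    """Read a mono WAV file; integer PCM is normalised to [-1, 1]."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return AudioRecording(data, float(fs), id=id if id is not None else str(path))


def write_wav(path, rec: AudioRecording, dtype: str = "float32") -> None:
    from scipy.io import wavfile

    if dtype == "float32":
        wavfile.write(path, int(rec.fs), rec.samples.astype(np.float32))
    elif dtype == "int16":
        x = np.clip(rec.samples, -1.0, 1.0)
        wavfile.write(path, int(rec.fs), np.round(x * 32767).astype(np.int16))
    else:
        raise ValueError("dtype must be 'float32' or 'int16'")


def plot_spectrogram(spec: Spectrogram, ax=None, db_floor: float = -120.0):
    """Debug view of a spectrogram in dB (never used in the detection
    path, which thresholds each frame against its own statistics)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ref = spec.params.amplitude_reference
    img = 20 * np.log10(np.maximum(spec.A, 1e-30) / ref)
    img = np.maximum(img, db_floor)
    ax.imshow(
        img,
        origin="lower",
        aspect="auto",
        extent=(
            spec.frame_start_times[0],
            spec.frame_start_times[-1] + spec.params.hop_s,
            spec.band_lo_freqs[0] / 1000,
            (spec.band_lo_freqs[-1] + spec.params.band_width) / 1000,
        ),
        cmap="magma",
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (kHz)")
    return ax


def export_spectrogram_csv(spec: Spectrogram, path) -> None:
    """Debug dump: dense matrix with frame times and band frequencies."""
    import pandas as pd

    df = pd.DataFrame(
        spec.A,
        index=[f"{f:.2f}" for f in spec.band_lo_freqs],
        columns=[f"{t:.6f}" for t in spec.frame_start_times],
    )
    df.index.name = "band_lo_hz"
    df.to_csv(path)
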