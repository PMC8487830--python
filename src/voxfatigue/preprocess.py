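"""Speech preprocessing: pre-emphasis, overlapping framing, Hamming windowing.

Radiotelephony speech is treated as short-term stationary; the signal is
cut into overlapping fixed-length chunks (default 256 samples with a
64-sample stride at 16 kHz, i.e. 16 ms frames overlapping by 192 samples)
after a first-order pre-emphasis filter boosts the high-frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioSignal:
    """A sampled waveform with its sample rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D vector")
        if self.rate <= 0:
            raise ValueError("rate must be a positive integer")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class PreprocessConfig:
    """Framing parameters.

    mu : pre-emphasis coefficient in [0, 1]
    frame_len : samples per frame
    stride : hop between adjacent frames, in samples
    window : "hamming" or "none"
    """

    mu: float = 0.95
    frame_len: int = 256
    stride: int = 64
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if not 0 < self.stride <= self.frame_len:
            raise ValueError("require 0 < stride <= frame_len")
        if self.window not in ("hamming", "none"):
            raise ValueError("window must be 'hamming' or 'none'")


@dataclass(frozen=True)
class FrameMatrix:
    """Stacked overlapping frames (n_frames x frame_len)."""

    frames: np.ndarray
    rate: int
    config: PreprocessConfig = field(default_factory=PreprocessConfig)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
    np.dtype(np.uint8): 128.0,
}


def read_wav(path: str | Path) -> AudioSignal:
    """Read a RIFF/PCM WAV file into an AudioSignal scaled to [-1, 1].

    Stereo files are down-mixed by channel averaging.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.size == 0:
        raise ValueError("zero-length audio")
    data = np.asarray(data)
    unsigned = np.issubdtype(data.dtype, np.unsignedinteger)
    if data.dtype in _PCM_SCALE:
        data = data.astype(float) / _PCM_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / (float(np.iinfo(data.dtype).max) + 1.0)
    else:
        data = data.astype(float)
    if unsigned:
        data = data - 1.0  # uint8 PCM is offset-binary
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioSignal(samples=data, rate=int(rate))


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write an AudioSignal as 16-bit PCM WAV, clipping to [-1, 1]."""
    x = np.clip(signal.samples, -1.0, 1.0)
    wavfile.write(str(path), signal.rate, (x * 32767.0).astype(np.int16))


def preemphasize(signal: AudioSignal, mu: float = 0.95) -> AudioSignal:
    """First-difference high-pass filter y_n = x_n - mu * x_{n-1}.

    The first sample is passed through unchanged (x_{-1} = 0 convention).
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    x = signal.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - mu * x[:-1]
    return AudioSignal(samples=y, rate=signal.rate)


def hamming_window(n_points: int) -> np.ndarray:
    """Symmetric Hamming window w(n) = 0.54 - 0.46 cos(2 pi n / (N-1))."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    n = np.arange(n_points)
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * n / (n_points - 1))


def frame_signal(signal: AudioSignal, config: PreprocessConfig | None = None) -> FrameMatrix:
    """Cut a signal into overlapping frames, optionally Hamming-windowed.

    n_frames = floor((N - frame_len) / stride) + 1; trailing samples that do
    not fill a complete frame are dropped.
    """
    if config is None:
        config = PreprocessConfig()
    x = signal.samples
    flen, hop = config.frame_len, config.stride
    if x.size < flen:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one frame ({flen})"
        )
    n_frames = (x.size - flen) // hop + 1
    idx = np.arange(flen)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    if config.window == "hamming":
        frames = frames * hamming_window(flen)[None, :]
    return FrameMatrix(frames=frames, rate=signal.rate, config=config)


def preprocess_signal(signal: AudioSignal, config: PreprocessConfig | None = None) -> FrameMatrix:
    """Pre-emphasize then frame+window in one call."""
    if config is None:
        config = PreprocessConfig()
    return frame_signal(preemphasize(signal, config.mu), config)
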