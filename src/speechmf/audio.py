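"""Waveform container, WAV I/O, and the magnitude transform.

All downstream fractal analysis operates on the absolute value of the
acoustic pressure series (magnitudes-only decomposition); the sign series
is redundant for signals that are symmetric about zero, and the direct
multifractal estimator is undefined for non-positive measures.

On-disk canonical form is 16-bit PCM mono RIFF/WAV; floats are scaled to
[-1, 1] on read and to full scale on write so fixtures round-trip
bit-exactly up to the 2**-15 quantization step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "MagnitudeSeries",
    "read_wav",
    "write_wav",
    "magnitude_series",
]

_PCM16_SCALE = 32767.0


@dataclass
class Waveform:
    """A mono acoustic pressure series with its sampling rate."""

    samples: np.ndarray
    rate: int
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if self.samples.size < 1:
            raise ValueError("Waveform requires at least one sample")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.rate = int(self.rate)

    @property
    def duration_seconds(self) -> float:
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class MagnitudeSeries:
    """Non-negative |pressure| series feeding the multifractal estimator."""

    values: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size < 1:
            raise ValueError("MagnitudeSeries requires at least one value")
        if np.any(self.values < 0):
            raise ValueError("magnitudes must be non-negative")

    @property
    def is_degenerate(self) -> bool:
        """True when the series carries no mass (all zeros)."""
        return bool(np.all(self.values == 0.0))

    def __len__(self) -> int:
        return self.values.size


def read_wav(path: str | Path, channel_policy: str = "strict") -> Waveform:
    """Read a PCM WAV file into a Waveform scaled to [-1, 1].

    Parameters
    ----------
    path:
        Path to a RIFF/WAV file.
    channel_policy:
        ``"strict"`` rejects multichannel input; ``"average"`` averages
        channels to mono.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such WAV file: {path}")
    rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        if channel_policy == "average":
            data = data.mean(axis=1)
        else:
            raise ValueError("multichannel unsupported (use channel_policy='average')")
    if np.issubdtype(data.dtype, np.integer):
        # symmetric full scale (matches the write-side scaling exactly)
        samples = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        samples = data.astype(np.float64)
    return Waveform(samples=samples, rate=int(rate), label=path.stem)


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a Waveform as 16-bit PCM mono, clipping to [-1, 1]."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(clipped * _PCM16_SCALE).astype(np.int16)
    wavfile.write(str(path), w.rate, pcm)


def magnitude_series(w: Waveform) -> MagnitudeSeries:
    """Element-wise absolute value of the waveform (length preserved)."""
    if len(w) < 1:
        raise ValueError("empty waveform")
    return MagnitudeSeries(values=np.abs(w.samples), source_label=w.label)
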