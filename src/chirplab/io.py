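"""Audio input/output and annotation export.

Reads PCM WAV recordings into the canonical :class:`AudioRecording`
container, peak-normalizes waveforms to the [-1, 1] range the detector
expects, and writes Audacity label tracks so detections can be inspected
visually in an ordinary audio editor.

Conventions: sample indices are 0-based, event intervals are half-open
``[onset, offset)`` in samples, and times in seconds are ``index /
sample_rate``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile


class AudioFormatError(ValueError):
    """Raised when a file cannot be read as PCM WAV audio."""


# full-scale divisors for integer PCM widths
_PCM_SCALE = {
    np.dtype(np.int16): 2**15,
    np.dtype(np.int32): 2**31,
}


@dataclass(frozen=True)
class AudioRecording:
    """A mono waveform with its sample rate.

    ``samples`` are dimensionless float amplitudes; after
    :func:`normalize` they span [-1, 1] with ``max(|samples|) == 1`` for
    any non-silent signal.
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError("AudioRecording holds a single channel")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def load_audio(path: str | Path, channel: str | int = "mix") -> AudioRecording:
    """Read a PCM WAV file into a mono :class:`AudioRecording`.

    Integer PCM is divided by full scale; float WAV is taken as-is.  No
    peak normalization is applied here — call :func:`normalize` before
    detection.

    Parameters
    ----------
    path
        Path to a PCM WAV file (16/24/32-bit integer or float).
    channel
        ``"mix"`` (default) averages the channels of a multi-channel
        file; an integer selects a single channel.

    Raises
    ------
    AudioFormatError
        If the file is unreadable, compressed, or holds no samples.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot read {path} as PCM WAV: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"{path} contains no samples")

    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        samples = data.astype(np.float64)

    if samples.ndim == 2:
        if channel == "mix":
            samples = samples.mean(axis=1)
        else:
            samples = samples[:, int(channel)]
    return AudioRecording(samples=samples, sample_rate=int(rate), source_id=path.stem)


def save_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV."""
    # symmetric full-scale convention: divide by 2^15 on read, multiply on
    # write, so round-trips stay within one quantization step
    scaled = np.round(np.clip(rec.samples, -1.0, 1.0) * 2**15)
    pcm = np.clip(scaled, -(2**15), 2**15 - 1).astype(np.int16)
    wavfile.write(Path(path), rec.sample_rate, pcm)


def normalize(rec: AudioRecording) -> AudioRecording:
    """Peak-normalize amplitudes to the range [-1, 1].

    Silent input (all zeros) is returned unchanged rather than raising:
    downstream detection then correctly yields zero events.
    """
    peak = np.max(np.abs(rec.samples)) if len(rec.samples) else 0.0
    if peak == 0.0:
        return rec
    return replace(rec, samples=rec.samples / peak)


def export_audacity_labels(
    events: Iterable[tuple[float, float, str]], path: str | Path
) -> None:
    """Write labeled intervals in the Audacity label-track format.

    One TAB-separated line per event — ``start<TAB>end<TAB>label`` with
    times in seconds at 6 decimal places — sorted chronologically, so the
    file imports directly into the editor for visual validation.
    """
    rows = sorted(events, key=lambda ev: (ev[0], ev[1]))
    for start, end, _ in rows:
        if start > end:
            raise ValueError(f"label interval has start {start} > end {end}")
    with open(path, "w", encoding="utf-8") as fh:
        for start, end, label in rows:
            fh.write(f"{start:.6f}\t{end:.6f}\t{label}\n")


def read_audacity_labels(path: str | Path) -> list[tuple[float, float, str]]:
    """Parse an Audacity label track back into (start_s, end_s, label) tuples."""
    out: list[tuple[float, float, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            out.append((float(parts[0]), float(parts[1]), parts[2] if len(parts) > 2 else ""))
    return out
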