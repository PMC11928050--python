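"""Syllable detection by amplitude-envelope double thresholding.

The detector works in three stages, mirroring how cricket stridulation
is segmented by eye on an oscillogram:

1. :func:`compute_envelope` — a frame-maximum amplitude envelope over
   short (~2 ms) fragments of the normalized waveform.
2. :func:`detect_events` — hysteresis thresholding: an event opens where
   the envelope exceeds a high threshold (default 0.1 of full scale) and
   extends outward over every contiguous frame still above a second, low
   threshold that separates song from the noise floor between syllables.
3. :func:`refine_boundaries` — each frame-resolution boundary is moved
   to the nearest zero-amplitude point of the raw waveform, so onsets
   and offsets land where the wing stroke actually starts and stops.

:func:`filter_syllables` then keeps only events whose duration is
plausible for a single syllable, discarding clicks and merged artefacts.
Detection is deterministic throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert

from .io import AudioRecording

logger = logging.getLogger(__name__)

#: minimum number of consecutive near-zero samples that count as a
#: genuine silence boundary (single near-zero samples occur at carrier
#: zero crossings inside a syllable and must not terminate it)
_MIN_ZERO_RUN = 3


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and duration windows for syllable/chirp detection.

    Attributes
    ----------
    high_threshold
        Envelope amplitude that defines a calling-song event (0.1 of
        full scale on a normalized recording).
    low_threshold
        Second, low threshold that separates song from the noise floor;
        an open event extends over contiguous frames above it.  The
        default 0.05 sits above the frame-maximum of a typical chamber
        noise floor after normalization (see the methods note) and well
        below any real syllable.
    frame_ms, hop_fraction
        Envelope fragment length in milliseconds and hop as a fraction
        of the frame (50% overlap by default).
    min_syllable_ms, max_syllable_ms
        Duration window for a single syllable; events outside it are
        discarded as clicks or merged artefacts.
    max_intra_chirp_gap_ms
        Largest silent gap still counted as an inter-syllable interval;
        larger gaps separate chirps.
    min_inter_chirp_gap_ms, max_inter_chirp_gap_ms
        Gap window classified as an inter-chirp interval; gaps above the
        maximum are pauses in calling and excluded from interval
        statistics.
    zero_eps
        Absolute amplitude below which a sample counts as "zero" when
        refining boundaries (exact zeros are rare in dithered PCM).
    envelope_method
        ``"frame_max"`` (default) or ``"hilbert"`` (frame-maximum of the
        analytic-signal magnitude).
    """

    high_threshold: float = 0.1
    low_threshold: float = 0.05
    frame_ms: float = 2.0
    hop_fraction: float = 0.5
    min_syllable_ms: float = 5.0
    max_syllable_ms: float = 60.0
    max_intra_chirp_gap_ms: float = 40.0
    min_inter_chirp_gap_ms: float = 40.0
    max_inter_chirp_gap_ms: float = 2000.0
    zero_eps: float = 1e-4
    envelope_method: str = "frame_max"

    def __post_init__(self) -> None:
        if not 0.0 < self.low_threshold < self.high_threshold < 1.0:
            raise ValueError("need 0 < low_threshold < high_threshold < 1")
        if not 0.0 < self.min_syllable_ms < self.max_syllable_ms:
            raise ValueError("need 0 < min_syllable_ms < max_syllable_ms")
        if self.max_intra_chirp_gap_ms > self.min_inter_chirp_gap_ms:
            raise ValueError(
                "max_intra_chirp_gap_ms must not exceed min_inter_chirp_gap_ms "
                "(gap classification is a partition)"
            )
        if self.min_inter_chirp_gap_ms >= self.max_inter_chirp_gap_ms:
            raise ValueError("inter-chirp gap window is empty")
        if self.frame_ms <= 0 or not 0.0 < self.hop_fraction <= 1.0:
            raise ValueError("invalid frame_ms / hop_fraction")
        if self.envelope_method not in ("frame_max", "hilbert"):
            raise ValueError("envelope_method must be 'frame_max' or 'hilbert'")

    # -- flat key=value config files ------------------------------------
    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "DetectionConfig":
        kwargs: dict[str, object] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key not in cls.__dataclass_fields__:
                    raise ValueError(f"unknown detection option {key!r}")
                kwargs[key] = value if key == "envelope_method" else float(value)
        return cls(**kwargs)  # type: ignore[arg-type]


@dataclass(frozen=True)
class Envelope:
    """Per-frame amplitude envelope of a recording."""

    values: np.ndarray
    frame_length: int
    hop_length: int
    sample_rate: int
    n_samples: int

    @property
    def frame_starts(self) -> np.ndarray:
        """Sample index where each frame begins."""
        return np.arange(len(self.values)) * self.hop_length


@dataclass(frozen=True)
class RawCandidate:
    """A frame-resolution event interval prior to boundary refinement."""

    start_sample: int
    end_sample: int
    peak_amplitude: float


@dataclass(frozen=True)
class SyllableEvent:
    """One detected syllable; interval is half-open in samples."""

    onset_sample: int
    offset_sample: int
    sample_rate: int
    peak_amplitude: float

    def __post_init__(self) -> None:
        if self.onset_sample >= self.offset_sample:
            raise ValueError("syllable must have onset < offset")

    @property
    def onset_s(self) -> float:
        return self.onset_sample / self.sample_rate

    @property
    def offset_s(self) -> float:
        return self.offset_sample / self.sample_rate

    @property
    def duration_ms(self) -> float:
        return (self.offset_sample - self.onset_sample) / self.sample_rate * 1e3


def compute_envelope(
    rec: AudioRecording,
    frame_ms: float = 2.0,
    hop_fraction: float = 0.5,
    method: str = "frame_max",
) -> Envelope:
    """Extract the amplitude envelope over many small waveform fragments.

    Each frame's value is the maximum of ``|x|`` within the window
    (``method="frame_max"``) or of the Hilbert analytic magnitude
    (``method="hilbert"``); frames advance by ``frame_length *
    hop_fraction`` samples.  A frame longer than the recording yields a
    single-frame envelope.
    """
    x = rec.samples
    fs = rec.sample_rate
    frame_length = max(1, round(frame_ms * fs / 1000.0))
    hop = max(1, round(frame_length * hop_fraction))
    n = len(x)
    n_frames = max(1, math.ceil(n / hop))

    mag = np.abs(hilbert(x)) if method == "hilbert" else np.abs(x)
    pad = (n_frames - 1) * hop + frame_length - n
    if pad > 0:
        mag = np.concatenate([mag, np.zeros(pad)])
    windows = sliding_window_view(mag, frame_length)[::hop][:n_frames]
    values = windows.max(axis=1)
    return Envelope(
        values=values,
        frame_length=frame_length,
        hop_length=hop,
        sample_rate=fs,
        n_samples=n,
    )


def detect_events(env: Envelope, cfg: DetectionConfig) -> list[RawCandidate]:
    """Hysteresis detection of calling-song events on the envelope.

    A candidate opens at a frame exceeding ``high_threshold`` and spans
    the surrounding contiguous frames above ``low_threshold``; runs that
    never reach the high threshold are noise and produce no event.
    Candidates are frame-resolution sample intervals.
    """
    above_low = env.values > cfg.low_threshold
    if not above_low.any():
        return []
    # contiguous runs of frames above the low threshold
    edges = np.flatnonzero(np.diff(above_low.astype(np.int8)))
    starts = np.concatenate([[0] if above_low[0] else [], edges[~above_low[edges]] + 1]).astype(int)
    ends = np.concatenate([edges[above_low[edges]] + 1, [len(above_low)] if above_low[-1] else []]).astype(int)

    out: list[RawCandidate] = []
    for s, e in zip(starts, ends):
        peak = float(env.values[s:e].max())
        if peak <= cfg.high_threshold:
            continue  # never exceeded the event threshold: noise
        start_sample = int(s * env.hop_length)
        end_sample = min(int((e - 1) * env.hop_length + env.frame_length), env.n_samples)
        out.append(RawCandidate(start_sample, end_sample, peak))
    return out


def _zero_runs(is_zero: np.ndarray, min_run: int = _MIN_ZERO_RUN) -> np.ndarray:
    """Start/end (half-open) of runs of True of length >= min_run, shape (k, 2)."""
    if not is_zero.any():
        return np.empty((0, 2), dtype=int)
    d = np.diff(is_zero.astype(np.int8))
    starts = np.concatenate([[0] if is_zero[0] else [], np.flatnonzero(d == 1) + 1]).astype(int)
    ends = np.concatenate([np.flatnonzero(d == -1) + 1, [len(is_zero)] if is_zero[-1] else []]).astype(int)
    runs = np.stack([starts, ends], axis=1)
    return runs[(runs[:, 1] - runs[:, 0]) >= min_run]


def _refine_onset(x: np.ndarray, anchor: int, lo_limit: int, eps: float) -> int:
    """Move an onset to the zero-amplitude boundary at or before `anchor`.

    Prefers the nearest run of near-zero samples (true silence); falls
    back to the nearest sign change (ties widen: take the earlier
    sample); keeps `anchor` clamped to `lo_limit` when neither exists.
    """
    seg = x[lo_limit : anchor + 1]
    runs = _zero_runs(np.abs(seg) <= eps)
    if len(runs):
        return lo_limit + int(runs[-1, 1]) - 1  # last sample of nearest silence run
    sign_change = np.flatnonzero(seg[:-1] * seg[1:] < 0)
    if len(sign_change):
        return lo_limit + int(sign_change[-1])  # earlier side of the crossing
    return max(lo_limit, anchor)


def _refine_offset(x: np.ndarray, anchor: int, hi_limit: int, eps: float) -> int:
    """Offset counterpart of :func:`_refine_onset`; returns half-open end."""
    seg = x[anchor : hi_limit + 1]
    runs = _zero_runs(np.abs(seg) <= eps)
    if len(runs):
        return anchor + int(runs[0, 0])  # first sample of nearest silence run
    sign_change = np.flatnonzero(seg[:-1] * seg[1:] < 0)
    if len(sign_change):
        return anchor + int(sign_change[0]) + 1  # later side of the crossing
    return min(hi_limit, anchor + 1)


def refine_boundaries(
    rec: AudioRecording,
    candidates: Sequence[RawCandidate],
    cfg: DetectionConfig | None = None,
) -> list[SyllableEvent]:
    """Snap frame-resolution boundaries to zero amplitude on the waveform.

    Within each candidate the first and last samples whose magnitude
    exceeds ``low_threshold`` anchor the true burst; each boundary then
    moves outward to the nearest zero-amplitude point — a run of
    near-zero samples when genuine silence surrounds the syllable,
    otherwise the nearest zero crossing.  The search never crosses a
    neighbouring event, and a candidate containing no above-threshold
    sample (pure envelope artefact) is kept unchanged.  Refinement is
    idempotent.
    """
    cfg = cfg or DetectionConfig()
    x = rec.samples
    frame_length = max(1, round(cfg.frame_ms * rec.sample_rate / 1000.0))
    events: list[SyllableEvent] = []
    prev_end = 0
    ordered = sorted(candidates, key=lambda c: c.start_sample)
    for i, cand in enumerate(ordered):
        next_start = ordered[i + 1].start_sample if i + 1 < len(ordered) else len(x)
        s = max(cand.start_sample, prev_end)
        e = min(cand.end_sample, next_start, len(x))
        if e <= s:
            continue
        body = np.abs(x[s:e]) > cfg.low_threshold
        idx = np.flatnonzero(body)
        if len(idx) == 0:
            # degenerate candidate in silence: keep frame-edge boundaries
            onset, offset = s, e
            logger.warning(
                "candidate [%d, %d) has no sample above low threshold; boundaries kept",
                s,
                e,
            )
        else:
            anchor_on = s + int(idx[0])
            anchor_off = s + int(idx[-1])
            lo_limit = max(prev_end, s - frame_length, 0)
            hi_limit = min(next_start, e + frame_length, len(x)) - 1
            onset = _refine_onset(x, anchor_on, lo_limit, cfg.zero_eps)
            offset = _refine_offset(x, anchor_off, hi_limit, cfg.zero_eps)
        if offset <= onset:
            offset = onset + 1
        events.append(
            SyllableEvent(
                onset_sample=onset,
                offset_sample=offset,
                sample_rate=rec.sample_rate,
                peak_amplitude=cand.peak_amplitude,
            )
        )
        prev_end = offset
    return events


def filter_syllables(
    events: Sequence[SyllableEvent], cfg: DetectionConfig
) -> tuple[list[SyllableEvent], int]:
    """Keep events with a plausible single-syllable duration.

    Returns the surviving events and the number discarded by the
    ``min_syllable_ms``/``max_syllable_ms`` window.
    """
    kept = [
        ev
        for ev in events
        if cfg.min_syllable_ms <= ev.duration_ms <= cfg.max_syllable_ms
    ]
    return kept, len(events) - len(kept)


def detect_syllables(
    rec: AudioRecording, cfg: DetectionConfig | None = None
) -> list[SyllableEvent]:
    """Full detection pipeline: envelope → hysteresis → refine → filter.

    Expects a peak-normalized recording (see :func:`chirplab.io.normalize`).
    """
    cfg = cfg or DetectionConfig()
    env = compute_envelope(
        rec, frame_ms=cfg.frame_ms, hop_fraction=cfg.hop_fraction, method=cfg.envelope_method
    )
    candidates = detect_events(env, cfg)
    refined = refine_boundaries(rec, candidates, cfg)
    kept, _ = filter_syllables(refined, cfg)
    return kept
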