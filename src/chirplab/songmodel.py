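"""Chirp grouping and per-recording song features.

A cricket calling song is a pulse train: syllables (single wing
strokes, ~15–25 ms) grouped into chirps of typically 3–4 syllables,
with chirp periods of the order of 300–400 ms.  This module turns a
sorted list of detected syllables into :class:`Chirp` objects, and
computes the per-recording feature vector (:class:`RecordingSummary`)
that group comparisons operate on: chirp and syllable counts and
durations, inter-chirp and inter-syllable intervals, the syllable-count
mixture, and the dominant (carrier) frequency.

Gap classification partitions silent gaps between consecutive
syllables: gaps up to ``max_intra_chirp_gap_ms`` are inter-syllable
intervals; gaps in ``(max_intra_chirp_gap_ms, max_inter_chirp_gap_ms]``
are inter-chirp intervals; anything longer is a pause in calling and is
excluded from interval statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .detect import DetectionConfig, SyllableEvent
from .io import AudioRecording

#: column order of the per-recording summary CSV
SUMMARY_COLUMNS = [
    "source_id",
    "individual_id",
    "n_chirps",
    "n_syllables",
    "mean_chirp_duration_ms",
    "mean_inter_chirp_interval_ms",
    "mean_syllable_duration_ms",
    "mean_inter_syllable_interval_ms",
    "mean_chirp_duration_ms_3syl",
    "mean_chirp_duration_ms_4syl",
    "mean_syllable_duration_ms_3syl",
    "mean_syllable_duration_ms_4syl",
    "mean_inter_syllable_interval_ms_3syl",
    "mean_inter_syllable_interval_ms_4syl",
    "mean_3to4_transition_interval_ms",
    "dominant_frequency_hz",
    "prop_1syl",
    "prop_2syl",
    "prop_3syl",
    "prop_4syl",
    "prop_5syl",
]


@dataclass
class Chirp:
    """An ordered group of syllables separated by short gaps."""

    syllables: list[SyllableEvent]
    following_inter_chirp_interval_ms: float | None = None

    def __post_init__(self) -> None:
        if not self.syllables:
            raise ValueError("a chirp contains at least one syllable")

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)

    @property
    def onset_s(self) -> float:
        return self.syllables[0].onset_s

    @property
    def offset_s(self) -> float:
        return self.syllables[-1].offset_s

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1e3

    @property
    def inter_syllable_intervals_ms(self) -> list[float]:
        return [
            (b.onset_s - a.offset_s) * 1e3
            for a, b in zip(self.syllables, self.syllables[1:])
        ]

    @property
    def syllable_durations_ms(self) -> list[float]:
        return [s.duration_ms for s in self.syllables]


def group_chirps(
    syllables: Sequence[SyllableEvent], cfg: DetectionConfig | None = None
) -> list[Chirp]:
    """Partition sorted syllables into chirps by gap classification.

    Every syllable ends up in exactly one chirp.  The recorded
    ``following_inter_chirp_interval_ms`` is ``None`` for the last chirp
    and for chirps followed by a pause longer than
    ``max_inter_chirp_gap_ms``.
    """
    cfg = cfg or DetectionConfig()
    if not syllables:
        return []
    chirps: list[Chirp] = []
    current = [syllables[0]]
    for prev, nxt in zip(syllables, syllables[1:]):
        gap_ms = (nxt.onset_s - prev.offset_s) * 1e3
        if gap_ms < 0:
            raise ValueError("syllables must be sorted and non-overlapping")
        if gap_ms <= cfg.max_intra_chirp_gap_ms:
            current.append(nxt)
        else:
            interval = gap_ms if gap_ms <= cfg.max_inter_chirp_gap_ms else None
            chirps.append(Chirp(current, following_inter_chirp_interval_ms=interval))
            current = [nxt]
    chirps.append(Chirp(current, following_inter_chirp_interval_ms=None))
    return chirps


def syllable_count_distribution(
    chirps: Sequence[Chirp],
) -> dict[int, tuple[int, float]]:
    """Tabulate chirps by syllable count.

    Returns ``{count: (n_chirps, proportion)}`` for every count from 1
    to the maximum observed (intermediate absent classes appear with
    zero), or an empty dict for no chirps.  No class is ever dropped —
    1- and 5-syllable chirps are rare in calling song but are tabulated.
    """
    if not chirps:
        return {}
    counts = np.array([c.n_syllables for c in chirps])
    total = len(counts)
    tab = np.bincount(counts, minlength=counts.max() + 1)
    return {k: (int(tab[k]), tab[k] / total) for k in range(1, counts.max() + 1)}


def transition_intervals(
    chirps: Sequence[Chirp], from_count: int, to_count: int
) -> list[float]:
    """Inter-chirp intervals at transitions between two chirp classes.

    Collects the interval wherever a ``from_count``-syllable chirp is
    immediately followed by a ``to_count``-syllable chirp (pauses do not
    count as adjacency).  An honest empty list is returned when no such
    transition occurs.
    """
    out: list[float] = []
    for a, b in zip(chirps, chirps[1:]):
        if (
            a.n_syllables == from_count
            and b.n_syllables == to_count
            and a.following_inter_chirp_interval_ms is not None
        ):
            out.append(a.following_inter_chirp_interval_ms)
    return out


def dominant_frequency(
    rec: AudioRecording, band_hz: tuple[float, float] = (1000.0, 10000.0)
) -> float | None:
    """Dominant (carrier) frequency of a recording in Hz.

    Peak of a Welch averaged periodogram (8192-sample Hann segments,
    50% overlap) restricted to ``band_hz``.  Returns ``None`` for a
    silent recording, where the quantity is undefined.
    """
    x = rec.samples
    if not np.any(x):
        return None
    nperseg = min(8192, len(x))
    freqs, psd = sps.welch(x, fs=rec.sample_rate, window="hann", nperseg=nperseg)
    lo, hi = band_hz
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        mask = np.ones_like(freqs, dtype=bool)
    band_freqs = freqs[mask]
    return float(band_freqs[np.argmax(psd[mask])])


@dataclass
class RecordingSummary:
    """Per-recording feature vector; the unit of group comparisons."""

    source_id: str
    n_chirps: int
    n_syllables: int
    mean_chirp_duration_ms: float | None
    mean_inter_chirp_interval_ms: float | None
    mean_syllable_duration_ms: float | None
    mean_inter_syllable_interval_ms: float | None
    mean_chirp_duration_ms_3syl: float | None
    mean_chirp_duration_ms_4syl: float | None
    mean_syllable_duration_ms_3syl: float | None
    mean_syllable_duration_ms_4syl: float | None
    mean_inter_syllable_interval_ms_3syl: float | None
    mean_inter_syllable_interval_ms_4syl: float | None
    mean_3to4_transition_interval_ms: float | None
    dominant_frequency_hz: float | None
    syllable_count_proportions: dict[int, float]
    individual_id: str = ""

    def to_row(self) -> dict[str, object]:
        row = {
            "source_id": self.source_id,
            "individual_id": self.individual_id,
            "n_chirps": self.n_chirps,
            "n_syllables": self.n_syllables,
            "mean_chirp_duration_ms": self.mean_chirp_duration_ms,
            "mean_inter_chirp_interval_ms": self.mean_inter_chirp_interval_ms,
            "mean_syllable_duration_ms": self.mean_syllable_duration_ms,
            "mean_inter_syllable_interval_ms": self.mean_inter_syllable_interval_ms,
            "mean_chirp_duration_ms_3syl": self.mean_chirp_duration_ms_3syl,
            "mean_chirp_duration_ms_4syl": self.mean_chirp_duration_ms_4syl,
            "mean_syllable_duration_ms_3syl": self.mean_syllable_duration_ms_3syl,
            "mean_syllable_duration_ms_4syl": self.mean_syllable_duration_ms_4syl,
            "mean_inter_syllable_interval_ms_3syl": self.mean_inter_syllable_interval_ms_3syl,
            "mean_inter_syllable_interval_ms_4syl": self.mean_inter_syllable_interval_ms_4syl,
            "mean_3to4_transition_interval_ms": self.mean_3to4_transition_interval_ms,
            "dominant_frequency_hz": self.dominant_frequency_hz,
        }
        for k in range(1, 6):
            row[f"prop_{k}syl"] = self.syllable_count_proportions.get(k, 0.0)
        return row


def _mean(values: Iterable[float]) -> float | None:
    vals = list(values)
    return float(np.mean(vals)) if vals else None


def summarize_recording(
    rec: AudioRecording | None,
    chirps: Sequence[Chirp],
    cfg: DetectionConfig | None = None,
    chirp_cap: int = 3500,
    band_hz: tuple[float, float] = (1000.0, 10000.0),
    individual_id: str = "",
    source_id: str | None = None,
) -> RecordingSummary:
    """Compute the full per-recording feature vector.

    Chirp-level means (chirp duration, inter-chirp interval) are taken
    over all chirps of the recording; syllable-level means (syllable
    duration, inter-syllable interval), overall and per chirp class, are
    taken over the first ``min(n_chirps, chirp_cap)`` chirps (default
    cap 3500).  ``rec`` may be ``None`` when only timing features are
    needed, in which case the dominant frequency is absent.
    """
    cfg = cfg or DetectionConfig()
    chirps = list(chirps)
    sid = source_id if source_id is not None else (rec.source_id if rec else "")
    n_syllables = sum(c.n_syllables for c in chirps)
    capped = chirps[: min(len(chirps), chirp_cap)]

    def class_chirps(k: int) -> list[Chirp]:
        return [c for c in capped if c.n_syllables == k]

    syl_dur = [d for c in capped for d in c.syllable_durations_ms]
    isi = [g for c in capped for g in c.inter_syllable_intervals_ms]
    dist = syllable_count_distribution(chirps)

    dom = dominant_frequency(rec, band_hz) if rec is not None else None
    return RecordingSummary(
        source_id=sid,
        individual_id=individual_id,
        n_chirps=len(chirps),
        n_syllables=n_syllables,
        mean_chirp_duration_ms=_mean(c.duration_ms for c in chirps),
        mean_inter_chirp_interval_ms=_mean(
            c.following_inter_chirp_interval_ms
            for c in chirps
            if c.following_inter_chirp_interval_ms is not None
        ),
        mean_syllable_duration_ms=_mean(syl_dur),
        mean_inter_syllable_interval_ms=_mean(isi),
        mean_chirp_duration_ms_3syl=_mean(c.duration_ms for c in class_chirps(3)),
        mean_chirp_duration_ms_4syl=_mean(c.duration_ms for c in class_chirps(4)),
        mean_syllable_duration_ms_3syl=_mean(
            d for c in class_chirps(3) for d in c.syllable_durations_ms
        ),
        mean_syllable_duration_ms_4syl=_mean(
            d for c in class_chirps(4) for d in c.syllable_durations_ms
        ),
        mean_inter_syllable_interval_ms_3syl=_mean(
            g for c in class_chirps(3) for g in c.inter_syllable_intervals_ms
        ),
        mean_inter_syllable_interval_ms_4syl=_mean(
            g for c in class_chirps(4) for g in c.inter_syllable_intervals_ms
        ),
        mean_3to4_transition_interval_ms=_mean(transition_intervals(chirps, 3, 4)),
        dominant_frequency_hz=dom,
        syllable_count_proportions={k: p for k, (_, p) in dist.items()},
    )


def inclusion_filter(n_days: float, n_chirps: int) -> bool:
    """Whether an individual's data enter the full chirp-duration analysis.

    True only for individuals recorded for more than 4 days with more
    than 20,000 chirps — both strict inequalities, so exactly 4 days or
    exactly 20,000 chirps is excluded.
    """
    return n_days > 4 and n_chirps > 20000


def summaries_to_frame(summaries: Sequence[RecordingSummary]) -> pd.DataFrame:
    """Stack summaries into a DataFrame with the stable column order."""
    return pd.DataFrame([s.to_row() for s in summaries], columns=SUMMARY_COLUMNS)


def write_summary_csv(summaries: Sequence[RecordingSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def chirps_to_frame(chirps: Sequence[Chirp], source_id: str = "") -> pd.DataFrame:
    """One row per chirp: onset, duration, syllable count, intervals."""
    rows = [
        {
            "source_id": source_id,
            "chirp_index": i,
            "onset_s": c.onset_s,
            "offset_s": c.offset_s,
            "duration_ms": c.duration_ms,
            "n_syllables": c.n_syllables,
            "mean_inter_syllable_interval_ms": _mean(c.inter_syllable_intervals_ms),
            "following_inter_chirp_interval_ms": c.following_inter_chirp_interval_ms,
        }
        for i, c in enumerate(chirps)
    ]
    columns = [
        "source_id",
        "chirp_index",
        "onset_s",
        "offset_s",
        "duration_ms",
        "n_syllables",
        "mean_inter_syllable_interval_ms",
        "following_inter_chirp_interval_ms",
    ]
    return pd.DataFrame(rows, columns=columns)
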