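import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chirplab import detect, io, songmodel, synth


def events_from_gaps(gaps_ms, dur_ms=18.0, fs=16000):
    """Build syllable events with prescribed inter-event gaps."""
    events = []
    cursor = 1000
    dur = round(dur_ms * fs / 1000)
    for gap in itertools.chain([None], gaps_ms):
        if gap is not None:
            cursor += round(gap * fs / 1000)
        events.append(detect.SyllableEvent(cursor, cursor + dur, fs, 1.0))
        cursor += dur
    return events


class TestGroupChirps:
    def test_gap_rule_two_chirps(self):
        events = events_from_gaps([15, 15, 15, 300, 15, 15, 15])
        chirps = songmodel.group_chirps(events)
        assert [c.n_syllables for c in chirps] == [4, 4]
        assert chirps[0].following_inter_chirp_interval_ms == pytest.approx(300, abs=0.1)
        assert chirps[1].following_inter_chirp_interval_ms is None

    def test_single_syllable_chirp(self):
        chirps = songmodel.group_chirps(events_from_gaps([]))
        assert len(chirps) == 1
        assert chirps[0].n_syllables == 1
        assert chirps[0].inter_syllable_intervals_ms == []

    def test_pause_excluded_from_intervals(self):
        events = events_from_gaps([15, 2500, 15])
        chirps = songmodel.group_chirps(events)
        assert [c.n_syllables for c in chirps] == [2, 2]
        assert chirps[0].following_inter_chirp_interval_ms is None  # pause, not interval

    def test_empty_input(self):
        assert songmodel.group_chirps([]) == []

    def test_recovers_generator_mixture_exactly(self):
        spec = replace(
            synth.preset("LD-like"),
            n_chirps=100,
            seed=23,
            sample_rate=16000,
            syllable_count_probs={3: 0.25, 4: 0.75},
        )
        rec, truth = synth.synthesize_song(spec)
        chirps = songmodel.group_chirps(detect.detect_syllables(rec))
        assert [c.n_syllables for c in chirps] == truth.syllable_counts()

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.sampled_from([10.0, 20.0, 40.0, 60.0, 400.0, 2500.0]), max_size=15))
    def test_partition_property(self, gaps):
        events = events_from_gaps(gaps)
        chirps = songmodel.group_chirps(events)
        regrouped = [s for c in chirps for s in c.syllables]
        assert regrouped == events  # every syllable in exactly one chirp, in order

    def test_additivity_of_chirp_duration(self):
        events = events_from_gaps([12, 17, 13])
        (chirp,) = songmodel.group_chirps(events)
        total = sum(chirp.syllable_durations_ms) + sum(chirp.inter_syllable_intervals_ms)
        assert chirp.duration_ms == pytest.approx(total, abs=1e-9)


class TestSyllableCountDistribution:
    def test_simple_tabulation(self):
        events = events_from_gaps([15, 15, 300, 15, 15, 300, 15, 15, 300, 15, 15, 15])
        chirps = songmodel.group_chirps(events)
        dist = songmodel.syllable_count_distribution(chirps)
        assert dist[3] == (3, 0.75)
        assert dist[4] == (1, 0.25)

    def test_single_class(self):
        chirps = songmodel.group_chirps(events_from_gaps([15, 15]))
        dist = songmodel.syllable_count_distribution(chirps)
        assert dist == {1: (0, 0.0), 2: (0, 0.0), 3: (1, 1.0)}

    def test_empty(self):
        assert songmodel.syllable_count_distribution([]) == {}

    def test_large_sample_within_binomial_error(self):
        # ground-truth timing draws only: no audio needed for this law-of-
        # large-numbers check at 5000 chirps
        probs = {2: 0.0139, 3: 0.2354, 4: 0.7507}
        spec = replace(
            synth.preset("LD-like"), n_chirps=5000, syllable_count_probs=probs, seed=31
        )
        rng = np.random.default_rng(spec.seed)
        truth = synth.synthesize_timing(spec, rng)
        counts = np.array(truth.syllable_counts())
        for k, p in probs.items():
            se = np.sqrt(p * (1 - p) / 5000)
            assert abs((counts == k).mean() - p) <= 3 * se


class TestTransitionIntervals:
    def test_alternating_sequence(self):
        events = events_from_gaps(
            [15, 15, 100, 15, 15, 15, 200, 15, 15, 300, 15, 15, 15]
        )  # counts 3,4,3,4 with inter-chirp gaps 100, 200, 300
        chirps = songmodel.group_chirps(events)
        assert [c.n_syllables for c in chirps] == [3, 4, 3, 4]
        got = songmodel.transition_intervals(chirps, 3, 4)
        assert got == pytest.approx([100, 300], abs=0.1)
        assert songmodel.transition_intervals(chirps, 4, 3) == pytest.approx([200], abs=0.1)

    def test_no_matching_transitions(self):
        chirps = songmodel.group_chirps(events_from_gaps([15, 15, 100, 15, 15]))
        assert songmodel.transition_intervals(chirps, 3, 4) == []

    def test_ground_truth_gaps_recovered(self):
        spec = replace(synth.preset("LD-like"), n_chirps=40, seed=13, sample_rate=16000)
        rec, truth = synth.synthesize_song(spec)
        chirps = songmodel.group_chirps(detect.detect_syllables(rec))
        fs = spec.sample_rate
        true_gaps = [
            (b[0] - a[1]) * 1e3
            for a, b in zip(truth.chirps, truth.chirps[1:])
            if a[2] == 3 and b[2] == 4
        ]
        got = songmodel.transition_intervals(chirps, 3, 4)
        assert len(got) == len(true_gaps)
        np.testing.assert_allclose(got, true_gaps, atol=2e3 / fs)


class TestDominantFrequency:
    def test_pure_sine(self):
        fs = 44100
        t = np.arange(fs) / fs
        rec = io.AudioRecording(np.sin(2 * np.pi * 4900 * t), fs)
        bin_hz = fs / 8192
        assert songmodel.dominant_frequency(rec) == pytest.approx(4900, abs=bin_hz)

    def test_dominant_component_wins(self):
        fs = 44100
        t = np.arange(fs) / fs
        x = np.sin(2 * np.pi * 4900 * t) + 0.2 * np.sin(2 * np.pi * 2000 * t)
        rec = io.AudioRecording(x, fs)
        assert songmodel.dominant_frequency(rec) == pytest.approx(4900, abs=fs / 8192)

    def test_synthetic_song_carrier(self, noisy_song):
        rec, truth = noisy_song
        got = songmodel.dominant_frequency(rec)
        # a periodically gated carrier is a comb around f0 spaced at the
        # syllable repetition rate (~1/34 ms ~ 29 Hz); the spectral peak
        # lands on a comb line near the carrier, not exactly on it
        comb_hz = 1e3 / (truth.spec.syllable_ms[0] + truth.spec.inter_syllable_ms[0])
        assert got == pytest.approx(truth.spec.carrier_hz, abs=comb_hz)

    def test_silent_recording_undefined(self):
        rec = io.AudioRecording(np.zeros(16000), 16000)
        assert songmodel.dominant_frequency(rec) is None


class TestSummarize:
    def test_mean_chirp_duration(self):
        fs = 16000
        events = events_from_gaps([20, 300, 40], dur_ms=30.0, fs=fs)
        chirps = songmodel.group_chirps(events)
        assert [round(c.duration_ms) for c in chirps] == [80, 100]
        summary = songmodel.summarize_recording(None, chirps)
        assert summary.mean_chirp_duration_ms == pytest.approx(90, abs=0.2)

    def test_duration_reconstruction_invariant(self, clean_song):
        rec, _ = clean_song
        chirps = songmodel.group_chirps(detect.detect_syllables(rec))
        for c in chirps:
            total = sum(c.syllable_durations_ms) + sum(c.inter_syllable_intervals_ms)
            assert c.duration_ms == pytest.approx(total, abs=1e-9)

    def test_closed_form_chirp_duration(self):
        # 4 syllables x 18 ms + 3 gaps x 16 ms = 120 ms
        spec = replace(
            synth.preset("LD-like"),
            n_chirps=150,
            seed=5,
            sample_rate=16000,
            syllable_count_probs={4: 1.0},
        )
        rec, truth = synth.synthesize_song(spec)
        chirps = songmodel.group_chirps(detect.detect_syllables(rec))
        summary = songmodel.summarize_recording(rec, chirps)
        assert summary.mean_chirp_duration_ms == pytest.approx(120, abs=2)
        assert summary.mean_inter_syllable_interval_ms == pytest.approx(16, abs=0.5)

    def test_chirp_cap_limits_syllable_level_means(self):
        events = events_from_gaps([10, 300, 30], dur_ms=20.0)
        chirps = songmodel.group_chirps(events)
        capped = songmodel.summarize_recording(None, chirps, chirp_cap=1)
        assert capped.mean_inter_syllable_interval_ms == pytest.approx(10, abs=0.1)
        # chirp-level means still cover the whole recording
        assert capped.n_chirps == 2

    def test_zero_chirps(self):
        summary = songmodel.summarize_recording(None, [])
        assert summary.n_chirps == 0 and summary.n_syllables == 0
        assert summary.mean_chirp_duration_ms is None
        assert summary.syllable_count_proportions == {}

    def test_proportions_sum_to_one(self, clean_song):
        rec, _ = clean_song
        chirps = songmodel.group_chirps(detect.detect_syllables(rec))
        summary = songmodel.summarize_recording(rec, chirps)
        assert sum(summary.syllable_count_proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert summary.n_syllables == sum(
            k * n for k, (n, _) in songmodel.syllable_count_distribution(chirps).items()
        )


class TestInclusionFilter:
    @pytest.mark.parametrize(
        "days,chirps,expected",
        [
            (5, 25000, True),
            (4, 25000, False),  # boundary: exactly 4 days excluded
            (5, 20000, False),  # boundary: exactly 20,000 chirps excluded
            (4.5, 20001, True),
            (10, 19999, False),
            (3, 50000, False),
        ],
    )
    def test_strict_boundaries(self, days, chirps, expected):
        assert songmodel.inclusion_filter(days, chirps) is expected

    def test_random_battery_matches_direct_boolean(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            days = rng.uniform(0, 10)
            chirps = int(rng.integers(0, 40000))
            assert songmodel.inclusion_filter(days, chirps) == (
                days > 4 and chirps > 20000
            )


class TestCsvRoundtrip:
    def test_summary_csv_columns_stable(self, tmp_path, clean_song):
        import pandas as pd

        rec, _ = clean_song
        chirps = songmodel.group_chirps(detect.detect_syllables(rec))
        summary = songmodel.summarize_recording(rec, chirps)
        path = tmp_path / "summary.csv"
        songmodel.write_summary_csv([summary], path)
        df = pd.read_csv(path)
        assert list(df.columns) == songmodel.SUMMARY_COLUMNS
        assert df.loc[0, "n_chirps"] == summary.n_chirps
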