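# Methods

## Signal model and detection procedure

A cricket calling song is modelled as a sparse pulse train: syllables are
tone bursts at a single carrier (~4–5 kHz) separated by near-silent gaps,
grouped into chirps. Detection assumes (i) one animal per recording,
(ii) a noise floor well below syllable amplitude after peak
normalization, and (iii) no implicit resampling — any rate ≥ 8 kHz is
accepted as-is.

**Normalization.** Waveforms are scaled so max|x| = 1; silent input is
passed through unchanged (detection then yields zero events, which is the
correct result, so no error is raised). Detection is therefore invariant
to recording gain by construction.

**Envelope.** The amplitude envelope is the frame-maximum of |x| over
2 ms fragments advancing by 50% of the frame. Frame-maximum (rather than
RMS or Hilbert magnitude) keeps the high threshold interpretable: a frame
value of 0.1 means the waveform actually reached 10% of full scale in
that fragment. A Hilbert-magnitude variant is available behind
`DetectionConfig.envelope_method` for signals with slow carriers.

**Double thresholding.** An event opens at a frame exceeding
`high_threshold` (0.1) and extends over the surrounding contiguous frames
above `low_threshold`; runs that never reach the high threshold are
noise. The low threshold separates song from the inter-syllable noise
floor, and its default matters: for Gaussian noise of RMS σ the
*frame-maximum* over an n-sample fragment concentrates around
σ·√(2 ln 2n) — about 3.2σ for 2 ms at 44.1 kHz — so a low threshold of
2σ would be crossed by essentially every noise frame and hysteresis would
merge neighbouring syllables. The default 0.05 sits at 5σ of a σ = 0.01
noise floor (per-frame exceedance ~5·10⁻⁵) while remaining far below any
real syllable, whose envelope is of order 1 after normalization.

**Boundary refinement.** Frame-resolution boundaries are snapped to zero
amplitude on the raw waveform. Within each candidate, the first and last
samples with |x| > `low_threshold` anchor the true burst; each boundary
then moves outward to the nearest **run of ≥ 3 consecutive near-zero
samples** (|x| ≤ `zero_eps`, default 10⁻⁴ of full scale). Requiring a run
matters: isolated near-zero samples occur at every carrier zero crossing
*inside* a syllable and must not terminate it, whereas genuine silence
produces long runs. On noiseless gated sines this recovers the true gate
boundaries to ±1 sample. When no such run exists within one frame of the
anchor (e.g. a noise floor that never touches zero), the nearest sign
change is used instead (ties widen the event: earlier sample for onsets,
later for offsets), bounding the boundary error by the anchor's offset
from the true edge — a fraction of the 1 ms gate rise time. Boundaries
never cross a neighbouring event, and refinement is idempotent.

**Duration filter.** Events outside 5–60 ms are discarded. The window
brackets syllables of ~15–25 ms while rejecting sub-millisecond clicks
and any accidentally merged pair.

## Gap classification and features

Gaps between consecutive syllables are partitioned by duration:
≤ 40 ms → inter-syllable interval (same chirp); 40 ms–2 s → inter-chirp
interval; > 2 s → pause, which terminates the chirp but is excluded from
interval statistics (a silent animal should not drag interval means).
The 2 s ceiling is far above the ~300–400 ms chirp periods of normal
calling, and 40 ms cleanly separates the ~12–16 ms inter-syllable gaps
from the ~200–300 ms inter-chirp gaps; both are configurable since real
corpora may differ.

Chirp duration is defined by the bracketing syllables, so it is exactly
the sum of member syllable durations and internal gaps. Chirp-level
means are computed over the whole recording; syllable-level means
(syllable duration, inter-syllable interval, overall and per 3-/4-syllable
class) over the first `chirp_cap` chirps (default 3500), so recordings of
different lengths contribute comparable sample sizes. Dominant frequency
is the peak of a Welch averaged periodogram (8192-sample Hann segments,
50% overlap) in 1–10 kHz; for a periodically gated carrier the spectrum
is a comb spaced at the syllable repetition rate (~29 Hz for a 34 ms
syllable period), so the estimate is accurate to a comb line, not to an
FFT bin. The full-corpus inclusion rule for an individual is strict:
more than 4 recording days *and* more than 20,000 chirps.

## Statistical battery

Group comparisons operate on per-recording summaries with recordings
nested in individuals. The **nested t-test** collapses each individual's
recordings to one mean and applies an equal-variance two-sample t on
individual means (df = n₁+n₂−2). For balanced designs this is identical
to the t derived from a two-level nested ANOVA (the test suite keeps the
ANOVA oracle to document the equivalence); for unbalanced data the
individual-means convention is retained and documented rather than
guessing at proprietary weighting schemes. Duplicating recordings within
an individual cannot change the result — that immunity to
pseudoreplication is the test's purpose.

Normality is checked with Shapiro–Wilk at α = 0.05; if rejected, log
(strictly positive data only) then square-root transforms are tried, and
the first that passes is recorded so the *same* transform can be applied
to both groups. The ladder itself is a package convention. The variance
F-test uses the larger-over-smaller convention (order-invariant,
two-sided p capped at 1). The χ² goodness-of-fit accepts non-integer
counts — the statistic is well-defined on non-negative reals, which
allows counts reconstructed from printed percentages — and normalizes
expected proportions, so uniform scaling of them is irrelevant. A zero
expected proportion is an error unless its observed count is also zero.

## Synthetic songs and what they do (not) show

The generator draws syllable counts from a categorical mixture and
timings from truncated normals, renders each syllable as a zero-phase
sine gated by 1 ms raised-cosine edges (so true boundaries sit at zero
amplitude, matching the detector's boundary definition), adds white
noise, and peak-normalizes. Ground truth stores pre-noise gate times
quantized to the sample grid. Defaults: carrier 4900 Hz, syllable
18 ± 1.5 ms, inter-chirp interval 230 ± 20 ms (chirp period ≈ 350 ms),
amplitude jitter 5%, 44.1 kHz. The presets fix what group comparisons
need: `LD-like` has ISI 16 ± 1 ms and mixture {3: 0.24, 4: 0.75,
2: 0.01}; `LL-like` has ISI 11.71 ± 1 ms and {3: 0.47, 4: 0.51,
2: 0.02}. Means are anchored to printed group statistics; the spreads,
carrier and inter-chirp parameters are this package's choices since no
source prints them.

`make_group_dataset` simulates an experiment by adding a per-individual
normal offset (SD `between_individual_sd`) to the ISI mean, then drawing
independent recordings; audio is re-rendered on demand from stored seeds
so large corpora need not sit in memory. For calibration and power
studies that would be wasteful through audio, `sample_recording_isi_means`
draws per-recording mean ISIs directly from the same timing model
(multinomial syllable counts; the ISI sum drawn as the exact distribution
of a sum of normals — truncation at zero is ~16σ away and ignored).

What passing tests show: the detector recovers *this* signal family —
clean carrier, stationary noise floor, non-overlapping events — exactly,
and the statistics are correctly computed and calibrated. What they do
not show: robustness to wind/traffic noise, reverberation, multiple
singers, amplitude fading, or species with different song structure.
Real-recording group differences reported elsewhere cannot be recomputed
here; the presets only encode their direction conventions.

## Problem sizes and numerical choices

The validation suite uses sizes chosen to keep the full run fast while
leaving estimates far more precise than the tolerances tested: detector
closure on 20 songs × 40 chirps (noise RMS 0 and 0.01); the group
experiment at 5 individuals × 5 recordings × 500 chirps per recording at
16 kHz (≈ 2.4 h of audio overall); test power over 50 feature-level
replicates and type-I calibration over 1000. Group-mean ISI recovery is
judged against the simulated corpus's own ground truth (±0.5 ms):
the realized group mean differs from the preset mean by the sampling
error of five individual offsets (SE ≈ 0.45 ms at SD 1 ms), which is a
property of drawing five animals, not of the estimator.

Ties in zero-crossing refinement widen events conservatively. Welch p at
identical groups is exactly 1 by convention when both variances vanish.
16-bit WAV I/O uses the symmetric full-scale convention (divide by 2¹⁵ on
read, multiply and clip on write) so round-trips stay within one
quantization step. All detection is deterministic; all simulation
randomness flows from a single integer seed per spec.

## Known limitations

- Single-channel analysis only; stereo files are downmixed (or one
  channel selected) on load.
- The detector has no adaptive thresholding: recordings whose noise
  floor exceeds ~0.05 of the normalized peak need a custom
  `low_threshold`, and heavily clipped recordings violate the
  zero-boundary assumption.
- The nested t-test assumes approximately normal individual means; with
  2–3 individuals per group it has very few degrees of freedom, which is
  a property of the design, not the implementation.
- `min_inter_chirp_gap_ms` equals `max_intra_chirp_gap_ms` by default,
  i.e. the gap partition has no dead zone; configs that open one are
  rejected.
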