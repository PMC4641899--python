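# Methods

## The measurement model

A melodic cloze trial yields one sung note per participant per stem.
The pipeline treats the sung note as a frequency measurement: the mean
fundamental frequency `f` is mapped to the fractional semitone
`m = 69 + 12·log2(f/440)` and rounded half-up to the nearest integer
index, with the remainder stored as a signed cents deviation
(`1200·log2(f/f_nearest)`).  A frequency exactly halfway between two
semitones rounds to the upper tone — a deterministic tie-break that is
unobservable in practice (the tie set has measure zero in f).  All
downstream cloze statistics generalize across octaves: a response is its
pitch class, and its scale degree within the stem's key (integers 1–7
for diatonic classes; non-diatonic classes carry a `chromatic:<k>` label
and are pooled into a single non-diatonic bin in degree profiles,
since only the 7 diatonic degrees are individually interpretable in a
major-key design).

**Constraint** is the maximum cloze probability of a stem — the share of
valid respondents producing the modal pitch class.  Ties are preserved:
the constraint value is well defined, and every argmax class is
reported; stages needing a single modal note declare their own policy
(the model comparison counts a prediction hitting *any* tied class as
correct by default, configurable to strict).

**Participant screening** applies two rules.  (1) Every pitch-matching
calibration trial must round to the presented note; the comparison is
octave-equivalent by default because singers reproduce tones in a
comfortable register — an octave displacement is a register choice, not
a pitch error (strict index matching is available).  (2) A participant
is excluded when at least 25% (inclusive) of their trials deviate
strictly more than 40 cents from the nearest semitone.  A small epsilon
(1e-9 cents) guards the strict inequality against floating-point
round-trip noise.

**Onset detection** runs on an intensity envelope (default 1 ms
sampling): the onset is the start of the first contiguous run at least
50 ms long whose level stays within 25 dB of the track maximum.  A run
shorter than 50 ms never triggers, however loud.  When no such run
exists the detector returns a not-found marker rather than guessing.

**f0 estimation** from WAV is a pluggable backend; the default takes the
middle 50% of the recording (avoiding onset/offset transients), runs
frame-wise autocorrelation (40 ms frames, 10 ms hop) with unbiased-lag
normalization, picks the *first* autocorrelation peak within 90% of the
band maximum (later period multiples reach comparable height and would
otherwise cause subharmonic errors), refines the lag by parabolic
interpolation, and averages over voiced frames.  On pure tones at
chromatic frequencies it is accurate to within ±5 cents, which is all
the screening rules require; it is not a production pitch tracker for
noisy or breathy voices.

## Key-finding

Stimulus validation uses the Krumhansl–Schmuckler algorithm: the
duration-weighted pitch-class distribution of a stem (total sounded
beats per class; unnormalized, since Pearson correlation is
scale-invariant) is correlated with the 24 rotations of the
Krumhansl–Kessler probe-tone profiles.  The profile constants (major:
6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66, 2.29, 2.88;
minor: 6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75, 3.98, 2.69,
3.34, 3.17) are stored as documented module constants and are the single
source for both key-finding and the expectancy model's tonality factor.
Group validation averages the per-stem correlation with the labeled
correct key on the Fisher-z scale (atanh), reports the back-transformed
mean, and compares AC vs NC groups with a paired t across pairs —
matched stimulus groups should not differ.

## The simplified Implication–Realization model

The model scores every concrete pitch within ±24 semitones of the
stem's final note (49 candidates; candidates are pitches, not classes,
because proximity and reversal are octave-sensitive):

- **Proximity**: `max(0, 24 − |interval|)` — maximal at the unison,
  linearly decreasing.
- **Reversal**: a direction term (+1 if a leap of ≥ 7 semitones is
  followed by a direction change, −1 if it continues, 0 below threshold
  or on a repeated tone) plus a registral-return term (+1.5 if the
  candidate lands within 2 semitones of the penultimate tone), shifted
  by +1 to be nonnegative.
- **Tonality**: the Krumhansl–Kessler rating of the candidate's pitch
  class in the stem's key.

The published simplified formulation is cited rather than reproduced in
full by its sources, so these codings are a reconstruction of its two
melodic factors; every threshold and weight lives in `ModelConfig` so
alternative published codings can be substituted.  The tests pin the
coding's *structure* — monotonicity, symmetry, the leap threshold, the
return window, transposition equivariance — not the disputed constants.
"Weighting evenly by equalizing the maximum values" is implemented
literally: each factor is divided by its maximum over the current
candidate set before the (default equal) weights are applied; a factor
whose maximum is zero contributes nothing.  Argmax ties break toward the
candidate nearest the final note, then the lower pitch (the proximity
principle, made deterministic).

The model comparison restricts to high-constraint stems (constraint
strictly above the AC-condition mean, ≈0.69) — the stems where
listeners demonstrably shared one expectation.  A prediction is correct
when its pitch class matches the behavioral modal class.  Mismatch
distances are measured from the predicted concrete pitch to the modal
class lifted to the nearest octave, which equals distance on the
pitch-class circle (0–6 semitones); published mismatch distances do not
state their octave convention, so the folded measure is the default and
the raw candidate-to-lift distance coincides with it by construction.

## The synthetic-data generator

No stimulus set or response audio is publicly deposited, so every
pipeline stage is exercised on generated material shaped like the study:

- **Corpus**: 45 pairs at 120 bpm across the 12 major keys and the
  3/4, 4/4 and 6/8 meters; stem lengths 5–9 notes drawn to a mean of
  8.38; durations from eighth to half notes, totalling whole bars so the
  continuation falls on a strong beat; pitch range D3–A5.
- **Melody**: a constrained random walk on the diatonic ladder with
  step bias, occasional leaps, leap-reversal tendency, register
  attraction and probe-tone-weighted landing degrees, opening on a
  tonic-triad tone; longer durations are assigned to tonally stabler
  notes (agogic emphasis).  A candidate pair is rejected unless both
  stems' best Krumhansl–Schmuckler match is a major key — the stimuli
  are by construction unambiguously tonal.  No claim of musical quality
  is made; the walk exists to exercise the pipeline.
- **AC/NC matching**: the NC line keeps the AC rhythm and contour;
  each note is resampled near the AC note (proximity² × stability²
  weighting, with probability 0.15 of deliberate reuse), the final note
  avoiding degrees 2 and 7 (degree 5 with probability ≤ 0.1).  This
  yields a corpus-mean differing-note fraction near 0.48 and a mean
  shift near 2 semitones at differing positions.
- **Responses** ("harmonic" source, the default): each stem gets a
  planted modal probability — for AC stems the tonic nearest the final
  note, with the probability drawn per final degree (0.81 ± 0.12 after
  leading-tone endings, 0.56 ± 0.14 after degree 5, 0.58 ± 0.14 after
  degree 2, reflecting the much stronger pull of the leading tone); for
  NC stems a stability-weighted diatonic note near the final note, with
  probability 0.415 ± 0.153.  Planted values for the two members of a
  pair share a latent factor (correlation 0.5): matched stems share
  melodic material, so their predictability co-varies.  Residual mass is
  spread over the 49 candidates by a softmax of the I-R combined score
  (temperature 0.8).  Because AC behavior is tonic-driven while the
  model sees only local structure, the model-vs-behavior comparison on
  synthetic data is a genuine test, not self-confirmation.  Two
  alternative sources exist: `model-softmax` (the model's own softmax,
  temperature bisected per stem so its maximum equals the planted
  constraint) and `explicit` (user-supplied distributions).
- **Cohort**: 50 singers by default (58 with an off-pitch fraction of
  8/58 when exclusions are to be exercised), 24 AC + 21 NC stems each,
  42% singing an octave down; vocal jitter 15 cents SD (60 for
  off-pitch singers, enough to fail both screening rules); reaction
  times 767/1033 ms (AC/NC) with a 150 ms trial SD, a between-singer
  baseline derived from the 265 ms between-participant SD, and a
  190 ms SD participant-specific condition effect; confidence 5.14/4.36
  on the 7-point scale with analogous components (0.93 between, 0.5
  condition effect, 0.8 trial), integer-clipped to 1–7; training years
  9.0 ± 4.8, with trained singers' tonic probability raised by 0.065
  (degree 7) or 0.045 (degree 5) per SD of training.

**What the generator does not emulate**: real melodic phrase structure
(motivic repetition, compound lines, gap-fill patterns — precisely the
larger-scale factors the expectancy model misses), serial-position and
practice effects, per-singer register-dependent intonation, and any
dependence of reaction time on the sung note's identity.  Passing tests
therefore demonstrate that the *pipeline* recovers planted parameters
and reproduces condition-level structure, not that the generator's
melodies behave like composed music in every respect.

One systematic measurement effect is worth knowing: the empirical
constraint of a stem is the *maximum* of multinomial proportions over
~21–25 respondents and therefore overshoots the planted modal
probability by roughly +0.03–0.05, most visibly in the low-constraint
NC condition (planted 0.415, measured ≈0.46).  This is a property of
the constraint statistic at small n — any norming study's reported
constraints carry the same upward bias — and is left uncorrected.

## Numerical choices

- Equal temperament with A4 = 440 Hz throughout (configurable
  reference); printed stimulus frequencies match it to 0.1 Hz.
- Beats are the internal time unit; milliseconds only at the interfaces
  (conversion `ms = beats · 60000 / bpm`, exact inverse).
- Pearson correlations use the plain product-moment formula; paired t
  tests are computed in-module from `t = mean(d)·√n / sd(d)` with
  df = n−1 and two-sided p from the t distribution (scipy supplies the
  CDF; `scipy.stats.ttest_rel` serves as an independent oracle in the
  tests, never as the implementation).
- Correlation averaging is always done on the Fisher-z scale.
- Per-degree AC vs NC tests default to Welch two-sample t across items
  with Bonferroni m = 7 (the test unit is ambiguous in norming designs;
  a paired-by-pair variant is available via `paired=True`).
- Degenerate inputs fail loudly: empty distributions, zero-variance
  correlations, sub-2-note stems for the expectancy model, nonpositive
  frequencies and tempi all raise with the offending identifier.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data: corpora of 4–45 pairs, cohorts of 6–200 singers, and a
100-replicate significance study at the full 45-pair × 50-singer
design — sizes chosen to match the study design where it matters
(pair counts, cohort size) and to keep desk-scale runs in seconds
elsewhere.

## Known limitations

- MIDI support is import-only and minimal: single-track monophonic
  PPQ files with optional tempo/meter/key metadata; no SMPTE division,
  no MusicXML.
- The default f0 backend assumes clean, voiced, roughly periodic input.
- The I-R codings are a documented reconstruction (see above); absolute
  expectancy values should not be compared across codings, only the
  induced rankings.
- Minor keys are representable (and the key-finder searches all 24
  keys), but the scale-degree machinery and generator target the
  all-major stimulus design.
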