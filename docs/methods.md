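# Methods

This note documents the models, conventions, and design choices behind the
toolkit, in the order the pipeline runs: melody generation → synthesis →
masker → mixing and cues → sessions → scoring and psychometrics → simulated
responders.

## Target melodies and foils

Targets are monophonic, 4–7 notes, at 120 beats/min, with total notated
duration constrained to 3–4 s. Two parameters are not fixed by the task
description and are package defaults, both configurable via `MelodyParams`:

* **Pitch range** C4–C6 (MIDI 60–84): a typical melodic register that leaves
  spectral headroom for the masker to extend above and below the target.
* **Duration alphabet** {eighth, quarter, dotted-quarter, half} beats: the
  smallest natural set that fills 3–4 s with 4–7 notes.

Note counts and durations are drawn by rejection sampling against the
duration window; pitches follow a random walk with leaps capped at an octave
(a weak melodicity constraint — real stimuli were composed, ours are
sampled). Generation is rejected until at least two distinct pitches are
present, so every generated target admits a foil.

**Scrambling.** A foil is a permutation of the target's (pitch, duration)
tokens that (a) differs from the original order and (b) neither begins nor
ends on the melody's own minimum or maximum pitch, whenever such a
permutation exists; "extremes" are read as the melody's own pitch extrema.
The identity order is always rejected. Search is rejection sampling over
random permutations (10 000 attempts) with exact enumeration as the
fallback, so degenerate melodies either get a valid foil or a definitive
`UnscramblableMelodyError` (all notes identical). When no endpoint-compliant
permutation exists (e.g., only two distinct pitches) the endpoint rule is
waived, per its own "when possible" qualifier. Rhythm-condition stimuli are
targets flattened to one per-trial pitch before scrambling; generation
retries until the flattened melody has at least two distinct durations.

## Synthesis

A parametric additive synthesizer (harmonic partials with exponential decay,
5 ms attack, 20 ms raised-cosine release per note) stands in for the sampled
electric-grand timbre of the original materials; task logic is
timbre-agnostic and `SynthParams` is fully configurable. Rendered melodies
span the notated duration plus one 20 ms release tail; all duration
bookkeeping (excerpt margins, support windows) uses the rendered span.
Audio is 44.1 kHz throughout. WAV output defaults to 32-bit float — exact
for level verification — with 16-bit PCM as an option.

## Multi-music masker

Four procedurally generated streams of polyphonic music (chordal random
walks, 2–4 simultaneous notes, distinct tempi, registers, and timbres) are
rendered, mixed at equal RMS, and peak-normalized to ±1 to form a 46 s bed.
The staggered registers (lowest stream reaching MIDI 36, highest MIDI 103)
guarantee spectral energy below and above the target register, which the
tests verify as band-energy fractions below 200 Hz and above 2.5 kHz each
exceeding 1% of total energy. The procedural generator replaces the original
masker's published classical scores: what matters for informational masking
is the statistical character (overlapping tonal streams, broad spectrum),
not the identity of the pieces, and a seeded generator keeps the toolkit
self-contained and deterministic. One source ambiguity: the bed length is
described as both 46 s and 47 s in the task's documentation; this package
standardizes on 46 s (configurable).

The original clip was additionally chosen by ear to sound "relatively
uniform"; that selection is operationalized as a bound (max/min ≤ 4) on RMS
over 1 s windows, regenerating from a derived seed on failure (the attempt
count is recorded in the bed metadata).

Per-trial excerpts are `melody + 1 s` long, cut at a uniformly drawn,
seeded offset and tapered with 10 ms raised-cosine ramps
(`gain(t) = 0.5·(1 − cos(πt/ramp))`).

## Mixing and cues

**SNR convention.** 0 dB means equal RMS between target and masker measured
over the target's support window; negative SNRs scale the target down while
the masker stays constant. This makes the level contract exactly verifiable:
`measure_snr` applied to the stored component tracks returns the configured
SNR to float precision. Targets are embedded 0.5 s after noise onset. The
mixture and its two component tracks are all retained (`StereoMix`), with
`mixture = target + masker` holding sample-exactly; when writing WAV files a
joint headroom scale is applied to mixture and components together (recorded
in the manifest), which preserves every ratio.

**Spatial cue.** The attended ear receives the melody at +3 dB and the noise
at −3 dB; the opposite ear is inverted. The melody therefore carries a 6 dB
interaural level difference (and the noise the opposite one); per-ear SNR
shifts by ±6 dB relative to the configured value. The package reports the
spatial cue's ILD as the target's between-ear level difference re-measured
from the component tracks. The silent comparison interval remains diotic.
The attention icon is carried as a manifest field (side), not rendered
graphics.

**Visual cue.** A piano-roll descriptor: one event per target note, with
start/end in seconds on the in-noise interval timeline (0.5 s embed offset
included) and vertical position linear in MIDI pitch within the melody's own
range. It spans only the in-noise interval.

**Trial geometry.** The in-noise interval always embeds the target; on
mismatch trials the in-silence interval carries the foil. Prediction trials
put the silent interval first; all other noise conditions put the in-noise
interval first; control trials present both intervals in silence with no
masker. The inter-stimulus interval is 0.5 s, and response time is
unlimited (no deadline is stored).

## Sessions

A session version holds six 20-trial blocks (five noise conditions +
control) behind 4 familiarization trials per condition at the easiest SNR
(feedback on). Per noise block: 10 match / 10 mismatch and each SNR exactly
5 times. Five trials per SNR cannot split evenly into match/mismatch, so
match counts of 3/2 and 2/3 are counterbalanced across SNR levels (seeded),
keeping both marginals exact. Spatial blocks balance 10 left / 10 right.
Control trials carry no SNR (there is no masker to define one against).

The stimulus pools and masker-bed seed derive from the master seed alone, so
the four versions share materials; the SNR–stimulus pairing, match
assignment, sides, trial order, and block order are re-randomized per
version. Sessions are pure metadata (melodies, seeds, offsets, cue
descriptors); audio is rendered on demand, one trial at a time, and
re-rendering from a manifest is bit-identical because every random draw is
recorded. `validate` re-measures SNR and ILD from the written component
tracks and re-checks hashes and counts.

## Scoring and psychometrics

Correctness is `(response == "match") == is_match`. Missing trials are
reported and excluded from denominators; duplicates and unknown trial ids
are errors. The MINT average is the unweighted mean of the five
noise-condition accuracies. Percentiles come from the published norms table
shipped with the package, with linear interpolation between rows; scores at
or above the top row return the top band, scores below the bottom row clamp
to the bottom band. (The table itself is nearly linear in score and is not
consistent with a Normal(0.78, 0.09) fit at its tails; it is shipped
verbatim as the lookup norm rather than re-derived.)

**Split-half reliability.** Items are randomly partitioned into two equal
halves (balanced 10/10 — the Spearman–Brown step-up assumes equal-length
halves) `n_splits = 1000` times; per-split, half-mean scores are correlated
across subjects (Pearson), correlations are averaged, and `2r̄/(1+r̄)` is
applied to the average. Splits with a zero-variance half are dropped and
counted rather than imputed. The overall coefficient averages accuracy
across conditions per item position first, then applies the same procedure
— one documented reading of an ambiguous order of operations.

**Dependent correlations** use Steiger's (1980) z for overlapping
correlations: Fisher-transformed coefficients with the covariance term
evaluated at the pooled correlation. The comparison is antisymmetric and its
null type-I error is verified by simulation in the tests.

## Simulated responders

A responder is parameterized on the accuracy scale (the task reports
proportion correct throughout; a d′-scale model is a possible extension):

```
p(correct) = clip(base + offset[condition] + slope·SNR, 0.5, 1)·(1 − lapse) + 0.5·lapse
```

with chance fixed at 0.5 for the two-alternative judgement. A cohort draws
per-subject ability from Normal(mean, SD) truncated to [0.5, 1]; with the
default zero slope, ability equals the per-trial probability correct, so
recovery targets are closed-form. Defaults (67 subjects, mean 0.78, SD 0.09)
reproduce the scale of a healthy young-adult cohort. Because observed
averages add binomial noise (≈0.04 SD at 100 items) on top of the ability
distribution, `fit_score_distribution` also reports a debiased ability SD
that subtracts the mean within-subject binomial variance from the observed
score variance.

What the simulator emulates: graded ability, SNR-dependent difficulty,
lapses, condition offsets, and the resulting reliability structure. What it
does not: serial dependence, learning/fatigue, criterion bias between
"match" and "mismatch" responses, and any perceptual interaction with the
actual audio (responses are generated from the manifest, not the
waveforms). Passing simulation tests therefore validates the scoring and
reliability machinery, not human-likeness of the data.

## Problem sizes and tolerances

The test suite measures the SNR contract over a 200-trial sweep (two full
versions × five noise blocks) at a 0.1 dB tolerance; session combinatorics
over all four versions; scramble correctness against exhaustive permutation
enumeration for ≤6-note melodies; the split-half estimator against the
exhaustive 3-partition average on 4-item toys; null and consistent-cohort
reliability limits; Steiger-z type-I error over 300–400 simulated cohorts;
and responder-cohort parameter recovery at n = 67 within 2.5 standard
errors. Monte-Carlo assertions use fixed seeds chosen once; tolerances are
2–3 standard errors of the corresponding estimator.

## Known limitations

* Generated melodies are random-walk stand-ins, not the original composed
  stimulus sets (whose note lists are not published); norms shipped with the
  package were collected with the original stimuli.
* The procedural masker matches the original's function, not its sound; no
  attempt is made to reproduce the original spectra beyond band coverage.
* The visual cue is a structured descriptor for a presentation layer, not a
  rendered video; no presentation engine (timing, keyboard) is included.
* Information-content balancing of stimulus sets across conditions (done
  with an external predictive model for the original stimuli) is out of
  scope.
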