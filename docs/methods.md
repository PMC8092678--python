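# Methods

## Boundary model

The detector assumes that a prosodic phrase (intonation unit) boundary in
spontaneous speech is marked locally by one of two cues, both recoverable
from forced-alignment timings:

* a **discontinuity in speech rate (DSR)**: articulation slows over the
  last word of a phrase (pre-boundary lengthening) and accelerates on the
  first word of the next;
* a **silent pause** longer than a threshold comparable to one word
  (~300 ms).

Speech rate is local and relative: it is measured as the inverse of the
mean phone duration inside a 300 ms window, and DSR thresholds are
fractions of the largest rate increase *within the same turn*, so the
method adapts to fast, slow and monotonous speakers without training.
Two structural assumptions follow from the behaviour of the cue:
boundaries occur only at word onsets, and detection operates within
single-speaker turns (turn transitions are boundaries by definition and
are never scored).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `window_s` | 0.300 s | speech-rate window; ≈ mean word duration. Results are stable over 0.25–0.50 s |
| `dsr_threshold_frac` | 0.88 | first-pass threshold as a fraction of the turn's largest rate increase; trades missed boundaries against false alarms from emphasis-like slowdowns |
| `second_pass_threshold_frac` | 0.70 | re-threshold fraction inside long boundary-free stretches |
| `second_pass_min_duration_s` / `_min_words` | 3.0 s / 10 | a stretch is re-examined only when strictly longer than both |
| `min_pause_s` | 0.300 s | minimal silent gap marking a boundary (strict inequality) |
| `min_turn_words` | 2 | turns below this are passed through unsegmented, mirroring the exclusion of single-unit backchannel turns |

All threshold comparisons are strict (`>`), including the pause rule and
the stretch minima.

### Numerical and interpretive choices

* **Signed differences.** A DSR is a rate *increase* (dᵢ = rᵢ − rᵢ₋₁ > 0):
  boundaries are phrase-initial accelerations, which is where the rate
  peaks relative to the preceding lengthening.  Thresholding |d| instead is
  available as `use_absolute_diffs` for comparison.
* **Rate, not duration.** The thresholded quantity is the inverse mean
  phone duration (1/s).  Thresholding mean duration itself would make
  "difference above threshold" a deceleration criterion; the inverse keeps
  the acceleration reading.
* **Window membership by phone midpoint**, for the window and for
  phone-to-word attachment in TextGrid reading: robust to the 10 ms
  quantisation of aligner output at word edges.
* **Ties at the maximum** all exceed 88% of themselves and are all
  flagged.
* **Undefined rates** (no phone midpoint in the window, e.g. `<unk>`
  words without phone timings): the word is skipped and differences are
  taken between nearest defined neighbours — never silently zero.
* **Turn edges act as virtual boundaries** when delimiting second-pass
  stretches, so long boundary-free prefixes/suffixes are re-examined too.
  The second pass runs exactly once, on the pass-1 segmentation; maxima
  are not recomputed after insertions.
* **Stretch duration** is measured first-word onset to last-word end
  (trailing silence excluded), consistently with phrase ends.

## Evaluation

Boundary slots are the onsets of words 2..n of every multi-word turn; the
slot before a turn's first word is trivially a boundary and is excluded,
which also removes all slots at speaker changes.  Automatic and reference
boundaries are matched one-to-one, greedy nearest-first, within ±50 ms by
default (the coincidence window is not dictated by the data; 50 ms is five
times the aligner resolution, and exact-time agreement is obtained by
setting it to 0).  Cohen's κ is computed from the resulting 2×2 slot
table.  The chi-square statistic is implemented directly (expected counts
from marginals, optional Yates correction for 2×2); `round_expected`
reproduces statistics that were computed from a published table whose
expected counts are printed rounded to integers.  Final vs non-final
recall scores each reference unit by whether the boundary *terminating*
it was detected; units followed by speaker change are not considered.

## Pitch validation

Pitch is never used for detection; it validates it.  Supplied (time, F0)
tracks are median-filtered (5 samples), unvoiced gaps strictly shorter
than 25 ms are linearly interpolated, and the track is smoothed with a
normalized 25 ms Hamming moving average (identity on constants).  Each
phrase's span is linearly rescaled to [0, 1], resampled at 40 equally
spaced points, and divided by its own mean (so every normalized contour
has mean exactly 1; per-speaker normalization is available as an option
via the preprocessing hooks).  Contours with fewer than 4 voiced samples
or more than 50% missing are skipped.  The declination contrast compares
the mean contour over t = 0.15–0.25 against t = 0.85–0.95; variability
compares the across-contour standard deviation over t = 0–0.5 against
t = 0.9–1.0.  Both are one-sided paired t-tests across files.  The peak
location (t ≈ 0.2) is reported but not asserted in tests: it is a
generator/corpus property, not an invariant.

## Lexical/duration validation

Word and phone durations grouped by position from the phrase end
(phrases of 2–20 words), aggregated per file then across files
(mean ± s.e.m.).  Phrase-duration histograms use 0.25 s bins; the
exponential tail is fit by OLS on log-counts of non-empty bins from a
configurable tail start (default 1.0 s) — for an exponential tail the
log-histogram is exactly linear with slope −1/τ, and binning does not
bias the slope.  Word-position frequencies divide the count of a word at
position j by the number of phrases having a position j; error bars come
from splitting files into 3 groups.  `<unk>` tokens stay in the totals
but are excluded from the ranking tables by default.

## The synthetic world

The generator emulates the statistics the detector exploits, at the
values reported for conversational American English: middle words
201 ± 30 ms, final words 356 ± 60 ms, first words 15% shorter than middle
ones, middle phones ≈ 74 ms, final phones ≈ 118 ms, mean phrase length
4.1 words, pauses at 60% of within-turn boundaries (lognormal,
mean 0.6 s), two alternating speakers, 2–5 phrases per turn, pitch
declining 15% per phrase (the middle of the reported 10–20% range) from a
reset peak at normalized time 0.2 on a per-speaker baseline
(120–220 Hz), and a phrase-initial lexicon bias ("and" opening 10% of
phrases).  Defaults: 6 files × 40 turns ≈ 700 phrases.

Design choices where the stated world was open or inconsistent:

* **Word counts per phrase** are 2 + geometric with mean 4.1.  A pure
  exponential-tail law with mean 4.1 would put ~24% of mass on
  single-word phrases, whose only word is a lengthened final word — by
  construction such phrases carry *no* initial-acceleration cue, and no
  clean corpus containing them can make every true boundary
  rate-detectable.  The clean world therefore contains only multi-word
  phrases; the induced phrase-duration tail has τ ≈ 0.5 s, and the
  τ = 0.7 s tail-fit recovery is exercised on durations drawn from an
  exponential directly.
* **Phone counts** derive from the word duration (round(base/74 ms) for
  non-final, round(base/118 ms) for final words, clipped to 1–6), and
  phone durations partition the word.  Drawing phone counts independently
  of word durations cannot honour the stated word *and* phone means
  simultaneously (201/74 ⇒ ~2.7 phones per word).  First-word shortening
  shortens phones rather than removing them — faster articulation, same
  segmental content.
* **Word durations are lognormal** with the stated mean/std (positive
  support); only means ± spread are stated, not shapes.
* **The general lexicon** is a shifted Zipf over ~60 function/content
  words with the top word ("the") at ~6% of tokens, matching
  conversational English; a pure 1/rank law would give it >20% and
  swamp the stated phrase-initial "and" bias.
* **noise_frac** (default 0) multiplies all durations by exp(ε·N(0,1)) on
  top of the stated variation — the knob for degradation studies.

What a green test does *not* establish: the synthetic world has no
disfluencies, overlapping speech, emphasis, isorhythmic stretches,
alignment errors or genre variation, and its boundary cues are present by
construction.  Detector scores here (F ≈ 0.9) bound the method's
mechanics, not its performance on real conversation, which is far lower
(F ≈ 0.66 against manual tagging of ~20 h of recorded conversation).

## Known limitations

* The detector requires phone timings; turns consisting entirely of
  out-of-dictionary words are passed through unsegmented with a warning.
* Single-word units between boundaries are detectable only via pauses —
  inherent to a rate-jump cue measured at word onsets.
* The 88% / 70% / 300 ms constants are corpus-derived heuristics exposed
  as configuration, not re-optimised here.
* No octave-error correction is applied to supplied pitch tracks (the
  original workflow corrects them manually before export).
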