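"""Seeded synthetic-conversation generator with ground-truth boundaries.

The generator emits the stated world the rest of the package is validated
against: turn-structured two-speaker conversations of multi-word phrases
with

* position-dependent word durations — middle words ~201±30 ms, final words
  ~356±60 ms (pre-boundary lengthening), first words 15% shorter than
  middle ones;
* phone durations that partition their word, targeting ~74 ms for
  middle-word phones and ~118 ms for final-word phones;
* phrase word counts of 2 + geometric with overall mean 4.1 words, which
  induces a near-exponential phrase-duration tail (single-word phrases are
  excluded: they consist of one final-type word and therefore carry no
  initial-acceleration cue by construction — the clean corpus contains
  only boundaries that the speech-rate cue can in principle mark);
* optional silent pauses at a configurable fraction of true boundaries;
* per-phrase declining-with-reset pitch (peak near normalized time 0.2,
  decline by ``pitch_decline_frac`` between the begin and end measurement
  windows) on a per-speaker baseline;
* position-biased word labels ("and", "I", "you" ... dominate
  phrase-initial position).

The generator is a pure function of (config, seed): identical inputs give
byte-identical serialised corpora.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import (
    PhoneInterval,
    ReferencePhrase,
    ReferenceSegmentation,
    Turn,
    WordToken,
    write_alignment_tsv,
    write_reference_tsv,
)
from .pitch_analysis import PitchContour, write_pitch_tsv

_PHONE_LABELS = (
    "AA AE AH AO AW AY B CH D DH EH ER EY F G HH IH IY JH K L M N NG OW OY "
    "P R S SH T TH UH UW V W Y Z ZH"
).split()

# phrase-initial lexical bias (probabilities; remainder falls back to the
# general lexicon) — connectors, pronouns, discourse markers
_INITIAL_BIAS = {
    "and": 0.10,
    "i": 0.06,
    "you": 0.05,
    "but": 0.04,
    "the": 0.035,
    "yeah": 0.03,
    "so": 0.03,
    "that": 0.02,
    "well": 0.02,
    "oh": 0.015,
}

_GENERAL_LEXICON = (
    "the i you a to it that of and in know was he they like have don't "
    "she we what this there just not but so then out up all about one "
    "really when time going get them think right people said now some "
    "good see had want because how more here my no yes thing"
).split()


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Stated-world parameters of the synthetic corpus (times in the units
    of the field names; durations are lognormal with the given mean/std)."""

    n_files: int = 6
    turns_per_file: int = 40
    speakers: tuple[str, ...] = ("A", "B")

    words_per_phrase_mean: float = 4.1
    words_per_phrase_min: int = 2
    phrases_per_turn_min: int = 2
    phrases_per_turn_poisson: float = 1.0

    middle_word_ms: float = 201.0
    middle_word_std_ms: float = 30.0
    final_word_ms: float = 356.0
    final_word_std_ms: float = 60.0
    first_word_shortening_frac: float = 0.15
    middle_phone_ms: float = 74.0
    final_phone_ms: float = 118.0
    max_phones_per_word: int = 6

    pause_prob: float = 0.6
    pause_mean_s: float = 0.6
    pause_std_s: float = 0.4
    turn_gap_min_s: float = 0.5
    turn_gap_max_s: float = 1.5

    finality_prob: float = 0.4
    finality_effect: float = 1.0  # extra final-word lengthening for final units

    pitch_base_min_hz: float = 120.0
    pitch_base_max_hz: float = 220.0
    pitch_decline_frac: float = 0.15
    pitch_reset_depth: float = 0.05
    reset_peak_t: float = 0.2
    pitch_sample_s: float = 0.010
    pitch_jitter_frac: float = 0.02

    unk_prob: float = 0.0
    noise_frac: float = 0.0  # extra multiplicative duration jitter (0 = clean)
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "middle_word_ms",
            "final_word_ms",
            "middle_phone_ms",
            "final_phone_ms",
            "pause_mean_s",
            "pitch_sample_s",
        ):
            if getattr(self, name) <= 0:
                raise SynthConfigError(f"{name} must be positive")
        if not (0.0 <= self.pitch_decline_frac < 1.0):
            raise SynthConfigError("pitch_decline_frac must be in [0, 1)")
        decline_at_end = self.pitch_decline_frac * (1.0 - self.reset_peak_t) / (
            0.9 - self.reset_peak_t
        )
        if decline_at_end >= 1.0:
            raise SynthConfigError("pitch declines below zero before phrase end")
        if self.words_per_phrase_mean <= self.words_per_phrase_min:
            raise SynthConfigError(
                "words_per_phrase_mean must exceed words_per_phrase_min"
            )
        if self.middle_phone_ms > self.middle_word_ms or self.final_phone_ms > self.final_word_ms:
            raise SynthConfigError("phone duration target exceeds word duration")
        if self.finality_effect < 1.0:
            raise SynthConfigError("finality_effect must be >= 1")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TrueBoundary:
    file_id: str
    turn_id: str
    speaker: str
    time: float
    word_index: int
    finality: str  # finality of the unit the boundary terminates


@dataclass
class SynthCorpus:
    config: SynthConfig
    turns: list[Turn]
    reference: ReferenceSegmentation
    pitch: dict[tuple[str, str], PitchContour]
    truth: list[TrueBoundary]

    def turns_by_file(self) -> dict[str, list[Turn]]:
        out: dict[str, list[Turn]] = {}
        for t in self.turns:
            out.setdefault(t.file_id, []).append(t)
        return out


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------


def _lognormal(rng: np.random.Generator, mean: float, std: float) -> float:
    """Lognormal draw with the given arithmetic mean and std (positive
    support for durations)."""
    if std <= 0:
        return mean
    var = std * std
    sigma2 = np.log(1.0 + var / (mean * mean))
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _round_t(t: float) -> float:
    return round(t, 4)


class _Lexicon:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        words = list(_GENERAL_LEXICON)
        # shifted Zipf: top word ~6% of tokens, as in conversational English
        zipf = np.array([1.0 / (r + 5) for r in range(1, len(words) + 1)])
        self.general_words = words
        self.general_p = zipf / zipf.sum()
        bias_words = list(_INITIAL_BIAS)
        bias_p = np.array([_INITIAL_BIAS[w] for w in bias_words])
        rest = 1.0 - bias_p.sum()
        self.initial_words = bias_words + words
        self.initial_p = np.concatenate([bias_p, rest * self.general_p])

    def draw(self, position: int) -> str:
        if position == 1:
            i = self.rng.choice(len(self.initial_words), p=self.initial_p)
            return self.initial_words[int(i)]
        i = self.rng.choice(len(self.general_words), p=self.general_p)
        return self.general_words[int(i)]


def _make_word(
    rng: np.random.Generator,
    cfg: SynthConfig,
    start: float,
    role: str,  # first / middle / final
    label: str,
    is_final_unit: bool,
) -> WordToken:
    if role == "final":
        base = _lognormal(rng, cfg.final_word_ms, cfg.final_word_std_ms) / 1000.0
        phone_target = cfg.final_phone_ms / 1000.0
        dur = base * (cfg.finality_effect if is_final_unit else 1.0)
    else:
        base = _lognormal(rng, cfg.middle_word_ms, cfg.middle_word_std_ms) / 1000.0
        phone_target = cfg.middle_phone_ms / 1000.0
        dur = base * (1.0 - cfg.first_word_shortening_frac) if role == "first" else base
    if cfg.noise_frac > 0:
        dur *= float(np.exp(cfg.noise_frac * rng.standard_normal()))
    # phone count from the *base* duration so the canonical phone duration
    # scales with first-word shortening / finality lengthening (faster
    # speech = shorter phones, not fewer)
    n_phones = int(np.clip(round(base / phone_target), 1, cfg.max_phones_per_word))

    if cfg.unk_prob > 0 and rng.random() < cfg.unk_prob:
        return WordToken("<unk>", _round_t(start), _round_t(start + dur), ())

    weights = rng.uniform(0.9, 1.1, size=n_phones)
    pdurs = dur * weights / weights.sum()
    bounds = [_round_t(start + x) for x in np.concatenate([[0.0], np.cumsum(pdurs)])]
    phones = tuple(
        PhoneInterval(str(rng.choice(_PHONE_LABELS)), a, b)
        for a, b in zip(bounds[:-1], bounds[1:])
    )
    return WordToken(label, bounds[0], bounds[-1], phones)


# ---------------------------------------------------------------------------
# corpus generation
# ---------------------------------------------------------------------------


def generate_corpus(config: SynthConfig = SynthConfig()) -> SynthCorpus:
    """Generate a full synthetic conversation corpus (see module docstring).

    Returns in-memory :class:`Turn`/:class:`ReferenceSegmentation`/pitch
    structures plus the ground-truth boundary list; :func:`write_corpus`
    serialises them to the package's TSV/JSON formats.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    lex = _Lexicon(rng)

    turns: list[Turn] = []
    ref_phrases: list[ReferencePhrase] = []
    truth: list[TrueBoundary] = []
    pitch: dict[tuple[str, str], PitchContour] = {}

    extra_mean = cfg.words_per_phrase_mean - cfg.words_per_phrase_min
    p_geom = 1.0 / (1.0 + extra_mean)

    for fi in range(cfg.n_files):
        file_id = f"f{fi:02d}"
        baselines = {
            spk: rng.uniform(cfg.pitch_base_min_hz, cfg.pitch_base_max_hz)
            for spk in cfg.speakers
        }
        pitch_samples: dict[str, list[tuple[float, float]]] = {
            spk: [] for spk in cfg.speakers
        }
        cursor = float(rng.uniform(cfg.turn_gap_min_s, cfg.turn_gap_max_s))
        for ti in range(cfg.turns_per_file):
            speaker = cfg.speakers[ti % len(cfg.speakers)]
            turn_id = f"{file_id}_t{ti:03d}"
            n_phrases = cfg.phrases_per_turn_min + int(
                rng.poisson(cfg.phrases_per_turn_poisson)
            )
            words: list[WordToken] = []
            phrase_spans: list[tuple[int, int, str]] = []  # (first_wi, n, finality)
            for pj in range(n_phrases):
                n_words = cfg.words_per_phrase_min + int(rng.geometric(p_geom) - 1)
                is_last_phrase = pj == n_phrases - 1
                finality = (
                    "final"
                    if is_last_phrase or rng.random() < cfg.finality_prob
                    else "non-final"
                )
                first_wi = len(words)
                if pj > 0:
                    # true boundary before this phrase; optional pause
                    if rng.random() < cfg.pause_prob:
                        cursor += max(
                            _lognormal(rng, cfg.pause_mean_s, cfg.pause_std_s), 0.01
                        )
                for wj in range(n_words):
                    role = (
                        "final"
                        if wj == n_words - 1
                        else ("first" if wj == 0 else "middle")
                    )
                    label = lex.draw(wj + 1)
                    w = _make_word(
                        rng, cfg, cursor, role, label, finality == "final"
                    )
                    words.append(w)
                    cursor = w.end
                phrase_spans.append((first_wi, n_words, finality))

            turn = Turn(turn_id, speaker, tuple(words), file_id=file_id)
            turns.append(turn)

            for k, (first_wi, n_words, finality) in enumerate(phrase_spans):
                pstart = words[first_wi].start
                pend = words[first_wi + n_words - 1].end
                ref_phrases.append(
                    ReferencePhrase(
                        file_id,
                        speaker,
                        pstart,
                        pend,
                        finality,
                        tuple(w.label for w in words[first_wi : first_wi + n_words]),
                    )
                )
                if k > 0:
                    truth.append(
                        TrueBoundary(
                            file_id,
                            turn_id,
                            speaker,
                            pstart,
                            first_wi,
                            phrase_spans[k - 1][2],
                        )
                    )
                _sample_phrase_pitch(
                    rng, cfg, baselines[speaker], pstart, pend, pitch_samples[speaker]
                )

            cursor += float(rng.uniform(cfg.turn_gap_min_s, cfg.turn_gap_max_s))

        for spk, samples in pitch_samples.items():
            if samples:
                times = np.array([s[0] for s in samples])
                f0 = np.array([s[1] for s in samples])
                order = np.argsort(times, kind="stable")
                times, f0 = times[order], f0[order]
                keep = np.concatenate([[True], np.diff(times) > 1e-9])
                pitch[(file_id, spk)] = PitchContour(
                    times[keep], f0[keep], speaker=spk, file_id=file_id
                )

    return SynthCorpus(cfg, turns, ReferenceSegmentation(ref_phrases), pitch, truth)


def _phrase_pitch_shape(cfg: SynthConfig, u: np.ndarray) -> np.ndarray:
    """Normalized declination-with-reset template: rise to the peak at
    ``reset_peak_t``, then linear decline calibrated so that the mean over
    the end window (centered at t = 0.9) is ``1 - pitch_decline_frac``
    times the peak."""
    p = cfg.reset_peak_t
    rise = 1.0 - cfg.pitch_reset_depth * (1.0 - u / p)
    decline = 1.0 - cfg.pitch_decline_frac * (u - p) / (0.9 - p)
    return np.where(u < p, rise, decline)


def _sample_phrase_pitch(
    rng: np.random.Generator,
    cfg: SynthConfig,
    baseline_hz: float,
    start: float,
    end: float,
    out: list[tuple[float, float]],
) -> None:
    times = np.arange(start, end, cfg.pitch_sample_s)
    if len(times) < 2:
        return
    u = (times - start) / (end - start)
    f0 = baseline_hz * _phrase_pitch_shape(cfg, u)
    if cfg.pitch_jitter_frac > 0:
        f0 = f0 * np.exp(cfg.pitch_jitter_frac * rng.standard_normal(len(f0)))
    out.extend(zip(times.tolist(), f0.tolist()))


# ---------------------------------------------------------------------------
# serialisation & helpers
# ---------------------------------------------------------------------------


def write_corpus(corpus: SynthCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write alignment.tsv, reference.tsv, pitch.tsv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "alignment.tsv",
        "reference": out / "reference.tsv",
        "pitch": out / "pitch.tsv",
        "truth": out / "truth.json",
    }
    write_alignment_tsv(paths["alignment"], corpus.turns)
    write_reference_tsv(paths["reference"], corpus.reference)
    write_pitch_tsv(paths["pitch"], corpus.pitch)
    paths["truth"].write_text(
        json.dumps(
            [
                {
                    "file_id": b.file_id,
                    "turn_id": b.turn_id,
                    "speaker": b.speaker,
                    "time": round(b.time, 4),
                    "word_index": b.word_index,
                    "finality": b.finality,
                }
                for b in corpus.truth
            ],
            indent=1,
        ),
        encoding="utf-8",
    )
    return paths


def true_phrases(corpus: SynthCorpus) -> list[tuple[str, "Phrase"]]:
    """Ground-truth phrases as detector ``Phrase`` objects, keyed by file —
    the reference segmentation materialised over the generated word tokens."""
    from .detector import Phrase

    by_stream: dict[tuple[str, str], list[Turn]] = {}
    for t in corpus.turns:
        by_stream.setdefault((t.file_id, t.speaker), []).append(t)
    out: list[tuple[str, Phrase]] = []
    eps = 1e-6
    for ph in corpus.reference.phrases:
        for t in by_stream[(ph.file_id, ph.speaker)]:
            if t.start - eps <= ph.start and ph.end <= t.end + eps:
                words = tuple(
                    w
                    for w in t.words
                    if ph.start - eps <= w.start and w.end <= ph.end + eps
                )
                if words:
                    out.append((ph.file_id, Phrase(words)))
                break
    return out


def random_segmentation_spans(
    turns: list[Turn],
    mean_duration_s: float = 1.0,
    seed: int = 0,
) -> list[tuple[str, str, float, float]]:
    """Negative-control segmentation: cut every turn into spans of roughly
    ``mean_duration_s`` at positions unrelated to the true boundaries."""
    rng = np.random.default_rng(seed)
    spans = []
    for turn in turns:
        t = turn.start + float(rng.uniform(0.0, 0.3))
        while t < turn.end - 0.2:
            dur = float(np.clip(rng.normal(mean_duration_s, 0.25 * mean_duration_s), 0.3, None))
            spans.append((turn.file_id, turn.speaker, t, min(t + dur, turn.end)))
            t += dur
    return spans
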