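"""Training-free prosodic boundary detection from forced-alignment timings.

A phrase boundary in spontaneous speech is marked by a *discontinuity in
speech rate* (DSR): articulation slows on a phrase's last word (pre-boundary
lengthening) and accelerates on the next phrase's first word.  A local speech
rate is therefore measured at the onset of every word as the multiplicative
inverse of the mean phone duration inside a fixed window (default 300 ms,
about one average word), and boundaries are placed where the word-to-word
*increase* in this rate is large relative to the largest increase within the
same turn.  Silent pauses longer than a threshold (default 300 ms) mark
boundaries independently.  Two structural assumptions follow from the data:
a boundary can only occur at a word onset, and the detector operates within
single-speaker turns.

Detection pipeline per turn (see :func:`detect`):

1. :func:`compute_speech_rate` — rate at every word onset;
2. :func:`detect_dsr_pass1` — threshold rate increases at ``88%`` of the
   turn's largest increase;
3. :func:`detect_dsr_pass2` — one re-thresholding pass at ``70%`` inside
   long (> 3 s, > 10 words) boundary-free stretches;
4. :func:`detect_pause_boundaries` — inter-word gaps > 300 ms;
5. :func:`merge_boundaries` — union, DSR wins over pause at the same word;
6. :func:`segment_turn` — phrases between consecutive boundaries, each
   ending at its last word's end (trailing silence excluded).

Thresholds use strict inequalities throughout ("higher than", "longer
than", "more than").  No model is trained and no pitch is used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import Turn, WordToken

logger = logging.getLogger(__name__)

#: Boundary source labels, in priority order (highest first) for merging.
SOURCE_PRIORITY = ("dsr_pass1", "dsr_pass2", "pause")


class DetectorError(ValueError):
    """Detection cannot run on the given input."""


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the boundary detector.

    window_s:
        Speech-rate window duration W (s).  300 ms approximates the mean
        word duration; values in 250-500 ms behave similarly.
    dsr_threshold_frac:
        First-pass threshold θ1: a rate increase is a DSR when it exceeds
        θ1 × (largest increase in the turn).
    second_pass_threshold_frac:
        Second-pass threshold θ2 applied within long boundary-free
        stretches.
    second_pass_min_duration_s / second_pass_min_words:
        A stretch is re-examined only if strictly longer than 3 s *and*
        containing strictly more than 10 words.
    min_pause_s:
        Minimal silent-pause duration Δmin; gaps strictly longer mark a
        boundary.
    use_pauses:
        Disable to detect with speech rate only.
    min_turn_words:
        Turns with fewer words are returned unsegmented and flagged
        excluded (stand-in for the corpus' exclusion of single-unit
        turns such as "oh yeah" / "u-huh").
    use_absolute_diffs:
        Alternative reading in which thresholds apply to |Δrate| rather
        than to signed increases (off by default: a boundary is
        phrase-initial acceleration).
    """

    window_s: float = 0.300
    dsr_threshold_frac: float = 0.88
    second_pass_threshold_frac: float = 0.70
    second_pass_min_duration_s: float = 3.0
    second_pass_min_words: int = 10
    min_pause_s: float = 0.300
    use_pauses: bool = True
    min_turn_words: int = 2
    use_absolute_diffs: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.second_pass_threshold_frac <= self.dsr_threshold_frac <= 1.0):
            raise ValueError(
                "need 0 < second_pass_threshold_frac <= dsr_threshold_frac <= 1"
            )
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.min_pause_s < 0:
            raise ValueError("min_pause_s must be non-negative")

    def replace(self, **kwargs) -> "DetectorConfig":
        return replace(self, **kwargs)


@dataclass
class SpeechRateSeries:
    """Per-word-onset speech rate within one turn.

    ``rate[i]`` is 1 / (mean phone duration in the window starting at word
    ``i``'s onset), in 1/s; NaN where no phone midpoint falls in the window
    (``defined[i]`` is then False — undefined, never silently zero).
    ``diffs[j]`` is the rate change between consecutive *defined* words,
    attributed to the later word ``diff_word_index[j]``.
    """

    word_onsets: np.ndarray
    rate: np.ndarray
    n_phones_in_window: np.ndarray
    diff_word_index: np.ndarray
    diffs: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rate)


@dataclass(frozen=True)
class Boundary:
    """A detected boundary: always at a word onset of its turn."""

    time: float
    word_index: int
    source: str
    turn_id: str = ""

    def __post_init__(self) -> None:
        if self.source not in SOURCE_PRIORITY:
            raise ValueError(f"unknown boundary source {self.source!r}")


@dataclass(frozen=True)
class Phrase:
    """A contiguous word span between consecutive boundaries; ends at its
    last word's end so trailing silence is excluded."""

    words: tuple[WordToken, ...]
    first_word_index: int = 0

    @property
    def start(self) -> float:
        return self.words[0].start

    @property
    def end(self) -> float:
        return self.words[-1].end

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def duration_s(self) -> float:
        return self.end - self.start


@dataclass
class TurnDetection:
    """Per-turn result of :func:`detect`."""

    turn: Turn
    boundaries: list[Boundary]
    phrases: list[Phrase]
    excluded: bool = False
    series: SpeechRateSeries | None = None
    warning: str | None = None


# ---------------------------------------------------------------------------
# speech rate
# ---------------------------------------------------------------------------


def compute_speech_rate(turn: Turn, config: DetectorConfig = DetectorConfig()) -> SpeechRateSeries:
    """Speech rate at every word onset of ``turn``.

    For word ``i`` with onset ``t0`` the window is ``[t0, t0 + W)``; every
    phone of the turn whose midpoint lies in the window contributes its full
    duration.  Silence contributes nothing (only phones are counted), and a
    word whose window contains no phone midpoint gets NaN.
    """
    if not any(w.has_phone_timings for w in turn.words):
        raise DetectorError(
            f"turn {turn.turn_id!r}: no phone timings at all; speech rate "
            "is undefined"
        )
    phones = [(ph.midpoint, ph.duration) for w in turn.words for ph in w.phones]
    mids = np.array([m for m, _ in phones])
    durs = np.array([d for _, d in phones])

    onsets = np.array([w.start for w in turn.words])
    n = len(onsets)
    rate = np.full(n, np.nan)
    n_in = np.zeros(n, dtype=int)
    for i, t0 in enumerate(onsets):
        sel = (mids >= t0) & (mids < t0 + config.window_s)
        n_in[i] = int(sel.sum())
        if n_in[i] > 0:
            rate[i] = 1.0 / float(durs[sel].mean())

    def_idx = np.flatnonzero(~np.isnan(rate))
    if len(def_idx) >= 2:
        diff_word_index = def_idx[1:]
        diffs = rate[def_idx[1:]] - rate[def_idx[:-1]]
    else:
        diff_word_index = np.array([], dtype=int)
        diffs = np.array([])
    return SpeechRateSeries(onsets, rate, n_in, diff_word_index, diffs)


# ---------------------------------------------------------------------------
# DSR passes
# ---------------------------------------------------------------------------


def _candidate_diffs(series: SpeechRateSeries, config: DetectorConfig) -> np.ndarray:
    return np.abs(series.diffs) if config.use_absolute_diffs else series.diffs


def detect_dsr_pass1(
    series: SpeechRateSeries,
    config: DetectorConfig = DetectorConfig(),
    turn: Turn | None = None,
) -> list[Boundary]:
    """First-pass DSRs: rate increases strictly above θ1 × (largest increase
    in the turn).  If the turn has no positive increase, no DSR is emitted
    (the turn's first word is always an implicit phrase start and is never
    an explicit boundary).  All indices tying at the maximum are flagged,
    since d_max > θ1·d_max for any positive d_max and θ1 < 1.
    """
    d = _candidate_diffs(series, config)
    pos = d[d > 0]
    if len(pos) == 0:
        return []
    theta = config.dsr_threshold_frac * float(pos.max())
    out = []
    turn_id = turn.turn_id if turn is not None else ""
    for wi, di in zip(series.diff_word_index, d):
        if di > theta:
            out.append(
                Boundary(float(series.word_onsets[wi]), int(wi), "dsr_pass1", turn_id)
            )
    return out


def detect_dsr_pass2(
    turn: Turn,
    series: SpeechRateSeries,
    pass1_boundaries: Sequence[Boundary],
    config: DetectorConfig = DetectorConfig(),
) -> list[Boundary]:
    """Second (and only) re-thresholding pass.

    The turn is cut into stretches by the pass-1 boundaries, with the turn
    edges acting as virtual boundaries.  Every stretch strictly longer than
    3 s (first word onset to last word end) *and* containing strictly more
    than 10 words is re-examined: its rate increases are thresholded at
    θ2 × (largest increase within the stretch).  Pass-1 boundaries are never
    duplicated and there is no recursion.
    """
    n = turn.n_words
    cut_idx = sorted({b.word_index for b in pass1_boundaries})
    edges = [0] + cut_idx + [n]
    d = _candidate_diffs(series, config)
    # previous *defined* word of each diff, to keep diffs that straddle a
    # stretch edge out of both neighbouring stretches
    def_words = np.flatnonzero(series.defined)
    prev_map = {int(w): int(p) for p, w in zip(def_words[:-1], def_words[1:])}
    out: list[Boundary] = []
    for a, b in zip(edges, edges[1:]):
        if b <= a:
            continue
        n_words = b - a
        duration = turn.words[b - 1].end - turn.words[a].start
        if not (duration > config.second_pass_min_duration_s and n_words > config.second_pass_min_words):
            continue
        sel = []
        for j, wi in enumerate(series.diff_word_index):
            wi = int(wi)
            if a < wi < b and prev_map.get(wi, -1) >= a:
                sel.append(j)
        if not sel:
            continue
        dd = d[sel]
        pos = dd[dd > 0]
        if len(pos) == 0:
            continue
        theta = config.second_pass_threshold_frac * float(pos.max())
        for j, di in zip(sel, dd):
            wi = int(series.diff_word_index[j])
            if di > theta and wi not in cut_idx:
                out.append(
                    Boundary(float(series.word_onsets[wi]), wi, "dsr_pass2", turn.turn_id)
                )
    return out


# ---------------------------------------------------------------------------
# pauses, merging, segmentation
# ---------------------------------------------------------------------------


def detect_pause_boundaries(
    turn: Turn, config: DetectorConfig = DetectorConfig()
) -> list[Boundary]:
    """A silent pause is an inter-word gap strictly longer than Δmin; it
    marks a boundary at the onset of the following word."""
    if not config.use_pauses:
        return []
    out = []
    for i in range(1, turn.n_words):
        gap = turn.words[i].start - turn.words[i - 1].end
        if gap > config.min_pause_s:
            out.append(Boundary(turn.words[i].start, i, "pause", turn.turn_id))
    return out


def merge_boundaries(
    dsr: Iterable[Boundary], pause: Iterable[Boundary]
) -> list[Boundary]:
    """Union by word index; where a word is flagged by both a DSR and a
    pause, the boundary is attributed to speech rate."""
    rank = {src: i for i, src in enumerate(SOURCE_PRIORITY)}
    best: dict[int, Boundary] = {}
    for b in list(dsr) + list(pause):
        cur = best.get(b.word_index)
        if cur is None or rank[b.source] < rank[cur.source]:
            best[b.word_index] = b
    return sorted(best.values(), key=lambda b: (b.time, b.word_index))


def segment_turn(turn: Turn, boundaries: Sequence[Boundary]) -> list[Phrase]:
    """Phrases between consecutive boundaries; they partition the turn's
    words, each phrase ending at its last word's end."""
    onsets = {w.start for w in turn.words}
    for b in boundaries:
        if b.word_index <= 0 or b.word_index >= turn.n_words:
            raise DetectorError(
                f"turn {turn.turn_id!r}: boundary word_index {b.word_index} "
                "outside (0, n_words)"
            )
        if b.time not in onsets and not math.isclose(
            b.time, turn.words[b.word_index].start, abs_tol=1e-9
        ):
            raise DetectorError(
                f"turn {turn.turn_id!r}: boundary at {b.time} is not a word onset"
            )
    edges = [0] + sorted({b.word_index for b in boundaries}) + [turn.n_words]
    return [
        Phrase(tuple(turn.words[a:b]), first_word_index=a)
        for a, b in zip(edges, edges[1:])
        if b > a
    ]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def detect_turn(turn: Turn, config: DetectorConfig = DetectorConfig()) -> TurnDetection:
    """Run the full pipeline on one turn."""
    if turn.n_words < config.min_turn_words:
        return TurnDetection(turn, [], [Phrase(turn.words)], excluded=True)
    try:
        series = compute_speech_rate(turn, config)
    except DetectorError as exc:
        return TurnDetection(
            turn, [], [Phrase(turn.words)], excluded=True, warning=str(exc)
        )
    p1 = detect_dsr_pass1(series, config, turn)
    p2 = detect_dsr_pass2(turn, series, p1, config)
    pauses = detect_pause_boundaries(turn, config)
    boundaries = merge_boundaries(p1 + p2, pauses)
    phrases = segment_turn(turn, boundaries)
    return TurnDetection(turn, boundaries, phrases, series=series)


def detect(
    turns: Iterable[Turn], config: DetectorConfig = DetectorConfig()
) -> dict[str, TurnDetection]:
    """Detect boundaries in every turn; per-turn failures become warnings
    (the turn is passed through unsegmented and flagged), detection
    continues over the remaining turns.  Deterministic given input and
    config."""
    results: dict[str, TurnDetection] = {}
    n_warn = 0
    for turn in turns:
        key = f"{turn.file_id}/{turn.turn_id}"
        res = detect_turn(turn, config)
        if res.warning:
            n_warn += 1
            logger.warning("%s: %s", key, res.warning)
        results[key] = res
    if n_warn:
        logger.info("detection finished with %d turn warning(s)", n_warn)
    return results


def all_phrases(results: dict[str, TurnDetection], include_excluded: bool = True) -> list[Phrase]:
    """Flatten detection results into a phrase list (excluded turns'
    single phrases included by default, mirroring their role as single-unit
    turns)."""
    out: list[Phrase] = []
    for res in results.values():
        if res.excluded and not include_excluded:
            continue
        out.extend(res.phrases)
    return out
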