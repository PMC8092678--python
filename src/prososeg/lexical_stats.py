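"""Positional duration and word-frequency statistics of detected phrases.

These are the textual/timing validation channels for a segmentation: if
phrase boundaries are placed correctly,

* word (and phone) durations grouped by position from the phrase end show
  pre-boundary lengthening — the last word roughly 1.8x longer than words
  in the middle of a phrase;
* phrase durations show an exponential tail (time constant ~0.7 s in
  conversational English);
* the first phrase positions are dominated by a small set of connectors and
  pronouns ("and", "I", "you" ...), a known syntactic signature of
  conversational speech.

Statistics are computed per audio file (or per file group) and aggregated
as mean ± s.e.m. across files, mirroring how corpus studies treat files as
independent measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detector import Phrase, TurnDetection

logger = logging.getLogger(__name__)


class LexicalStatsError(ValueError):
    pass


def _phrases_by_file(
    results: Mapping[str, TurnDetection] | Sequence[tuple[str, Phrase]],
) -> list[tuple[str, Phrase]]:
    if isinstance(results, Mapping):
        return [
            (res.turn.file_id, ph)
            for res in results.values()
            for ph in res.phrases
        ]
    return list(results)


# ---------------------------------------------------------------------------
# durations by position
# ---------------------------------------------------------------------------


@dataclass
class PositionalDurations:
    """Mean ± s.e.m. durations by position from the phrase end (position 1 =
    last word), plus first/middle/last summaries.  Durations in seconds."""

    word_table: pd.DataFrame  # index: position from last; columns: mean, sem, n_files
    phone_table: pd.DataFrame
    summary: pd.DataFrame  # index: first/middle/last × word/phone


def duration_by_position(
    results: Mapping[str, TurnDetection] | Sequence[tuple[str, Phrase]],
    min_words: int = 2,
    max_words: int = 20,
    n_positions: int = 10,
) -> PositionalDurations:
    """Word and phone durations grouped by position from the last word.

    Only phrases with ``min_words``-``max_words`` words enter; per-position
    means are computed per file and aggregated across files (mean ± s.e.m.).
    Positions beyond a phrase's length are simply absent for that phrase.
    "Middle" words are those neither first nor last in their phrase.
    """
    items = [
        (fid, ph)
        for fid, ph in _phrases_by_file(results)
        if min_words <= ph.n_words <= max_words
    ]
    if not items:
        raise LexicalStatsError("no phrases in the selected length range")

    word_rows = []  # (file, pos_from_last, duration)
    phone_rows = []
    role_word_rows = []  # (file, role, duration)
    role_phone_rows = []
    for fid, ph in items:
        n = ph.n_words
        for k, w in enumerate(ph.words):
            pos_last = n - k  # 1 = last word
            word_rows.append((fid, pos_last, w.duration))
            role = "first" if k == 0 else ("last" if k == n - 1 else "middle")
            role_word_rows.append((fid, role, w.duration))
            for phn in w.phones:
                phone_rows.append((fid, pos_last, phn.duration))
                role_phone_rows.append((fid, role, phn.duration))

    def agg(rows: list, key: str) -> pd.DataFrame:
        df = pd.DataFrame(rows, columns=["file_id", key, "duration"])
        per_file = df.groupby(["file_id", key])["duration"].mean().reset_index()
        out = per_file.groupby(key)["duration"].agg(
            mean="mean", sem=lambda x: x.sem() if len(x) > 1 else 0.0, n_files="count"
        )
        return out

    word_table = agg(word_rows, "position").loc[lambda d: d.index <= n_positions]
    phone_table = agg(phone_rows, "position").loc[lambda d: d.index <= n_positions]
    summary_w = agg(role_word_rows, "role")
    summary_p = agg(role_phone_rows, "role")
    summary = pd.concat({"word": summary_w, "phone": summary_p}, names=["unit"])
    return PositionalDurations(word_table, phone_table, summary)


# ---------------------------------------------------------------------------
# length/duration distributions and exponential tail
# ---------------------------------------------------------------------------


@dataclass
class TailFit:
    tau_s: float
    r_squared: float
    n_bins: int
    intercept: float


@dataclass
class PhraseDistributions:
    word_count_hist: pd.Series  # index n_words -> count
    duration_hist: pd.Series  # index bin center (s) -> count
    mean_words: float
    mean_duration_s: float
    tail_fit: TailFit | None
    bin_s: float
    tail_start_s: float


def fit_exponential_tail(
    durations: np.ndarray, bin_s: float = 0.25, tail_start_s: float = 1.0
) -> TailFit | None:
    """OLS fit of log bin counts vs bin center over the tail of a duration
    histogram; for an exponential tail exp(-t/τ) the slope is -1/τ.

    Returns None (flagged in the log) when the tail has fewer than three
    non-empty bins or is degenerate (all mass in one bin).
    """
    durations = np.asarray(durations, dtype=float)
    edges = np.arange(0.0, durations.max() + bin_s, bin_s)
    counts, edges = np.histogram(durations, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sel = (centers >= tail_start_s) & (counts > 0)
    if sel.sum() < 3:
        logger.warning("tail fit skipped: fewer than 3 non-empty tail bins")
        return None
    x = centers[sel]
    y = np.log(counts[sel].astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        logger.warning("tail fit rejected: non-decaying tail (slope %.3f)", slope)
        return None
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return TailFit(tau_s=-1.0 / slope, r_squared=r2, n_bins=int(sel.sum()), intercept=float(intercept))


def phrase_length_duration_distributions(
    results: Mapping[str, TurnDetection] | Sequence[tuple[str, Phrase]],
    bin_s: float = 0.25,
    tail_start_s: float = 1.0,
    min_phrases_for_fit: int = 100,
) -> PhraseDistributions:
    """Histograms of phrase word counts and durations plus the exponential
    fit to the duration tail (skipped below ``min_phrases_for_fit``)."""
    items = _phrases_by_file(results)
    if not items:
        raise LexicalStatsError("no phrases")
    n_words = np.array([ph.n_words for _, ph in items])
    durs = np.array([ph.duration_s for _, ph in items])

    wc = pd.Series(n_words).value_counts().sort_index()
    edges = np.arange(0.0, durs.max() + bin_s, bin_s)
    counts, edges = np.histogram(durs, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dh = pd.Series(counts, index=np.round(centers, 6))

    fit = None
    if len(durs) >= min_phrases_for_fit:
        fit = fit_exponential_tail(durs, bin_s=bin_s, tail_start_s=tail_start_s)
    else:
        logger.warning(
            "tail fit skipped: %d phrases < %d", len(durs), min_phrases_for_fit
        )
    return PhraseDistributions(
        wc, dh, float(n_words.mean()), float(durs.mean()), fit, bin_s, tail_start_s
    )


# ---------------------------------------------------------------------------
# positional word frequencies
# ---------------------------------------------------------------------------


@dataclass
class PositionTable:
    """Per-position word probabilities with across-group s.e.m.

    ``probabilities[pos]`` maps word -> overall probability (count at that
    position / number of phrases having that position); ``ranked[pos]`` is
    the ordered list of (word, prob, sem).
    """

    probabilities: dict[int, dict[str, float]]
    ranked: dict[int, list[tuple[str, float, float]]]
    totals: dict[int, int]
    n_groups: int

    def top(self, pos: int, m: int = 10) -> list[str]:
        return [w for w, _, _ in self.ranked[pos][:m]]

    def to_frame(self, m: int = 10) -> pd.DataFrame:
        rows = []
        for pos, ranked in sorted(self.ranked.items()):
            for rank, (w, p, sem) in enumerate(ranked[:m], start=1):
                rows.append((pos, rank, w, p, sem))
        return pd.DataFrame(
            rows, columns=["position", "rank", "word", "probability", "sem"]
        )


def word_position_frequencies(
    results: Mapping[str, TurnDetection] | Sequence[tuple[str, Phrase]],
    k_positions: int = 4,
    n_groups: int = 3,
    min_phrase_words: int = 1,
    include_unk: bool = False,
) -> PositionTable:
    """Word frequency by phrase position (1 = phrase-initial).

    The probability of a word at position j divides its count at j by the
    number of phrases that have a position j.  Error bars come from
    splitting files into ``n_groups`` groups of comparable size and
    recomputing per group.  ``min_phrase_words`` restricts to longer
    phrases (to check that initial-position effects are not driven by
    short units); ``<unk>`` tokens are excluded from the tables but kept
    in the totals unless ``include_unk``.
    """
    items = [
        (fid, ph)
        for fid, ph in _phrases_by_file(results)
        if ph.n_words >= min_phrase_words
    ]
    if not items:
        raise LexicalStatsError("no phrases")

    files = sorted({fid for fid, _ in items})
    group_of = {fid: i % max(n_groups, 1) for i, fid in enumerate(files)}

    counts: dict[int, dict[str, int]] = {p: {} for p in range(1, k_positions + 1)}
    totals: dict[int, int] = {p: 0 for p in range(1, k_positions + 1)}
    gcounts: dict[int, dict[int, dict[str, int]]] = {
        g: {p: {} for p in range(1, k_positions + 1)} for g in range(n_groups)
    }
    gtotals: dict[int, dict[int, int]] = {
        g: {p: 0 for p in range(1, k_positions + 1)} for g in range(n_groups)
    }
    for fid, ph in items:
        g = group_of[fid]
        for j, w in enumerate(ph.words[:k_positions], start=1):
            totals[j] += 1
            gtotals[g][j] += 1
            label = w.normalized_label
            if label == "<unk>" and not include_unk:
                continue
            counts[j][label] = counts[j].get(label, 0) + 1
            gcounts[g][j][label] = gcounts[g][j].get(label, 0) + 1

    probabilities: dict[int, dict[str, float]] = {}
    ranked: dict[int, list[tuple[str, float, float]]] = {}
    for p in range(1, k_positions + 1):
        if totals[p] == 0:
            probabilities[p] = {}
            ranked[p] = []
            continue
        probs = {w: c / totals[p] for w, c in counts[p].items()}
        probabilities[p] = probs
        rank = []
        for w in sorted(probs, key=lambda w: (-probs[w], w)):
            gvals = [
                gcounts[g][p].get(w, 0) / gtotals[g][p]
                for g in range(n_groups)
                if gtotals[g][p] > 0
            ]
            sem = (
                float(np.std(gvals, ddof=1) / np.sqrt(len(gvals)))
                if len(gvals) > 1
                else 0.0
            )
            rank.append((w, probs[w], sem))
        ranked[p] = rank
    return PositionTable(probabilities, ranked, totals, n_groups)
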