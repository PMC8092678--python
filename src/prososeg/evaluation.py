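"""Scoring automatic boundaries against a reference segmentation.

The evaluation universe is the set of *boundary slots*: the onsets of words
2..n of every multi-word turn.  The slot before a turn's first word is
excluded (it is trivially a boundary), and so — by construction of the slot
universe — are slots at speaker changes.  Automatic and reference boundaries
are matched greedily, nearest first, within a time tolerance (default 50 ms,
five times the usual 10 ms aligner resolution), and the resulting
true/false positive/negative counts feed precision, recall, F-score,
accuracy and Cohen's kappa.

Also here: the chi-square test of independence used for the genre and
finality contrasts, the pause-threshold precision sweep, and final vs
non-final recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment_io import ReferenceSegmentation, Turn
from .detector import (
    Boundary,
    DetectorConfig,
    TurnDetection,
    detect,
)

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    """Boundary/no-boundary confusion counts over evaluation slots."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def n_slots(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass
class EvalMetrics:
    precision: float
    recall: float
    f_score: float
    accuracy: float
    kappa: float
    counts: ConfusionCounts


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    expected: np.ndarray
    yates: bool
    n: int


# ---------------------------------------------------------------------------
# slot matching
# ---------------------------------------------------------------------------


def _greedy_match(
    auto_times: Sequence[float], ref_times: Sequence[float], tol: float
) -> list[tuple[int, int]]:
    """Greedy nearest-first one-to-one matching within ±tol.

    Candidate pairs are ranked by |Δt|, ties broken toward the earlier
    reference boundary, then the earlier automatic boundary; each side is
    used at most once.  Quadratic and deliberately simple — turns are short.
    """
    cands = []
    for ai, at in enumerate(auto_times):
        for ri, rt in enumerate(ref_times):
            dt = abs(at - rt)
            if dt <= tol:
                cands.append((dt, rt, at, ai, ri))
    cands.sort()
    used_a: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, _, _, ai, ri in cands:
        if ai in used_a or ri in used_r:
            continue
        used_a.add(ai)
        used_r.add(ri)
        pairs.append((ai, ri))
    return pairs


def _ref_boundaries_in_turn(
    turn: Turn, ref_stream: Sequence, tol: float
) -> list[float]:
    """Reference boundary times falling strictly inside a turn: the starts
    of reference phrases other than the turn-initial one."""
    t0, t1 = turn.start, turn.end
    return [
        ph.start
        for ph in ref_stream
        if t0 + tol < ph.start <= t1 + tol
    ]


def align_boundaries(
    auto: Mapping[str, TurnDetection] | Iterable[Boundary],
    ref: ReferenceSegmentation,
    turns: Sequence[Turn] | None = None,
    tolerance_s: float = 0.050,
) -> ConfusionCounts:
    """Confusion counts of automatic vs reference boundaries.

    ``auto`` is normally the mapping returned by :func:`prososeg.detector.detect`
    (its turns supply the slot universe); alternatively a flat boundary list
    plus an explicit ``turns`` sequence.  Excluded turns contribute no slots.
    """
    if tolerance_s < 0:
        raise EvaluationError("tolerance must be non-negative")

    if isinstance(auto, Mapping):
        items = [
            (res.turn, [b for b in res.boundaries])
            for res in auto.values()
            if not res.excluded
        ]
    else:
        if turns is None:
            raise EvaluationError("flat boundary lists require explicit turns")
        blist = list(auto)
        items = []
        for turn in turns:
            items.append(
                (turn, [b for b in blist if b.turn_id == turn.turn_id])
            )

    streams = ref.by_stream()
    counts = ConfusionCounts()
    for turn, bounds in items:
        if turn.n_words < 2:
            continue
        n_slots = turn.n_words - 1
        ref_stream = streams.get((turn.file_id, turn.speaker), [])
        ref_times = _ref_boundaries_in_turn(turn, ref_stream, tolerance_s)
        auto_times = [b.time for b in bounds]
        pairs = _greedy_match(auto_times, ref_times, tolerance_s)
        tp = len(pairs)
        fp = len(auto_times) - tp
        fn = len(ref_times) - tp
        tn = max(n_slots - tp - fp - fn, 0)
        counts = counts + ConfusionCounts(tp, fp, fn, tn)
    return counts


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def compute_metrics(c: ConfusionCounts) -> EvalMetrics:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F = 2pr/(p+r), accuracy
    (TP+TN)/(TP+FP+FN+TN), and Cohen's kappa on the binary slot labels."""
    if c.n_slots == 0:
        raise EvaluationError("all-zero confusion counts: metrics undefined")
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    ac = (c.tp + c.tn) / c.n_slots
    n = c.n_slots
    po = ac
    pe = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / (n * n)
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return EvalMetrics(p, r, f, ac, kappa, c)


def evaluate(
    results: Mapping[str, TurnDetection],
    ref: ReferenceSegmentation,
    tolerance_s: float = 0.050,
) -> dict:
    """Overall and per-file metrics as a JSON-ready dict."""
    overall = compute_metrics(align_boundaries(results, ref, tolerance_s=tolerance_s))
    per_file: dict[str, EvalMetrics] = {}
    by_file: dict[str, dict] = {}
    for key, res in results.items():
        by_file.setdefault(res.turn.file_id, {})[key] = res
    for file_id, sub in sorted(by_file.items()):
        try:
            per_file[file_id] = compute_metrics(
                align_boundaries(sub, ref, tolerance_s=tolerance_s)
            )
        except EvaluationError:
            logger.warning("file %s: no evaluation slots", file_id)

    def as_dict(m: EvalMetrics) -> dict:
        return {
            "precision": m.precision,
            "recall": m.recall,
            "f_score": m.f_score,
            "accuracy": m.accuracy,
            "kappa": m.kappa,
            "counts": vars(m.counts),
        }

    return {
        "overall": as_dict(overall),
        "per_file": {k: as_dict(v) for k, v in per_file.items()},
        "tolerance_s": tolerance_s,
    }


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------


def chi_square_independence(
    observed: np.ndarray | Sequence[Sequence[float]],
    yates: bool = False,
    round_expected: bool = False,
) -> ChiSquareResult:
    """Pearson chi-square test of independence for an r×c count table.

    Expected counts are ``row_total × col_total / grand_total``;
    ``chi2 = Σ (O−E)²/E`` with the Yates continuity correction
    (|O−E| − 0.5) applied only to 2×2 tables when ``yates`` is set.

    ``round_expected`` computes the statistic against expected counts
    rounded to integers — the arithmetic used when a statistic is derived
    from a published table whose expected counts are printed rounded.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise EvaluationError("need a table with at least 2 rows and 2 columns")
    if (obs < 0).any():
        raise EvaluationError("negative counts")
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        raise EvaluationError("zero marginal total")
    expected = rows * cols / n
    e_used = np.round(expected) if round_expected else expected
    dev = np.abs(obs - e_used)
    if yates and obs.shape == (2, 2):
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / e_used).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquareResult(chi2, df, expected, yates and obs.shape == (2, 2), int(n))


# ---------------------------------------------------------------------------
# pause-threshold sweep
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    grid_s: list[float]
    precision_mean: list[float]
    precision_sem: list[float]
    no_pause_precision_mean: float
    no_pause_precision_sem: float


def _per_file_precision(
    turns: Sequence[Turn],
    ref: ReferenceSegmentation,
    config: DetectorConfig,
    tolerance_s: float,
) -> list[float]:
    results = detect(turns, config)
    by_file: dict[str, dict] = {}
    for key, res in results.items():
        by_file.setdefault(res.turn.file_id, {})[key] = res
    vals = []
    for file_id in sorted(by_file):
        c = align_boundaries(by_file[file_id], ref, tolerance_s=tolerance_s)
        if c.tp + c.fp > 0:
            vals.append(c.tp / (c.tp + c.fp))
    return vals


def pause_threshold_sweep(
    turns: Sequence[Turn],
    ref: ReferenceSegmentation,
    grid_s: Sequence[float],
    config: DetectorConfig = DetectorConfig(),
    tolerance_s: float = 0.050,
) -> SweepResult:
    """Mean per-file precision ± s.e.m. as a function of the minimal pause
    duration, plus the pauses-off condition (the sweep's Δmin → ∞ point)."""
    if len(grid_s) == 0:
        raise EvaluationError("empty sweep grid")

    def mean_sem(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals, dtype=float)
        if len(arr) == 0:
            return float("nan"), float("nan")
        sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        return float(arr.mean()), sem

    means, sems = [], []
    for dmin in grid_s:
        vals = _per_file_precision(
            turns, ref, config.replace(min_pause_s=float(dmin), use_pauses=True), tolerance_s
        )
        m, s = mean_sem(vals)
        means.append(m)
        sems.append(s)
    m_off, s_off = mean_sem(
        _per_file_precision(turns, ref, config.replace(use_pauses=False), tolerance_s)
    )
    return SweepResult(list(map(float, grid_s)), means, sems, m_off, s_off)


# ---------------------------------------------------------------------------
# finality contrast
# ---------------------------------------------------------------------------


@dataclass
class FinalityRecall:
    recall_final: float
    recall_non_final: float
    table: np.ndarray  # rows final/non-final × cols detected/missed
    chi2: ChiSquareResult


def finality_recall(
    results: Mapping[str, TurnDetection],
    ref: ReferenceSegmentation,
    tolerance_s: float = 0.050,
) -> FinalityRecall:
    """Recall of final vs non-final reference units.

    A reference unit is *detected* when the boundary terminating it (the
    start of the next reference phrase in the same turn) is matched by an
    automatic boundary within tolerance.  Units followed by a speaker
    change — the last unit of each turn — are not considered.
    """
    streams = ref.by_stream()
    det = {"final": 0, "non-final": 0}
    mis = {"final": 0, "non-final": 0}
    any_labels = False
    for res in results.values():
        if res.excluded:
            continue
        turn = res.turn
        ref_stream = streams.get((turn.file_id, turn.speaker), [])
        in_turn = [
            ph
            for ph in ref_stream
            if turn.start - tolerance_s <= ph.start <= turn.end + tolerance_s
        ]
        auto_times = [b.time for b in res.boundaries]
        for unit, nxt in zip(in_turn, in_turn[1:]):
            if unit.finality == "unknown":
                continue
            any_labels = True
            hit = any(abs(t - nxt.start) <= tolerance_s for t in auto_times)
            (det if hit else mis)[unit.finality] += 1
    if not any_labels:
        raise EvaluationError("reference carries no finality labels")
    n_fin = det["final"] + mis["final"]
    n_non = det["non-final"] + mis["non-final"]
    if n_fin == 0 or n_non == 0:
        raise EvaluationError(
            "need both final and non-final units for the contrast"
        )
    table = np.array(
        [[det["final"], mis["final"]], [det["non-final"], mis["non-final"]]]
    )
    chi2 = chi_square_independence(table, yates=True)
    return FinalityRecall(det["final"] / n_fin, det["non-final"] / n_non, table, chi2)
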