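"""Phrase-level pitch statistics: declination, reset, end variability.

Pitch never drives detection here — it is the *independent* validation
channel: if detected phrase boundaries are real, the F0 contour averaged
over phrases should show the classic declination-with-reset shape (an early
peak around normalized time 0.2, a 10-20% decline toward the end), whereas
randomly placed boundaries average out to a flat curve.

Input is a pre-extracted pitch track per (file, speaker): (time, F0)
samples, e.g. Praat output at 10 ms steps (75-600 Hz range).  Extraction
from audio is out of scope.  Post-processing mirrors the usual Praat
recipe: median filter, interpolation of sub-25 ms unvoiced gaps, 25 ms
Hamming smoothing; each phrase's contour is then resampled at 40 equally
spaced points over its normalized [0, 1] time axis and divided by its own
mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

N_GRID = 40
#: Normalized-time grid of the resampled contours.
T_GRID = np.linspace(0.0, 1.0, N_GRID)

BEGIN_WINDOW = (0.15, 0.25)
END_WINDOW = (0.85, 0.95)
FIRST_HALF = (0.0, 0.5)
LAST_TENTH = (0.9, 1.0)


class PitchError(ValueError):
    pass


@dataclass
class PitchContour:
    """Raw (time, F0) samples; NaN = unvoiced/missing.  Times strictly
    increasing."""

    times: np.ndarray
    f0: np.ndarray
    speaker: str = ""
    file_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.times.size == 0:
            raise PitchError("empty pitch contour")
        if self.times.size != self.f0.size:
            raise PitchError("times and f0 differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise PitchError("times must be strictly increasing")

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)


@dataclass(frozen=True)
class NormalizedContour:
    """40-point, time- and amplitude-normalized contour of one phrase.
    ``value`` has mean 1 and no missing entries."""

    value: np.ndarray
    file_id: str = ""
    speaker: str = ""


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _median_filter_runs(f0: np.ndarray, voiced: np.ndarray, length: int) -> np.ndarray:
    out = f0.copy()
    n = len(f0)
    idx = np.flatnonzero(voiced)
    if idx.size == 0:
        return out
    # contiguous voiced runs
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    half = length // 2
    for run in runs:
        vals = f0[run]
        if len(vals) < 3:
            continue
        med = np.empty_like(vals)
        for i in range(len(vals)):
            lo = max(0, i - half)
            hi = min(len(vals), i + half + 1)
            med[i] = np.median(vals[lo:hi])
        out[run] = med
    return out


def preprocess_pitch(
    contour: PitchContour,
    median_len: int = 5,
    max_gap_s: float = 0.025,
    hamming_s: float = 0.025,
) -> PitchContour:
    """Median-filter, fill short unvoiced gaps, and smooth one pitch track.

    A gap is fillable when the time span between its flanking voiced
    samples is strictly below ``max_gap_s``; longer gaps stay missing.
    Smoothing is a normalized Hamming-window moving average of ``hamming_s``
    extent, applied per voiced run, hence the identity on constants.
    """
    t = contour.times
    f0 = _median_filter_runs(contour.f0, contour.voiced, median_len)

    # interpolate short gaps
    voiced = ~np.isnan(f0)
    idx = np.flatnonzero(voiced)
    if idx.size == 0:
        raise PitchError("contour has no voiced samples")
    filled = f0.copy()
    for a, b in zip(idx, idx[1:]):
        if b - a > 1 and (t[b] - t[a]) < max_gap_s:
            filled[a + 1 : b] = np.interp(t[a + 1 : b], [t[a], t[b]], [f0[a], f0[b]])

    # Hamming smoothing per voiced run
    voiced = ~np.isnan(filled)
    dt = np.median(np.diff(t))
    n_win = max(int(round(hamming_s / dt)), 1)
    if n_win % 2 == 0:
        n_win += 1
    if n_win >= 3:
        win = np.hamming(n_win)
        win /= win.sum()
        out = filled.copy()
        runs = np.split(
            np.flatnonzero(voiced), np.flatnonzero(np.diff(np.flatnonzero(voiced)) > 1) + 1
        )
        for run in runs:
            if len(run) == 0:
                continue
            vals = filled[run]
            if len(vals) < 3:
                continue
            pad = n_win // 2
            padded = np.concatenate(
                [vals[pad:0:-1], vals, vals[-2 : -2 - pad : -1]]
            )
            out[run] = np.convolve(padded, win, mode="valid")
        filled = out
    return PitchContour(t, filled, contour.speaker, contour.file_id)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_contour(
    contour: PitchContour,
    start: float,
    end: float,
    min_voiced: int = 4,
    max_missing_frac: float = 0.5,
) -> NormalizedContour | None:
    """Time- and amplitude-normalize the contour segment over one phrase.

    The phrase span is linearly rescaled to [0, 1] and resampled on the
    40-point grid from the voiced samples; the result is divided by its own
    mean (so the normalized values average exactly 1).  Returns None (with
    a logged reason) when the segment has fewer than ``min_voiced`` voiced
    samples or more than ``max_missing_frac`` missing ones.
    """
    if end <= start:
        raise PitchError(f"empty phrase span [{start}, {end}]")
    sel = (contour.times >= start) & (contour.times <= end)
    t = contour.times[sel]
    f0 = contour.f0[sel]
    voiced = ~np.isnan(f0)
    if voiced.sum() < min_voiced:
        logger.debug("phrase [%s, %s]: only %d voiced samples", start, end, voiced.sum())
        return None
    if f0.size and (1.0 - voiced.sum() / f0.size) > max_missing_frac:
        logger.debug("phrase [%s, %s]: too much missing pitch", start, end)
        return None
    u = (t[voiced] - start) / (end - start)
    vals = np.interp(T_GRID, u, f0[voiced])
    vals = vals / vals.mean()
    return NormalizedContour(vals, contour.file_id, contour.speaker)


def phrase_contours(
    spans: Iterable[tuple[str, str, float, float]],
    pitch_by_stream: Mapping[tuple[str, str], PitchContour],
    preprocess: bool = True,
) -> list[NormalizedContour]:
    """Normalized contours for ``(file_id, speaker, start, end)`` spans;
    spans without usable pitch are skipped."""
    prepped: dict[tuple[str, str], PitchContour] = {}
    out: list[NormalizedContour] = []
    for file_id, speaker, start, end in spans:
        key = (file_id, speaker)
        if key not in pitch_by_stream:
            continue
        if key not in prepped:
            prepped[key] = (
                preprocess_pitch(pitch_by_stream[key]) if preprocess else pitch_by_stream[key]
            )
        nc = normalize_contour(prepped[key], start, end)
        if nc is not None:
            out.append(nc)
    return out


# ---------------------------------------------------------------------------
# reset statistics
# ---------------------------------------------------------------------------


def _window_mask(window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (T_GRID >= lo - 1e-12) & (T_GRID <= hi + 1e-12)


@dataclass
class PitchResetStats:
    """Across-file pitch declination/reset summary (per-file statistics,
    paired t-tests across files)."""

    mean_curve: np.ndarray
    std_curve: np.ndarray
    begin_mean: float
    end_mean: float
    decline_frac: float
    p_decline: float
    std_first_half: float
    std_last_tenth: float
    p_end_variability: float
    n_files: int
    n_contours: int
    per_file_begin: np.ndarray | None = None
    per_file_end: np.ndarray | None = None


def pitch_reset_stats(contours: Sequence[NormalizedContour]) -> PitchResetStats:
    """Mean/variability curves and the begin-vs-end contrasts.

    Per file: the across-contour mean curve and the across-contour standard
    deviation curve on the normalized grid; the "begin" statistic is the
    mean over t = 0.15-0.25, "end" over t = 0.85-0.95; variability is
    contrasted between the first half (t = 0-0.5) and the last tenth
    (t = 0.9-1).  Contrasts are one-sided paired Student's t-tests across
    files (skipped, p = NaN, when there is a single file).
    """
    if len(contours) < 2:
        raise PitchError("need at least two contours")
    by_file: dict[str, list[np.ndarray]] = {}
    for c in contours:
        by_file.setdefault(c.file_id, []).append(c.value)
    files = sorted(by_file)

    m_begin = _window_mask(BEGIN_WINDOW)
    m_end = _window_mask(END_WINDOW)
    m_half = _window_mask(FIRST_HALF)
    m_tenth = _window_mask(LAST_TENTH)

    mean_curves, std_curves = [], []
    f_begin, f_end, f_half, f_tenth = [], [], [], []
    for fid in files:
        arr = np.vstack(by_file[fid])
        if arr.shape[0] < 2:
            logger.warning("file %s: fewer than 2 contours, skipping", fid)
            continue
        mc = arr.mean(axis=0)
        sc = arr.std(axis=0, ddof=1)
        mean_curves.append(mc)
        std_curves.append(sc)
        f_begin.append(mc[m_begin].mean())
        f_end.append(mc[m_end].mean())
        f_half.append(sc[m_half].mean())
        f_tenth.append(sc[m_tenth].mean())
    if not mean_curves:
        raise PitchError("no file group with at least two contours")

    mean_curve = np.vstack(mean_curves).mean(axis=0)
    std_curve = np.vstack(std_curves).mean(axis=0)
    begin = float(np.mean(f_begin))
    end = float(np.mean(f_end))
    if len(f_begin) >= 2:
        p_decl = float(stats.ttest_rel(f_begin, f_end, alternative="greater").pvalue)
        p_var = float(stats.ttest_rel(f_tenth, f_half, alternative="greater").pvalue)
    else:
        logger.warning("single file: t-tests skipped")
        p_decl = p_var = float("nan")
    return PitchResetStats(
        mean_curve=mean_curve,
        std_curve=std_curve,
        begin_mean=begin,
        end_mean=end,
        decline_frac=1.0 - end / begin,
        p_decline=p_decl,
        std_first_half=float(np.mean(f_half)),
        std_last_tenth=float(np.mean(f_tenth)),
        p_end_variability=p_var,
        n_files=len(mean_curves),
        n_contours=len(contours),
        per_file_begin=np.asarray(f_begin),
        per_file_end=np.asarray(f_end),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_pitch_tsv(path: str | Path) -> dict[tuple[str, str], PitchContour]:
    """Read a pitch TSV (``file_id speaker time f0``; empty f0 = unvoiced)
    into one contour per (file, speaker) stream."""
    lines = [
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()
    ]
    if not lines or lines[0].split("\t")[:4] != ["file_id", "speaker", "time", "f0"]:
        raise PitchError(f"{path}: expected header 'file_id speaker time f0'")
    data: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for row_no, ln in enumerate(lines[1:], start=2):
        cols = ln.split("\t")
        try:
            t = float(cols[2])
            f0 = float(cols[3]) if len(cols) > 3 and cols[3] != "" else float("nan")
        except (ValueError, IndexError) as exc:
            raise PitchError(f"{path}: row {row_no}: malformed row ({exc})") from None
        data.setdefault((cols[0], cols[1]), []).append((t, f0))
    out = {}
    for key, samples in data.items():
        samples.sort()
        times = np.array([s[0] for s in samples])
        f0 = np.array([s[1] for s in samples])
        out[key] = PitchContour(times, f0, speaker=key[1], file_id=key[0])
    return out


def write_pitch_tsv(
    path: str | Path, contours: Mapping[tuple[str, str], PitchContour]
) -> None:
    lines = ["\t".join(["file_id", "speaker", "time", "f0"])]
    for (file_id, speaker), c in contours.items():
        for t, f0 in zip(c.times, c.f0):
            f0s = "" if np.isnan(f0) else f"{f0:.2f}"
            lines.append("\t".join([file_id, speaker, f"{t:.4f}", f0s]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pitch_tier(path: str | Path, file_id: str = "", speaker: str = "") -> PitchContour:
    """Read a Praat PitchTier (text format, long or short) as a contour."""
    text = Path(path).read_text(encoding="utf-8")
    if "PitchTier" not in text:
        raise PitchError(f"{path}: not a PitchTier file")
    import re

    pairs = re.findall(
        r"number\s*=\s*([-\d.eE+]+)\s*value\s*=\s*([-\d.eE+]+)", text
    )
    if not pairs:  # short format: xmin, xmax, n, then time/value pairs
        nums = re.findall(r"^\s*([-\d.eE+]+)\s*$", text, flags=re.M)
        vals = [float(x) for x in nums][3:]
        pairs = list(zip(vals[0::2], vals[1::2]))
    if not pairs:
        raise PitchError(f"{path}: no pitch points found")
    times = np.array([float(a) for a, _ in pairs])
    f0 = np.array([float(b) for _, b in pairs])
    order = np.argsort(times)
    return PitchContour(times[order], f0[order], speaker=speaker, file_id=file_id)
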