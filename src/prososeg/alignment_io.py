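"""Forced-alignment timing I/O and turn assembly.

The detector consumes word- and phone-level timings as produced by a forced
aligner (e.g. the Montreal Forced Aligner).  Two on-disk representations are
supported:

* Praat TextGrid files with a word interval tier and a phone interval tier
  (one file per recording/speaker channel);
* a flat tab-separated "alignment TSV" with one row per phone, which is the
  native exchange format of this package (see :data:`ALIGNMENT_COLUMNS`).

All times are absolute seconds from file start; intervals are half-open
``[start, end)``.  Silence is never represented as a token: it exists only as
the gap between consecutive words, which is exactly the quantity the
detector's pause rule operates on.

Words without phone timings (the aligner emits ``<unk>`` for out-of-dictionary
words) are kept as :class:`WordToken` with an empty phone list: they occupy
their time span (and therefore shape gaps and positions) but contribute no
phones to speech-rate windows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._textgrid import read_textgrid_tiers, write_textgrid_file

logger = logging.getLogger(__name__)

#: Column order of the alignment TSV dialect (one row per phone; phone columns
#: empty for words lacking phone timings).
ALIGNMENT_COLUMNS = (
    "file_id",
    "turn_id",
    "speaker",
    "word_index",
    "word_label",
    "word_start",
    "word_end",
    "phone_label",
    "phone_start",
    "phone_end",
)

#: Time resolution (seconds) used when serialising; forced aligners typically
#: quantise at 10 ms, we keep 1 ms headroom below that.
TIME_DECIMALS = 4


class AlignmentFormatError(ValueError):
    """A file does not follow the expected alignment format."""


class AlignmentValidationError(ValueError):
    """Timing data violate an ordering/containment invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhoneInterval:
    """One phone with absolute timings, ``end > start``."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.end > self.start >= 0.0):
            raise AlignmentValidationError(
                f"phone {self.label!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class WordToken:
    """One word with absolute timings and its (possibly empty) phones."""

    label: str
    start: float
    end: float
    phones: tuple[PhoneInterval, ...] = ()

    def __post_init__(self) -> None:
        if not (self.end > self.start >= 0.0):
            raise AlignmentValidationError(
                f"word {self.label!r}: invalid interval [{self.start}, {self.end})"
            )
        eps = 1e-9
        prev_end = None
        for ph in self.phones:
            if ph.start < self.start - eps or ph.end > self.end + eps:
                raise AlignmentValidationError(
                    f"phone {ph.label!r} [{ph.start}, {ph.end}) outside word "
                    f"{self.label!r} [{self.start}, {self.end})"
                )
            if prev_end is not None and ph.start < prev_end - eps:
                raise AlignmentValidationError(
                    f"overlapping phones in word {self.label!r} at {ph.start}"
                )
            prev_end = ph.end

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def has_phone_timings(self) -> bool:
        return len(self.phones) > 0

    @property
    def normalized_label(self) -> str:
        """Lowercased label with surrounding annotation marks stripped
        (used for lexical statistics only; the original label is kept)."""
        return self.label.strip().strip("-=~%@.,?!\"'()[]").lower()


@dataclass(frozen=True)
class Turn:
    """One speaker's uninterrupted stretch of speech: ordered, non-overlapping
    words."""

    turn_id: str
    speaker: str
    words: tuple[WordToken, ...]
    file_id: str = ""
    genre_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.words:
            raise AlignmentValidationError(f"turn {self.turn_id!r} holds no words")
        eps = 1e-9
        for prev, cur in zip(self.words, self.words[1:]):
            if cur.start < prev.end - eps:
                raise AlignmentValidationError(
                    f"turn {self.turn_id!r}: words {prev.label!r}/{cur.label!r} "
                    f"overlap at {cur.start}"
                )

    @property
    def start(self) -> float:
        return self.words[0].start

    @property
    def end(self) -> float:
        return self.words[-1].end

    @property
    def n_words(self) -> int:
        return len(self.words)

    def gaps(self) -> list[float]:
        """Inter-word silent gaps, one per word pair (``len == n_words - 1``)."""
        return [b.start - a.end for a, b in zip(self.words, self.words[1:])]


@dataclass(frozen=True)
class ReferencePhrase:
    """One manually annotated phrase (intonation unit)."""

    file_id: str
    speaker: str
    start: float
    end: float
    finality: str = "unknown"  # {final, non-final, unknown}
    words: tuple[str, ...] = ()


@dataclass
class ReferenceSegmentation:
    """Ordered, per-speaker-stream reference phrases."""

    phrases: list[ReferencePhrase] = field(default_factory=list)

    def by_stream(self) -> dict[tuple[str, str], list[ReferencePhrase]]:
        streams: dict[tuple[str, str], list[ReferencePhrase]] = {}
        for ph in self.phrases:
            streams.setdefault((ph.file_id, ph.speaker), []).append(ph)
        for key, phs in streams.items():
            phs.sort(key=lambda p: p.start)
            for a, b in zip(phs, phs[1:]):
                if b.start < a.end - 1e-9:
                    raise AlignmentValidationError(
                        f"reference phrases overlap in stream {key} at {b.start}"
                    )
        return streams

    def __len__(self) -> int:
        return len(self.phrases)


# ---------------------------------------------------------------------------
# TextGrid
# ---------------------------------------------------------------------------


def read_textgrid(
    path: str | Path,
    word_tier: str = "words",
    phone_tier: str = "phones",
) -> list[WordToken]:
    """Read word and phone interval tiers from a Praat TextGrid.

    Non-empty, non-silence word intervals become :class:`WordToken`; phone
    intervals are attached to the word whose span contains their midpoint
    (robust to 10 ms rounding at word edges).  Empty / silence-labelled
    intervals are ignored, i.e. silence stays implicit as inter-word gaps.
    """
    tiers = read_textgrid_tiers(path)
    for name in (word_tier, phone_tier):
        if name not in tiers:
            raise AlignmentFormatError(
                f"{path}: tier {name!r} not found; available tiers: "
                f"{sorted(tiers)}"
            )

    silence_labels = {"", "sil", "sp", "spn", "<sil>", "", "sil "}
    word_ivs = [
        iv for iv in tiers[word_tier] if iv[2].strip().lower() not in silence_labels
    ]
    phone_ivs = [
        iv for iv in tiers[phone_tier] if iv[2].strip().lower() not in silence_labels
    ]

    for i, (a, b) in enumerate(zip(word_ivs, word_ivs[1:])):
        if b[0] < a[1] - 1e-9:
            raise AlignmentValidationError(
                f"{path}: word intervals {i} and {i + 1} overlap "
                f"([{a[0]}, {a[1]}) vs [{b[0]}, {b[1]}))"
            )

    words: list[WordToken] = []
    for wstart, wend, wlabel in word_ivs:
        phones = tuple(
            PhoneInterval(plabel, pstart, pend)
            for pstart, pend, plabel in phone_ivs
            if wstart <= 0.5 * (pstart + pend) < wend
        )
        words.append(WordToken(wlabel.strip(), wstart, wend, phones))
    return words


def write_textgrid(
    path: str | Path,
    words: Sequence[WordToken],
    word_tier: str = "words",
    phone_tier: str = "phones",
) -> None:
    """Write words/phones as a (long-format) TextGrid with two interval tiers,
    inserting empty intervals for the silent gaps."""
    word_ivs = [(w.start, w.end, w.label) for w in words]
    phone_ivs = [(p.start, p.end, p.label) for w in words for p in w.phones]
    write_textgrid_file(path, {word_tier: word_ivs, phone_tier: phone_ivs})


# ---------------------------------------------------------------------------
# alignment TSV
# ---------------------------------------------------------------------------


def _fmt_time(t: float) -> str:
    return f"{t:.{TIME_DECIMALS}f}"


def write_alignment_tsv(path: str | Path, turns: Iterable[Turn]) -> None:
    """Serialise turns to the alignment TSV dialect (one row per phone; a
    single row with empty phone columns for words without phone timings)."""
    lines = ["\t".join(ALIGNMENT_COLUMNS)]
    for turn in turns:
        for wi, w in enumerate(turn.words):
            base = [
                turn.file_id,
                turn.turn_id,
                turn.speaker,
                str(wi),
                w.label,
                _fmt_time(w.start),
                _fmt_time(w.end),
            ]
            if w.phones:
                for ph in w.phones:
                    lines.append(
                        "\t".join(
                            base + [ph.label, _fmt_time(ph.start), _fmt_time(ph.end)]
                        )
                    )
            else:
                lines.append("\t".join(base + ["", "", ""]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_alignment_tsv(path: str | Path) -> list[Turn]:
    """Read the alignment TSV dialect back into validated :class:`Turn` lists.

    Rows are grouped by ``(file_id, turn_id)`` in order of first appearance;
    non-monotone word times within a turn raise
    :class:`AlignmentValidationError` naming the row.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AlignmentFormatError(f"{path}: empty file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != ALIGNMENT_COLUMNS:
        raise AlignmentFormatError(
            f"{path}: bad header {header!r}, expected {ALIGNMENT_COLUMNS!r}"
        )

    # (file_id, turn_id) -> word_index -> (label, start, end, speaker, phones)
    order: list[tuple[str, str]] = []
    turns_raw: dict[tuple[str, str], dict[int, dict]] = {}
    for row_no, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != len(ALIGNMENT_COLUMNS):
            raise AlignmentFormatError(
                f"{path}: row {row_no}: expected {len(ALIGNMENT_COLUMNS)} "
                f"columns, got {len(cols)}"
            )
        rec = dict(zip(ALIGNMENT_COLUMNS, cols))
        try:
            widx = int(rec["word_index"])
            wstart = float(rec["word_start"])
            wend = float(rec["word_end"])
        except ValueError as exc:
            raise AlignmentFormatError(
                f"{path}: row {row_no}: malformed numeric field ({exc})"
            ) from None
        key = (rec["file_id"], rec["turn_id"])
        if key not in turns_raw:
            turns_raw[key] = {}
            order.append(key)
        word = turns_raw[key].setdefault(
            widx,
            {
                "label": rec["word_label"],
                "start": wstart,
                "end": wend,
                "speaker": rec["speaker"],
                "phones": [],
                "row": row_no,
            },
        )
        if rec["phone_label"]:
            try:
                pstart = float(rec["phone_start"])
                pend = float(rec["phone_end"])
            except ValueError as exc:
                raise AlignmentFormatError(
                    f"{path}: row {row_no}: malformed phone time ({exc})"
                ) from None
            word["phones"].append(PhoneInterval(rec["phone_label"], pstart, pend))

    turns: list[Turn] = []
    for file_id, turn_id in order:
        raw = turns_raw[(file_id, turn_id)]
        words = []
        prev_end = None
        for widx in sorted(raw):
            rec = raw[widx]
            if prev_end is not None and rec["start"] < prev_end - 1e-9:
                raise AlignmentValidationError(
                    f"{path}: row {rec['row']}: non-monotone word times in turn "
                    f"{turn_id!r} (word starts at {rec['start']} before previous "
                    f"end {prev_end})"
                )
            prev_end = rec["end"]
            words.append(
                WordToken(
                    rec["label"], rec["start"], rec["end"], tuple(rec["phones"])
                )
            )
        speaker = raw[min(raw)]["speaker"]
        turns.append(Turn(turn_id, speaker, tuple(words), file_id=file_id))
    return turns


# ---------------------------------------------------------------------------
# turn assembly & reference boundaries
# ---------------------------------------------------------------------------


def assemble_turns(
    words: Sequence[WordToken],
    speakers: Sequence[str],
    file_id: str = "",
) -> list[Turn]:
    """Group a time-ordered word stream into turns: consecutive same-speaker
    words form one turn; a speaker change closes the turn."""
    if len(words) != len(speakers):
        raise AlignmentValidationError(
            f"{len(words)} words but {len(speakers)} speaker labels"
        )
    turns: list[Turn] = []
    run: list[WordToken] = []
    run_speaker: str | None = None
    for w, spk in zip(words, speakers):
        if run and spk != run_speaker:
            turns.append(
                Turn(f"t{len(turns)}", run_speaker, tuple(run), file_id=file_id)
            )
            run = []
        run.append(w)
        run_speaker = spk
    if run:
        turns.append(Turn(f"t{len(turns)}", run_speaker, tuple(run), file_id=file_id))
    return turns


def read_reference_boundaries(path: str | Path) -> ReferenceSegmentation:
    """Read a reference TSV (``file_id speaker start end [finality]``) into a
    :class:`ReferenceSegmentation`; rows are sorted by start per stream."""
    lines = [
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()
    ]
    if not lines:
        raise AlignmentFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    required = ["file_id", "speaker", "start", "end"]
    if header[: len(required)] != required:
        raise AlignmentFormatError(
            f"{path}: bad header {header!r}, expected columns {required} "
            "(+ optional 'finality')"
        )
    has_finality = len(header) > 4 and header[4] == "finality"

    phrases: list[ReferencePhrase] = []
    for row_no, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        try:
            start, end = float(cols[2]), float(cols[3])
        except (ValueError, IndexError) as exc:
            raise AlignmentFormatError(
                f"{path}: row {row_no}: malformed row ({exc})"
            ) from None
        finality = cols[4] if has_finality and len(cols) > 4 and cols[4] else "unknown"
        if finality not in ("final", "non-final", "unknown"):
            raise AlignmentFormatError(
                f"{path}: row {row_no}: bad finality label {finality!r}"
            )
        phrases.append(ReferencePhrase(cols[0], cols[1], start, end, finality))

    seg = ReferenceSegmentation(phrases)
    ordered = [p for phs in seg.by_stream().values() for p in phs]  # validates
    keys = [(p.file_id, p.speaker, p.start) for p in seg.phrases]
    by_stream_order = sorted(keys, key=lambda k: (k[0], k[1]))
    if [k[2] for k in by_stream_order] != [
        k[2] for k in sorted(keys)
    ]:
        logger.warning("%s: reference rows were not sorted by start; sorting", path)
    seg.phrases = sorted(ordered, key=lambda p: (p.file_id, p.speaker, p.start))
    return seg


def write_reference_tsv(path: str | Path, seg: ReferenceSegmentation) -> None:
    lines = ["\t".join(["file_id", "speaker", "start", "end", "finality"])]
    for ph in seg.phrases:
        lines.append(
            "\t".join(
                [ph.file_id, ph.speaker, _fmt_time(ph.start), _fmt_time(ph.end), ph.finality]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def phrases_to_json(results: Mapping[str, list], path: str | Path | None = None) -> str:
    """Serialise per-turn detection results (see ``detector.detect``) to the
    phrases JSON schema; returns the JSON text, optionally writing it."""
    payload = []
    by_file: dict[str, list] = {}
    for res in results.values():
        by_file.setdefault(res.turn.file_id, []).append(res)
    for file_id in sorted(by_file):
        payload.append(
            {
                "file_id": file_id,
                "turns": [
                    {
                        "turn_id": r.turn.turn_id,
                        "speaker": r.turn.speaker,
                        "excluded": r.excluded,
                        "boundaries": [
                            {
                                "time": round(b.time, TIME_DECIMALS),
                                "word_index": b.word_index,
                                "source": b.source,
                            }
                            for b in r.boundaries
                        ],
                        "phrases": [
                            {
                                "start": round(p.start, TIME_DECIMALS),
                                "end": round(p.end, TIME_DECIMALS),
                                "n_words": p.n_words,
                                "words": [w.label for w in p.words],
                            }
                            for p in r.phrases
                        ],
                    }
                    for r in sorted(by_file[file_id], key=lambda r: r.turn.start)
                ],
            }
        )
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
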