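"""Independent brute-force reference implementation of the boundary
detector, used only as a test oracle.

Deliberately naive: nested loops, no numpy, no shared code with the
package's detector beyond the data types.  Any divergence between this and
``prososeg.detector.detect_turn`` on random inputs is a bug in one of them.
"""

from __future__ import annotations

from prososeg.alignment_io import Turn
from prososeg.detector import DetectorConfig


def naive_speech_rate(turn: Turn, cfg: DetectorConfig) -> list[float | None]:
    """Rate per word onset: 1 / mean duration of phones whose midpoint lies
    in [onset, onset + W); None where no phone qualifies."""
    rates: list[float | None] = []
    for w in turn.words:
        t0 = w.start
        durs = []
        for ww in turn.words:
            for ph in ww.phones:
                mid = (ph.start + ph.end) / 2.0
                if t0 <= mid < t0 + cfg.window_s:
                    durs.append(ph.end - ph.start)
        rates.append(len(durs) / sum(durs) if durs else None)
    return rates


def naive_detect_turn(turn: Turn, cfg: DetectorConfig) -> set[tuple[int, str]]:
    """Boundary set as {(word_index, source)}; empty for excluded turns."""
    if turn.n_words < cfg.min_turn_words:
        return set()
    if all(not w.phones for w in turn.words):
        return set()
    rates = naive_speech_rate(turn, cfg)

    defined = [(i, r) for i, r in enumerate(rates) if r is not None]
    diffs = []  # (word_index, prev_word_index, diff)
    for (i0, r0), (i1, r1) in zip(defined, defined[1:]):
        d = r1 - r0
        if cfg.use_absolute_diffs:
            d = abs(d)
        diffs.append((i1, i0, d))

    # pass 1
    pos = [d for _, _, d in diffs if d > 0]
    pass1 = set()
    if pos:
        theta = cfg.dsr_threshold_frac * max(pos)
        for wi, _, d in diffs:
            if d > theta:
                pass1.add(wi)

    # pass 2: one re-thresholding inside long boundary-free stretches
    pass2 = set()
    edges = [0] + sorted(pass1) + [turn.n_words]
    for a, b in zip(edges, edges[1:]):
        if b <= a:
            continue
        duration = turn.words[b - 1].end - turn.words[a].start
        if not (
            duration > cfg.second_pass_min_duration_s
            and (b - a) > cfg.second_pass_min_words
        ):
            continue
        local = [(wi, d) for wi, pi, d in diffs if a < wi < b and pi >= a]
        lpos = [d for _, d in local if d > 0]
        if not lpos:
            continue
        theta2 = cfg.second_pass_threshold_frac * max(lpos)
        for wi, d in local:
            if d > theta2 and wi not in pass1:
                pass2.add(wi)

    # pauses
    pauses = set()
    if cfg.use_pauses:
        for i in range(1, turn.n_words):
            if turn.words[i].start - turn.words[i - 1].end > cfg.min_pause_s:
                pauses.add(i)

    out = set()
    for wi in pass1:
        out.add((wi, "dsr_pass1"))
    for wi in pass2:
        out.add((wi, "dsr_pass2"))
    for wi in pauses:
        if wi not in pass1 and wi not in pass2:
            out.add((wi, "pause"))
    return out
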