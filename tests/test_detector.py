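"""Detector: speech rate, DSR passes, pauses, merging, segmentation."""

import numpy as np
import pytest

from prososeg.alignment_io import PhoneInterval, Turn, WordToken, phrases_to_json
from prososeg.detector import (
    Boundary,
    DetectorConfig,
    DetectorError,
    SpeechRateSeries,
    compute_speech_rate,
    detect,
    detect_dsr_pass1,
    detect_dsr_pass2,
    detect_pause_boundaries,
    detect_turn,
    merge_boundaries,
    segment_turn,
)
from prososeg.synth import SynthConfig, generate_corpus

from conftest import make_random_turn
from reference_impl import naive_speech_rate


def word(label, start, phone_durs, gap_before=0.0):
    """Build a word whose phones partition it."""
    bounds = [start]
    for d in phone_durs:
        bounds.append(bounds[-1] + d)
    phones = tuple(
        PhoneInterval("P", a, b) for a, b in zip(bounds[:-1], bounds[1:])
    )
    return WordToken(label, bounds[0], bounds[-1], phones)


def chain(phone_dur_lists, gaps=None):
    """Turn of words with the given per-word phone durations and optional
    inter-word gaps."""
    gaps = gaps or [0.0] * (len(phone_dur_lists) - 1)
    t = 0.0
    words = []
    for i, pd in enumerate(phone_dur_lists):
        words.append(word(f"w{i}", t, pd))
        t = words[-1].end + (gaps[i] if i < len(gaps) else 0.0)
    return Turn("t0", "A", tuple(words), file_id="f")


def series_from_rates(rates):
    """Hand-built SpeechRateSeries at 1-s word spacing."""
    rates = np.asarray(rates, dtype=float)
    onsets = np.arange(len(rates), dtype=float)
    idx = np.flatnonzero(~np.isnan(rates))
    return SpeechRateSeries(
        onsets,
        rates,
        (~np.isnan(rates)).astype(int),
        idx[1:],
        rates[idx[1:]] - rates[idx[:-1]],
    )


class TestSpeechRate:
    def test_uniform_phones_give_inverse_mean(self):
        turn = chain([[0.1, 0.1, 0.1], [0.1, 0.1]])
        s = compute_speech_rate(turn, DetectorConfig())
        # window at word 0 covers exactly the first 3 phones (0.3 s)
        assert s.rate[0] == pytest.approx(10.0)
        assert s.n_phones_in_window[0] == 3

    def test_silence_in_window_is_excluded(self):
        # 0.2 s word, 0.5 s silence, next word outside the window
        turn = chain([[0.1, 0.1], [0.1, 0.1]], gaps=[0.5])
        s = compute_speech_rate(turn, DetectorConfig())
        assert s.rate[0] == pytest.approx(10.0)  # only the first word's phones
        assert s.n_phones_in_window[0] == 2

    def test_unk_word_has_undefined_rate_not_zero(self):
        w0 = word("a", 0.0, [0.1, 0.1])
        unk = WordToken("<unk>", 0.2, 0.8)
        w2 = word("b", 0.8, [0.1, 0.1])
        turn = Turn("t", "A", (w0, unk, w2))
        s = compute_speech_rate(turn, DetectorConfig())
        assert np.isnan(s.rate[1])
        assert s.defined.tolist() == [True, False, True]
        # diffs skip the undefined word: one diff between words 0 and 2
        assert s.diff_word_index.tolist() == [2]

    def test_no_phones_at_all_raises(self):
        turn = Turn(
            "t", "A", (WordToken("<unk>", 0.0, 0.3), WordToken("<unk>", 0.3, 0.6))
        )
        with pytest.raises(DetectorError, match="no phone timings"):
            compute_speech_rate(turn, DetectorConfig())

    def test_matches_naive_enumeration_on_random_turns(self):
        rng = np.random.default_rng(12)
        cfg = DetectorConfig()
        for _ in range(200):
            turn = make_random_turn(rng)
            if all(not w.phones for w in turn.words):
                continue
            s = compute_speech_rate(turn, cfg)
            ref = naive_speech_rate(turn, cfg)
            for got, want in zip(s.rate, ref):
                if want is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, rel=1e-12)


class TestDsrPass1:
    def test_single_dominant_jump(self):
        s = series_from_rates([5, 5, 9, 5])
        assert s.diffs.tolist() == [0.0, 4.0, -4.0]
        bounds = detect_dsr_pass1(s, DetectorConfig())
        assert [(b.word_index, b.source) for b in bounds] == [(2, "dsr_pass1")]

    def test_strictly_decreasing_rates_give_no_boundary(self):
        s = series_from_rates([9, 7, 5, 3])
        assert detect_dsr_pass1(s, DetectorConfig()) == []

    def test_argmax_is_always_flagged(self):
        rng = np.random.default_rng(13)
        cfg = DetectorConfig()
        for _ in range(1000):
            rates = rng.uniform(2.0, 20.0, size=rng.integers(2, 12))
            s = series_from_rates(rates)
            d = s.diffs
            if len(d) == 0 or d.max() <= 0:
                continue
            argmax_word = int(s.diff_word_index[int(np.argmax(d))])
            flagged = {b.word_index for b in detect_dsr_pass1(s, cfg)}
            assert argmax_word in flagged

    def test_ties_at_maximum_all_flagged(self):
        s = series_from_rates([5, 9, 5, 9])
        flagged = {b.word_index for b in detect_dsr_pass1(s, DetectorConfig())}
        assert flagged == {1, 3}


class TestDsrPass2:
    def test_short_stretch_untouched(self):
        # 6 words x ~0.33 s = 2 s: below both stretch minima
        turn = chain([[0.11, 0.11, 0.11]] * 6)
        s = compute_speech_rate(turn, DetectorConfig())
        p1 = detect_dsr_pass1(s, DetectorConfig(), turn)
        assert detect_dsr_pass2(turn, s, p1, DetectorConfig()) == []

    def test_long_stretch_with_internal_jump_gets_pass2_boundary(self):
        # 13 words, one huge pass-1 jump at the last word; the remaining
        # 12-word, ~3.7 s prefix stretch holds a modest jump at word 6
        slow, fast, very_fast = [0.105] * 3, [0.085] * 3, [0.04] * 3
        turn = chain(
            [slow, slow, slow, slow, slow, slow, fast, slow, slow, slow, slow, slow, very_fast]
        )
        cfg = DetectorConfig()
        s = compute_speech_rate(turn, cfg)
        p1 = detect_dsr_pass1(s, cfg, turn)
        assert {b.word_index for b in p1} == {12}
        p2 = detect_dsr_pass2(turn, s, p1, cfg)
        assert [b.source for b in p2] == ["dsr_pass2"]
        assert {b.word_index for b in p2} == {6}

    def test_pass2_never_duplicates_pass1(self):
        rng = np.random.default_rng(14)
        cfg = DetectorConfig()
        for _ in range(300):
            turn = make_random_turn(rng, max_words=16)
            if all(not w.phones for w in turn.words):
                continue
            s = compute_speech_rate(turn, cfg)
            p1 = detect_dsr_pass1(s, cfg, turn)
            p2 = detect_dsr_pass2(turn, s, p1, cfg)
            assert {b.word_index for b in p1} & {b.word_index for b in p2} == set()


class TestPauses:
    def test_threshold_is_strict(self):
        turn = chain([[0.1, 0.1], [0.1, 0.1]], gaps=[0.300])
        assert detect_pause_boundaries(turn, DetectorConfig()) == []
        turn = chain([[0.1, 0.1], [0.1, 0.1]], gaps=[0.301])
        bounds = detect_pause_boundaries(turn, DetectorConfig())
        assert [(b.word_index, b.source) for b in bounds] == [(1, "pause")]

    def test_use_pauses_off(self):
        turn = chain([[0.1, 0.1], [0.1, 0.1]], gaps=[0.9])
        assert detect_pause_boundaries(turn, DetectorConfig(use_pauses=False)) == []


class TestMergeAndSegment:
    def test_dsr_wins_over_pause_at_same_word(self):
        dsr = [Boundary(1.0, 3, "dsr_pass1")]
        pause = [Boundary(1.0, 3, "pause")]
        merged = merge_boundaries(dsr, pause)
        assert [(b.word_index, b.source) for b in merged] == [(3, "dsr_pass1")]

    def test_disjoint_union_sorted(self):
        merged = merge_boundaries(
            [Boundary(2.0, 4, "dsr_pass1")], [Boundary(1.0, 2, "pause")]
        )
        assert [b.word_index for b in merged] == [2, 4]

    def test_empty_inputs(self):
        assert merge_boundaries([], []) == []

    def test_segmentation_partitions_words(self):
        turn = chain([[0.1, 0.1]] * 6)
        bounds = [
            Boundary(turn.words[2].start, 2, "dsr_pass1"),
            Boundary(turn.words[4].start, 4, "pause"),
        ]
        phrases = segment_turn(turn, bounds)
        assert [p.n_words for p in phrases] == [2, 2, 2]
        assert phrases[0].end == turn.words[1].end
        assert phrases[-1].end == turn.end

    def test_no_boundaries_single_phrase(self):
        turn = chain([[0.1, 0.1]] * 4)
        phrases = segment_turn(turn, [])
        assert len(phrases) == 1
        assert phrases[0].n_words == 4

    def test_boundary_off_word_onset_rejected(self):
        turn = chain([[0.1, 0.1]] * 4)
        with pytest.raises(DetectorError, match="not a word onset"):
            segment_turn(turn, [Boundary(0.123, 2, "pause")])

    def test_phrase_end_before_next_start_when_pause(self):
        corpus = generate_corpus(SynthConfig(seed=21, n_files=1, turns_per_file=10))
        results = detect(corpus.turns)
        for res in results.values():
            for a, b in zip(res.phrases, res.phrases[1:]):
                assert a.end <= b.start + 1e-9


class TestDetect:
    def test_deterministic_json(self, default_corpus):
        turns = default_corpus.turns[:10]
        j1 = phrases_to_json(detect(turns))
        j2 = phrases_to_json(detect(turns))
        assert j1 == j2

    def test_short_turn_excluded_as_single_phrase(self):
        turn = chain([[0.1, 0.1]])
        res = detect_turn(turn, DetectorConfig())
        assert res.excluded
        assert len(res.phrases) == 1
        assert res.boundaries == []

    def test_all_unk_turn_warned_and_excluded(self):
        turn = Turn(
            "t", "A", (WordToken("<unk>", 0.0, 0.3), WordToken("<unk>", 0.4, 0.9))
        )
        res = detect_turn(turn, DetectorConfig())
        assert res.excluded
        assert "no phone timings" in res.warning

    def test_no_pauses_boundaries_subset_of_full_run(self, default_corpus):
        turns = default_corpus.turns[:40]
        full = detect(turns, DetectorConfig())
        nopause = detect(turns, DetectorConfig(use_pauses=False))
        for key in full:
            full_dsr = {
                b.word_index
                for b in full[key].boundaries
                if b.source.startswith("dsr")
            }
            np_set = {b.word_index for b in nopause[key].boundaries}
            assert np_set == full_dsr

    def test_no_boundary_inside_a_word(self, default_corpus):
        results = detect(default_corpus.turns[:60])
        for res in results.values():
            onsets = {w.start for w in res.turn.words}
            for b in res.boundaries:
                assert b.time in onsets
                for w in res.turn.words:
                    assert not (w.start < b.time < w.end)
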