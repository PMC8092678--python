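"""Evaluation: slot matching, metrics, chi-square, sweep, finality."""

import numpy as np
import pytest
from scipy import stats as sps

from prososeg.alignment_io import ReferencePhrase, ReferenceSegmentation
from prososeg.detector import DetectorConfig, detect
from prososeg.evaluation import (
    ConfusionCounts,
    EvaluationError,
    align_boundaries,
    chi_square_independence,
    compute_metrics,
    finality_recall,
    pause_threshold_sweep,
)
from prososeg.synth import SynthConfig, generate_corpus

# Published genre contrast table: observed counts, rows TP/TN/FP/FN
# by conversational / audience-oriented files.
GENRE_OBSERVED = np.array(
    [
        [16171, 4973],
        [100664, 29560],
        [13050, 2797],
        [12884, 3090],
    ]
)
GENRE_EXPECTED_PRINTED = np.array(
    [
        [16479, 4665],
        [101491, 28733],
        [12350, 3497],
        [12449, 3525],
    ]
)


def ref_from_corpus(corpus):
    return corpus.reference


class TestAlignBoundaries:
    def test_identical_sets_are_perfect(self, default_corpus):
        results = detect(default_corpus.turns)
        # reference = the detector's own boundaries
        phrases = []
        for res in results.values():
            for p in res.phrases:
                phrases.append(
                    ReferencePhrase(
                        res.turn.file_id, res.turn.speaker, p.start, p.end
                    )
                )
        ref = ReferenceSegmentation(phrases)
        m = compute_metrics(align_boundaries(results, ref))
        assert m.precision == m.recall == m.f_score == m.accuracy == 1.0
        assert m.kappa == 1.0

    def test_empty_auto_counts_all_ref_as_misses(self, default_corpus):
        results = detect(
            default_corpus.turns, DetectorConfig(use_pauses=False, dsr_threshold_frac=1.0)
        )
        # dsr_threshold_frac=1.0 still flags nothing only if no diff exceeds
        # the max itself; strip boundaries manually instead
        for res in results.values():
            res.boundaries.clear()
        ref = ref_from_corpus(default_corpus)
        c = align_boundaries(results, ref)
        assert c.tp == 0 and c.fp == 0
        assert c.fn == len(default_corpus.truth)

    def test_counts_match_per_slot_oracle(self):
        # random auto/ref labels over 500 discrete slots, spacing far above
        # tolerance: greedy matching must equal per-slot label comparison
        rng = np.random.default_rng(17)
        slot_times = np.arange(500) * 1.0
        auto_lab = rng.random(500) < 0.3
        ref_lab = rng.random(500) < 0.3
        from prososeg.evaluation import _greedy_match

        pairs = _greedy_match(
            slot_times[auto_lab].tolist(), slot_times[ref_lab].tolist(), 0.05
        )
        tp = len(pairs)
        fp = int(auto_lab.sum()) - tp
        fn = int(ref_lab.sum()) - tp
        tn = 500 - tp - fp - fn
        assert tp == int((auto_lab & ref_lab).sum())
        assert fp == int((auto_lab & ~ref_lab).sum())
        assert fn == int((~auto_lab & ref_lab).sum())
        assert tn == int((~auto_lab & ~ref_lab).sum())

    def test_negative_tolerance_rejected(self, default_corpus):
        with pytest.raises(EvaluationError):
            align_boundaries(
                detect(default_corpus.turns[:2]),
                ref_from_corpus(default_corpus),
                tolerance_s=-0.01,
            )

    def test_permutation_invariance(self, default_corpus):
        results = detect(default_corpus.turns[:50])
        ref = ref_from_corpus(default_corpus)
        c1 = align_boundaries(results, ref)
        shuffled = dict(reversed(list(results.items())))
        c2 = align_boundaries(shuffled, ref)
        assert vars(c1) == vars(c2)


class TestComputeMetrics:
    def test_published_totals_accuracy(self):
        c = ConfusionCounts(tp=21144, fp=15847, fn=15974, tn=130224)
        m = compute_metrics(c)
        assert m.accuracy == pytest.approx(0.8263, abs=1e-3)
        assert m.precision == pytest.approx(21144 / (21144 + 15847))
        assert m.recall == pytest.approx(21144 / (21144 + 15974))

    def test_kappa_perfect_agreement(self):
        assert compute_metrics(ConfusionCounts(50, 0, 0, 450)).kappa == pytest.approx(1.0)

    def test_kappa_near_zero_for_independent_labels(self):
        rng = np.random.default_rng(7)
        a = rng.random(10_000) < 0.25
        r = rng.random(10_000) < 0.25
        c = ConfusionCounts(
            tp=int((a & r).sum()),
            fp=int((a & ~r).sum()),
            fn=int((~a & r).sum()),
            tn=int((~a & ~r).sum()),
        )
        assert abs(compute_metrics(c).kappa) < 0.05

    def test_all_zero_counts_error(self):
        with pytest.raises(EvaluationError):
            compute_metrics(ConfusionCounts())


class TestChiSquare:
    def test_genre_table_exact_statistic_vs_scipy(self):
        res = chi_square_independence(GENRE_OBSERVED)
        chi2, p, dof, exp = sps.chi2_contingency(GENRE_OBSERVED, correction=False)
        assert res.chi2 == pytest.approx(chi2, rel=1e-12)
        assert res.df == dof == 3
        np.testing.assert_allclose(res.expected, exp, rtol=1e-12)

    def test_genre_table_published_statistic_from_printed_expecteds(self):
        # the published value 305.31 reproduces only when the statistic is
        # computed against the rounded expected counts as printed
        res = chi_square_independence(GENRE_OBSERVED, round_expected=True)
        assert res.chi2 == pytest.approx(305.31, abs=0.02)

    def test_expected_counts_match_printed_table(self):
        res = chi_square_independence(GENRE_OBSERVED)
        np.testing.assert_allclose(res.expected, GENRE_EXPECTED_PRINTED, atol=0.5)
        # marginals preserved
        np.testing.assert_allclose(
            res.expected.sum(axis=0), GENRE_OBSERVED.sum(axis=0), atol=1e-6
        )
        np.testing.assert_allclose(
            res.expected.sum(axis=1), GENRE_OBSERVED.sum(axis=1), atol=1e-6
        )

    def test_uniform_table_is_zero(self):
        assert chi_square_independence([[5, 5], [5, 5]]).chi2 == 0.0

    def test_random_tables_match_scipy(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            obs = rng.integers(1, 200, size=(3, 3))
            res = chi_square_independence(obs)
            chi2, _, dof, _ = sps.chi2_contingency(obs, correction=False)
            assert res.chi2 == pytest.approx(chi2, rel=1e-10)
            assert res.df == dof

    def test_yates_matches_scipy_2x2(self):
        rng = np.random.default_rng(29)
        for _ in range(25):
            obs = rng.integers(5, 100, size=(2, 2))
            res = chi_square_independence(obs, yates=True)
            chi2, _, _, _ = sps.chi2_contingency(obs, correction=True)
            assert res.chi2 == pytest.approx(chi2, rel=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(EvaluationError):
            chi_square_independence([[0, 0], [3, 4]])


@pytest.fixture(scope="module")
def pause_fixture():
    # every true boundary marked by an exactly 350 ms pause
    cfg = SynthConfig(
        seed=31,
        n_files=3,
        turns_per_file=20,
        pause_prob=1.0,
        pause_mean_s=0.35,
        pause_std_s=0.0,
    )
    return generate_corpus(cfg)


class TestSweep:
    def test_precision_peaks_below_the_pause_duration(self, pause_fixture):
        corpus = pause_fixture
        res = pause_threshold_sweep(
            corpus.turns, corpus.reference, [0.200, 0.300, 0.500]
        )
        # thresholds below 350 ms keep the (always correct) pause cue alive
        assert res.precision_mean[0] >= res.precision_mean[2]
        assert res.precision_mean[1] >= res.precision_mean[2]

    def test_single_value_grid_equals_full_run(self, pause_fixture):
        corpus = pause_fixture
        res = pause_threshold_sweep(corpus.turns, corpus.reference, [0.300])
        from prososeg.evaluation import _per_file_precision

        vals = _per_file_precision(
            corpus.turns, corpus.reference, DetectorConfig(min_pause_s=0.300), 0.05
        )
        assert res.precision_mean[0] == pytest.approx(float(np.mean(vals)))

    def test_infinite_threshold_equals_pauses_off(self, default_corpus):
        corpus = default_corpus
        res = pause_threshold_sweep(
            corpus.turns[:60], corpus.reference, [1e9]
        )
        assert res.precision_mean[0] == pytest.approx(res.no_pause_precision_mean)

    def test_empty_grid_rejected(self, default_corpus):
        with pytest.raises(EvaluationError):
            pause_threshold_sweep(default_corpus.turns, default_corpus.reference, [])


class TestFinality:
    def test_final_units_better_recalled_with_finality_effect(self):
        cfg = SynthConfig(
            seed=37,
            n_files=4,
            turns_per_file=40,
            finality_effect=1.35,
            pause_prob=0.2,
        )
        corpus = generate_corpus(cfg)
        results = detect(corpus.turns)
        fr = finality_recall(results, corpus.reference)
        assert fr.recall_final > fr.recall_non_final
        assert fr.chi2.df == 1 and fr.chi2.yates

    def test_no_labels_is_an_error(self, default_corpus):
        ref = ReferenceSegmentation(
            [
                ReferencePhrase(p.file_id, p.speaker, p.start, p.end, "unknown")
                for p in default_corpus.reference.phrases
            ]
        )
        results = detect(default_corpus.turns[:20])
        with pytest.raises(EvaluationError, match="finality"):
            finality_recall(results, ref)

    def test_all_final_is_an_error_path(self, default_corpus):
        ref = ReferenceSegmentation(
            [
                ReferencePhrase(p.file_id, p.speaker, p.start, p.end, "final")
                for p in default_corpus.reference.phrases
            ]
        )
        results = detect(default_corpus.turns[:20])
        with pytest.raises(EvaluationError, match="both final and non-final"):
            finality_recall(results, ref)

    def test_hand_built_table_consistent_with_chi_square(self):
        table = np.array([[694, 306], [513, 487]])
        res = chi_square_independence(table, yates=True)
        chi2, _, dof, _ = sps.chi2_contingency(table, correction=True)
        assert res.chi2 == pytest.approx(chi2)
        assert dof == 1
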