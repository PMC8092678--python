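import sys
from pathlib import Path

import numpy as np
import pytest

from prososeg.alignment_io import PhoneInterval, Turn, WordToken
from prososeg.synth import SynthConfig, generate_corpus

sys.path.insert(0, str(Path(__file__).parent))  # for reference_impl


def make_random_turn(
    rng: np.random.Generator,
    turn_id: str = "t0",
    min_words: int = 2,
    max_words: int = 16,
    unk_prob: float = 0.05,
    pause_prob: float = 0.25,
) -> Turn:
    """A random small turn: variable word/phone durations, occasional
    phone-less words and inter-word gaps (some beyond the pause threshold)."""
    n_words = int(rng.integers(min_words, max_words + 1))
    t = float(rng.uniform(0.0, 2.0))
    words = []
    for i in range(n_words):
        dur = float(rng.uniform(0.08, 0.55))
        if rng.random() < unk_prob:
            words.append(WordToken("<unk>", round(t, 4), round(t + dur, 4)))
        else:
            n_ph = int(rng.integers(1, 6))
            w = rng.uniform(0.5, 1.5, size=n_ph)
            pdur = dur * w / w.sum()
            bounds = [round(t + x, 4) for x in np.concatenate([[0.0], np.cumsum(pdur)])]
            phones = tuple(
                PhoneInterval("P", a, b) for a, b in zip(bounds[:-1], bounds[1:])
            )
            words.append(WordToken(f"w{i}", bounds[0], bounds[-1], phones))
        t = words[-1].end
        if i < n_words - 1 and rng.random() < pause_prob:
            t += float(rng.uniform(0.05, 0.8))
    return Turn(turn_id, "S", tuple(words), file_id="rand")


@pytest.fixture(scope="session")
def default_corpus():
    """The clean default synthetic corpus, seed 1."""
    return generate_corpus(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def pitch_corpus():
    """Corpus used for pitch parameter recovery (decline 0.15, seed 3)."""
    return generate_corpus(SynthConfig(seed=3))
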