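"""Test conditions, key readout and trajectory measures.

The trained network is probed with three fixed sets of five short tone
sequences, all of which Western listeners would hear in C major:

* ``in_scale_regular`` — C-major scale tones arranged as three consecutive
  triad arpeggios outlining a regular harmonic progression (I-V-I or I-IV-I);
* ``in_scale_irregular`` — C-major scale tones ordered so that no three
  consecutive tones outline any major or minor triad (no clear implied
  harmony);
* ``out_of_scale_irregular`` — sequences containing chromatic tones outside
  the C-major scale and no regular progression.

A sequence is scored correct when the C-major output unit carries the
largest raw activation. Contrasting the first two conditions isolates
sensitivity to implied harmony; contrasting them with the third isolates
sensitivity to scale membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import Corpus, EmptyCorpusError, KeyLabel, MAJOR_SCALE, Melody, Mode
from .encoding import active_indices, decode_key
from .network import Checkpoint, NetworkState, forward_indices

logger = logging.getLogger(__name__)

C_MAJOR = KeyLabel(0, Mode.MAJOR)

#: C-major pitch-class set
_C_SCALE = frozenset(MAJOR_SCALE)

#: triads of C major used when screening for outlined harmony
_MAJOR_TRIADS = [frozenset({r, (r + 4) % 12, (r + 7) % 12}) for r in range(12)]
_MINOR_TRIADS = [frozenset({r, (r + 3) % 12, (r + 7) % 12}) for r in range(12)]
_ALL_TRIADS = _MAJOR_TRIADS + _MINOR_TRIADS

_TONIC = frozenset({0, 4, 7})
_DOMINANT = frozenset({7, 11, 2})
_SUBDOMINANT = frozenset({5, 9, 0})


class TestCondition(str, Enum):
    IN_SCALE_REGULAR = "in_scale_regular"
    IN_SCALE_IRREGULAR = "in_scale_irregular"
    OUT_OF_SCALE_IRREGULAR = "out_of_scale_irregular"


# Nine-tone fixtures (three 3-tone groups); lengths are matched across
# conditions so that sequence length cannot confound the contrasts.
_REGULAR_FIXTURES = (
    (0, 4, 7, 7, 11, 2, 0, 4, 7),   # I-V-I, root-position ascending arpeggios
    (0, 4, 7, 5, 9, 0, 0, 4, 7),    # I-IV-I, ascending
    (0, 7, 4, 2, 7, 11, 4, 0, 7),   # I-V-I, varied contour
    (0, 4, 7, 0, 9, 5, 7, 4, 0),    # I-IV-I, descending close
    (4, 0, 7, 11, 2, 7, 0, 4, 7),   # I-V-I, opening on the mediant
)

# Scalar, non-triadic sequences. Opening tones exactly mirror the regular
# set's (four tonic openings, one mediant), and most close on the tonic, so
# the regular/irregular contrast isolates triad grouping — the implied
# harmony — rather than the opening tone; no 3-tone window forms any major
# or minor triad, so no regular progression is implied.
_IRREGULAR_FIXTURES = (
    (0, 2, 4, 5, 7, 9, 11, 2, 0),   # stepwise ascent and turn
    (4, 5, 9, 11, 0, 2, 5, 7, 0),   # mediant opening
    (0, 2, 7, 9, 4, 2, 11, 2, 0),   # tonic-anchored meander
    (0, 11, 9, 7, 5, 4, 2, 0, 2),   # descending scale from the tonic
    (0, 9, 7, 2, 4, 11, 5, 2, 0),   # arch contour
)

_OUT_OF_SCALE_FIXTURES = (
    (0, 1, 6, 8, 3, 10, 6, 1, 0),
    (1, 3, 6, 8, 10, 1, 3, 6, 8),
    (0, 6, 1, 10, 4, 8, 3, 6, 1),
    (8, 10, 1, 3, 6, 8, 10, 1, 8),
    (4, 1, 8, 6, 11, 3, 10, 8, 6),
)


@dataclass(frozen=True)
class TestSet:
    condition: TestCondition
    sequences: tuple[Melody, ...]
    correct_key: KeyLabel = C_MAJOR


def _outlines_triad(window: Sequence[int]) -> bool:
    return frozenset(window) in _ALL_TRIADS


def _check_fixture(condition: TestCondition, chromas: Sequence[int]) -> None:
    in_scale = all(c in _C_SCALE for c in chromas)
    if condition is TestCondition.OUT_OF_SCALE_IRREGULAR:
        if in_scale:
            raise AssertionError("out-of-scale fixture contains only scale tones")
        return
    if not in_scale:
        raise AssertionError("in-scale fixture contains an out-of-scale tone")
    groups = [chromas[i : i + 3] for i in range(0, len(chromas) - 2, 3)]
    if condition is TestCondition.IN_SCALE_REGULAR:
        sets = [frozenset(g) for g in groups]
        ok = sets[0] == _TONIC and sets[-1] == _TONIC and sets[1] in (_DOMINANT, _SUBDOMINANT)
        if not ok:
            raise AssertionError("regular fixture does not outline I-V-I or I-IV-I")
    else:
        for i in range(len(chromas) - 2):
            if _outlines_triad(chromas[i : i + 3]):
                raise AssertionError(
                    f"irregular fixture outlines a triad at positions {i}..{i+2}"
                )


def build_test_sets() -> tuple[TestSet, TestSet, TestSet]:
    """The three deterministic five-sequence test sets (correct key: C major)."""
    plan = (
        (TestCondition.IN_SCALE_REGULAR, _REGULAR_FIXTURES),
        (TestCondition.IN_SCALE_IRREGULAR, _IRREGULAR_FIXTURES),
        (TestCondition.OUT_OF_SCALE_IRREGULAR, _OUT_OF_SCALE_FIXTURES),
    )
    sets = []
    for condition, fixtures in plan:
        melodies = []
        for i, chromas in enumerate(fixtures):
            _check_fixture(condition, chromas)
            melodies.append(Melody(f"{condition.value}-{i}", chromas, C_MAJOR))
        sets.append(TestSet(condition, tuple(melodies)))
    return tuple(sets)


def generate_condition_sequence(
    condition: TestCondition, rng: np.random.Generator, length: int = 9
) -> Melody:
    """Sample an additional sequence conforming to a condition's criteria."""
    condition = TestCondition(condition)
    if condition is TestCondition.IN_SCALE_REGULAR:
        if length % 3 != 0:
            raise ValueError("regular-harmony sequences need a multiple of 3 tones")
        middle = _DOMINANT if rng.random() < 0.5 else _SUBDOMINANT
        groups = [_TONIC] + [middle] * (length // 3 - 2) + [_TONIC]
        chromas = [int(c) for g in groups for c in rng.permutation(sorted(g))]
    elif condition is TestCondition.IN_SCALE_IRREGULAR:
        scale = sorted(_C_SCALE)
        while True:
            chromas = [int(c) for c in rng.choice(scale, size=length)]
            windows = [chromas[i : i + 3] for i in range(length - 2)]
            if not any(_outlines_triad(w) for w in windows):
                break
    else:
        accidentals = sorted(set(range(12)) - _C_SCALE)
        while True:
            chromas = [int(c) for c in rng.choice(12, size=length)]
            if any(c in accidentals for c in chromas):
                break
    _check_fixture(condition, chromas)
    return Melody(f"{condition.value}-gen", tuple(chromas), C_MAJOR)


# ---------------------------------------------------------------------------
# Readout and measures
# ---------------------------------------------------------------------------

def identify_key(state: NetworkState, melody: Melody) -> KeyLabel:
    """Key of the output unit with the largest raw activation (argmax readout).

    Exact ties are broken toward the lowest unit index, with a warning.
    """
    outputs = forward_indices(state, active_indices(melody))
    winner = int(np.argmax(outputs))
    if np.count_nonzero(outputs == outputs[winner]) > 1:
        logger.warning(
            "tie among output units for melody %s; choosing lowest index %d",
            melody.id, winner,
        )
    return decode_key(winner)


def percent_correct(state: NetworkState, test_set: TestSet) -> float:
    """Percentage of the set's sequences identified as the correct key."""
    hits = sum(
        identify_key(state, m) == test_set.correct_key for m in test_set.sequences
    )
    return 100.0 * hits / len(test_set.sequences)


def normalized_correct_key_activation(state: NetworkState, test_set: TestSet) -> float:
    """Mean correct-key output, linearly rescaled from (-1, 1) to (0, 1)."""
    k = test_set.correct_key.index
    acts = [
        forward_indices(state, active_indices(m))[k] for m in test_set.sequences
    ]
    return float(np.mean([(a + 1.0) / 2.0 for a in acts]))


def agreement_rate(state: NetworkState, corpus: Corpus) -> float:
    """Percent of corpus melodies whose argmax key matches the teacher key."""
    if len(corpus) == 0:
        raise EmptyCorpusError("agreement rate needs a non-empty corpus")
    hits = 0
    for m in corpus:
        outputs = forward_indices(state, active_indices(m))
        hits += int(np.argmax(outputs)) == m.key.index
    return 100.0 * hits / len(corpus)


@dataclass(frozen=True)
class TrajectoryRecord:
    """Performance of one run at one checkpoint under one condition."""

    run_id: int
    epoch: int
    condition: TestCondition
    percent_correct: float
    mean_correct_key_activation: float


def evaluate_trajectory(
    checkpoints: Iterable[Checkpoint],
    test_sets: Sequence[TestSet],
    run_id: int = 0,
) -> list[TrajectoryRecord]:
    """One record per checkpoint x condition, sorted by (epoch, condition).

    Purely read-only: no parameter is touched.
    """
    order = {c: i for i, c in enumerate(TestCondition)}
    records = []
    for cp in checkpoints:
        for ts in test_sets:
            records.append(
                TrajectoryRecord(
                    run_id=run_id,
                    epoch=cp.epoch,
                    condition=ts.condition,
                    percent_correct=percent_correct(cp.state, ts),
                    mean_correct_key_activation=normalized_correct_key_activation(
                        cp.state, ts
                    ),
                )
            )
    records.sort(key=lambda r: (r.epoch, order[r.condition]))
    return records


def agreement_trajectory(
    checkpoints: Iterable[Checkpoint], corpus: Corpus
) -> dict[int, float]:
    """Training agreement rate (%) at each checkpoint epoch."""
    return {cp.epoch: agreement_rate(cp.state, corpus) for cp in checkpoints}


def records_to_frame(records: Iterable[TrajectoryRecord]) -> pd.DataFrame:
    """Tidy DataFrame with columns run_id, epoch, condition, percent_correct,
    mean_correct_key_activation."""
    return pd.DataFrame(
        {
            "run_id": r.run_id,
            "epoch": r.epoch,
            "condition": r.condition.value,
            "percent_correct": r.percent_correct,
            "mean_correct_key_activation": r.mean_correct_key_activation,
        }
        for r in records
    )
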