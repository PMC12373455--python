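import numpy as np
import pytest

from qreuse import (
    QuestionDataset,
    QuestionRecord,
    TrialArray,
    canonical_arrays,
    parse,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def arrays14():
    """One seeded trial array per canonical hidden-feature pattern."""
    return canonical_arrays(0)


@pytest.fixture
def purple_head_hidden():
    """Everything revealed except the purple monster's head."""
    return TrialArray(
        "purple-head",
        {
            "Blue": {"head": "Square", "legs": 3},
            "Red": {"head": "Circle", "legs": 2},
            "Purple": {"head": None, "legs": 1},
        },
    )


@pytest.fixture
def blue_legs_hidden():
    """Red has two legs, purple one leg; only the blue monster's legs hidden."""
    return TrialArray(
        "blue-legs",
        {
            "Blue": {"head": "Square", "legs": None},
            "Red": {"head": "Circle", "legs": 2},
            "Purple": {"head": "Circle", "legs": 1},
        },
    )


def make_dataset(questions_by_participant, arrays=None, array_cycle=None, **conditions):
    """Build a QuestionDataset from {participant: [program strings]}.

    ``array_cycle`` assigns array ids per trial index (defaults to distinct
    ids a0, a1, ... shared across participants).
    """
    records = []
    for pid, progs in questions_by_participant.items():
        for t, text in enumerate(progs):
            aid = array_cycle[t % len(array_cycle)] if array_cycle else f"a{t}"
            records.append(
                QuestionRecord(
                    participant_id=pid,
                    trial_index=t,
                    array_id=aid,
                    program=parse(text),
                    **{k: (v(pid) if callable(v) else v) for k, v in conditions.items()},
                )
            )
    return QuestionDataset(records=records, arrays=arrays or {})


@pytest.fixture
def make_ds():
    return make_dataset
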