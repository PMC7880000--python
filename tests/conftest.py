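import numpy as np
import pandas as pd
import pytest

from eventdep.design import DIRECTIONS


def trials_from_matrix(correct, participant_id="p1", age_group="adult",
                       condition="simultaneous"):
    """Build a retrieval-trial DataFrame from an events x 6 correctness
    matrix (columns ordered as DIRECTIONS); NaN entries become missing."""
    correct = np.asarray(correct, dtype=float)
    rows = []
    for e in range(correct.shape[0]):
        for d, (cue, target) in enumerate(DIRECTIONS):
            rows.append(
                {
                    "participant_id": participant_id,
                    "age_group": age_group,
                    "condition": condition,
                    "phase": "retrieval",
                    "event_id": e + 1,
                    "cue_role": cue,
                    "target_role": target,
                    "set_index": 1 if d % 2 == 0 else 2,
                    "block_index": 1 + d % 3,
                    "within_block_position": e + 1,
                    "correct": correct[e, d],
                    "attended": np.nan,
                }
            )
    return pd.DataFrame(rows)


def encoding_rows(event_ids, attended=None, participant_id="p1",
                  age_group="adult", condition="simultaneous"):
    """Simultaneous-style encoding rows, one per event, with attention flags."""
    if attended is None:
        attended = [1.0] * len(event_ids)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "age_group": age_group,
            "condition": condition,
            "phase": "encoding",
            "event_id": list(event_ids),
            "cue_role": None,
            "target_role": None,
            "set_index": np.nan,
            "block_index": 1,
            "within_block_position": range(1, len(event_ids) + 1),
            "correct": np.nan,
            "attended": list(attended),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
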