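import numpy as np
import pandas as pd
import pytest

from songboot.pitch import PitchDataset, Timeline


def make_dataset(rows, timeline=None, group_label="test"):
    """Build a PitchDataset from (bird, syllable, epoch, day, pitch_hz) tuples."""
    df = pd.DataFrame(rows, columns=["bird_id", "syllable_id", "epoch", "day", "pitch_hz"])
    df = df[["bird_id", "syllable_id", "day", "epoch", "pitch_hz"]]
    return PitchDataset(df, timeline or Timeline(), group_label)


def flat_syllable(bird, syll, epoch_days, hz, n=5):
    """Rows for one syllable at a constant pitch over (epoch, day) pairs."""
    return [
        (bird, syll, epoch, day, hz) for epoch, day in epoch_days for _ in range(n)
    ]


@pytest.fixture
def constant_dataset():
    """One bird, one syllable, every record at the 1000 Hz baseline."""
    rows = []
    for epoch, n_days in (("baseline", 3), ("shift", 14), ("washout", 7)):
        rows += flat_syllable("b0", "s0", [(epoch, d) for d in range(1, n_days + 1)], 1000.0)
    return make_dataset(rows)
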