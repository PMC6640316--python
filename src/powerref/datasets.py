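"""Small bundled example datasets used in the documentation and tests.

Both are classic textbook-scale toy datasets: a 10-participant primed
word-recognition experiment (mean reaction times under related and
unrelated primes) and a 6-participant reliability example with four
repeated responses to the same stimulus.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["priming_example", "repeated_measures_example",
           "repeated_measures_example_long"]

_PRIMING = {
    "Participant": [f"p{i}" for i in range(1, 11)],
    "Related": [638, 701, 597, 640, 756, 589, 635, 678, 659, 597],
    "Unrelated": [654, 751, 623, 641, 760, 613, 665, 701, 668, 584],
}

_REPEATED = np.array([
    [7, 5, 10, 6],
    [9, 11, 8, 10],
    [12, 9, 17, 14],
    [11, 8, 6, 18],
    [7, 3, 3, 6],
    [10, 14, 7, 14],
], dtype=float)


def priming_example() -> pd.DataFrame:
    """Reaction times (ms) of 10 participants to target words preceded by
    related vs. unrelated primes; the Priming column is their difference.

    Almost every participant responds faster after a related prime, so the
    difference scores are far more stable (SD 17.7) than the raw times
    (SDs ~52-57), which is why dz (.96) dwarfs dav (.31) here.
    """
    df = pd.DataFrame(_PRIMING)
    df["Priming"] = df["Unrelated"] - df["Related"]
    return df


def repeated_measures_example() -> pd.DataFrame:
    """Responses of six participants (P1-P6) to four repetitions of the
    same stimulus (S1-S4), in wide format."""
    return pd.DataFrame(_REPEATED, columns=["S1", "S2", "S3", "S4"],
                        index=[f"P{i}" for i in range(1, 7)])


def repeated_measures_example_long() -> pd.DataFrame:
    """The same 6 x 4 reliability example in long notation with columns
    Participant, Condition, Response (one row per observation)."""
    wide = repeated_measures_example()
    long = wide.reset_index(names="Participant").melt(
        id_vars="Participant", var_name="Condition", value_name="Response")
    return long.sort_values(["Participant", "Condition"],
                            ignore_index=True)
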