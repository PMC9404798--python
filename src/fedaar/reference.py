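"""Bookkeeping for the public six-horse neck-IMU activity benchmark.

The benchmark this package's protocol defaults were designed around consists
of two-second accelerometer/gyroscope windows sampled at 100 Hz from six
horses, labelled with six activities.  The per-subject, per-activity window
counts are embedded here so sanity checks and sizing arithmetic work without
downloading the data; the package never reads the real recordings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SUBJECTS",
    "ACTIVITIES",
    "window_counts",
    "subject_totals",
    "activity_totals",
    "grand_total",
]

SUBJECTS = ("Happy", "Zafir", "Driekus", "Galoway", "Patron", "Bacardi")
ACTIVITIES = (
    "eating",
    "galloping",
    "standing",
    "trotting",
    "walking-natural",
    "walking-rider",
)

_COUNTS = np.array(
    [
        [5063, 696, 1186, 7038, 746, 8896],
        [1091, 835, 347, 3559, 161, 5078],
        [2496, 323, 341, 2673, 270, 4024],
        [4331, 1043, 1750, 6423, 1402, 9653],
        [1951, 714, 1244, 3402, 388, 5150],
        [1116, 328, 245, 1981, 360, 1317],
    ],
    dtype=np.int64,
)


def window_counts() -> pd.DataFrame:
    """Window counts as a subjects x activities DataFrame."""
    return pd.DataFrame(_COUNTS.copy(), index=list(SUBJECTS), columns=list(ACTIVITIES))


def subject_totals() -> dict[str, int]:
    """Total window count per subject, summed over activities."""
    return {s: int(n) for s, n in zip(SUBJECTS, _COUNTS.sum(axis=1))}


def activity_totals() -> dict[str, int]:
    """Total window count per activity, summed over subjects."""
    return {a: int(n) for a, n in zip(ACTIVITIES, _COUNTS.sum(axis=0))}


def grand_total() -> int:
    """Total number of windows in the benchmark."""
    return int(_COUNTS.sum())
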