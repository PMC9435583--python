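"""Reference bookkeeping of the emulated clinical MEG cohort.

The synthetic generator emulates a published resting-state MEG cohort of
16 CPS and 16 SPS subjects whose per-subject 4-s segment yields were
strongly unbalanced.  The printed per-subject counts and the reported
fold-wise validation accuracies are kept here as reference inputs: the
counts drive the simulator's default yield heterogeneity and the
subset-pairing logic, and the aggregation helpers reproduce the reported
totals and accuracy summaries.

Subject identifiers are as printed in the source tables (identifiers may
recur across the train/test split and across groups; they label rows, not
unique persons here).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CPS_TRAINING_COUNTS",
    "CPS_TEST_COUNTS",
    "SPS_TRAINING_COUNTS",
    "SPS_TEST_COUNTS",
    "SUBSET_LOO_ACCURACIES",
    "RANDOM_SPLIT_ACCURACIES",
    "segment_count_totals",
    "summarize_fold_accuracies",
]

# (subject label, number of 4-s segments) per training subset, in subset order
CPS_TRAINING_COUNTS = (
    ("Su12", 102), ("Su01", 73), ("Su03", 78), ("Su05", 81), ("Su17", 33),
    ("Su10", 34), ("Su18", 37), ("Su09", 40), ("Su07", 72), ("Su14", 84),
    ("Su08", 117), ("Su04", 125), ("Su16", 144), ("Su15", 169),
)
CPS_TEST_COUNTS = (("Su02", 75), ("Su04", 42))

SPS_TRAINING_COUNTS = (
    ("Su11", 105), ("Su16", 77), ("Su32", 123), ("Su33", 146), ("Su14", 51),
    ("Su22", 57), ("Su09", 58), ("Su18", 59), ("Su15", 64), ("Su12", 89),
    ("Su07", 117), ("Su23", 148), ("Su03", 150), ("Su06", 168),
)
SPS_TEST_COUNTS = (("Su24", 34), ("Su31", 80))

# Fold-wise validation accuracies (%) of the two reported schemes
SUBSET_LOO_ACCURACIES = (88.73, 76.55, 81.28, 74.44, 85.06, 81.02, 83.58,
                         76.32, 88.29, 80.56, 75.13, 77.85, 72.39, 76.98)
RANDOM_SPLIT_ACCURACIES = (83.25, 81.94, 79.27, 78.55, 87.21, 84.35, 81.13,
                           84.57, 86.88, 82.46, 86.12, 81.97, 82.48, 84.59)


def segment_count_totals() -> dict:
    """Group-wise segment totals and test-set sizes from the reference counts."""
    cps_train = sum(c for _, c in CPS_TRAINING_COUNTS)
    cps_test = sum(c for _, c in CPS_TEST_COUNTS)
    sps_train = sum(c for _, c in SPS_TRAINING_COUNTS)
    sps_test = sum(c for _, c in SPS_TEST_COUNTS)
    return {
        "cps_total": cps_train + cps_test,
        "sps_total": sps_train + sps_test,
        "cps_test": cps_test,
        "sps_test": sps_test,
    }


def summarize_fold_accuracies(accuracies) -> dict:
    """Mean / min / max of a sequence of fold accuracies (percent scale)."""
    arr = np.asarray(accuracies, dtype=float)
    if arr.size == 0:
        raise ValueError("no fold accuracies to summarize")
    return {
        "mean": round(float(arr.mean()), 2),
        "min": float(arr.min()),
        "max": float(arr.max()),
    }
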