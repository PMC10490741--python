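"""Published per-subject reference results for the four-class benchmark.

These tables hold the per-subject validation/test metrics reported for
the standard 9-subject, four-class motor-imagery benchmark (two sessions
of 288 cue-based trials, 22 EEG channels at 250 Hz) under the two
transfer protocols and the two feature cases:

* case 1 — channel-based translation-invariant features (TIFs) only;
* case 2 — TIFs fused with phase-correlation connectivity features.

They are inputs for desk-scale statistics (paired Wilcoxon tests between
the cases, cross-subject averages); reproducing them from raw EEG
requires the external competition recordings, which this package treats
as an optional adapter concern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SUBJECTS = list(range(1, 10))

#: SST protocol, case 1 (TIFs only): per-subject validation/test metrics.
SST_CASE1 = pd.DataFrame(
    {
        "acc_val": [93.03, 81.11, 90.37, 85.84, 60.56, 83.96, 84.91, 78.72, 95.31],
        "acc_test": [68.33, 32.86, 52.38, 50.44, 30.43, 40.47, 33.21, 45.76, 76.52],
        "kappa_val": [0.91, 0.75, 0.87, 0.81, 0.47, 0.79, 0.80, 0.72, 0.94],
        "kappa_test": [0.58, 0.11, 0.36, 0.33, 0.07, 0.21, 0.12, 0.28, 0.69],
        "prec_val": [0.94, 0.85, 0.91, 0.89, 0.63, 0.86, 0.87, 0.83, 0.96],
        "prec_test": [0.70, 0.30, 0.52, 0.44, 0.31, 0.39, 0.34, 0.49, 0.79],
        "rec_val": [0.93, 0.81, 0.90, 0.86, 0.61, 0.84, 0.85, 0.79, 0.95],
        "rec_test": [0.68, 0.33, 0.52, 0.50, 0.30, 0.40, 0.33, 0.46, 0.77],
    },
    index=pd.Index(SUBJECTS, name="subject"),
)

#: SST protocol, case 2 (TIFs fused with phase correlation).
SST_CASE2 = pd.DataFrame(
    {
        "acc_val": [92.66, 74.81, 90.37, 86.61, 60.57, 86.73, 86.03, 90.85, 95.27],
        "acc_test": [79.72, 38.16, 69.23, 56.14, 37.32, 41.86, 35.02, 67.53, 79.92],
        "kappa_val": [0.90, 0.66, 0.87, 0.82, 0.47, 0.82, 0.81, 0.88, 0.94],
        "kappa_test": [0.73, 0.18, 0.59, 0.41, 0.16, 0.22, 0.14, 0.57, 0.73],
        "prec_val": [0.93, 0.75, 0.92, 0.89, 0.60, 0.89, 0.88, 0.93, 0.96],
        "prec_test": [0.80, 0.38, 0.70, 0.52, 0.37, 0.44, 0.43, 0.70, 0.83],
        "rec_val": [0.93, 0.77, 0.90, 0.87, 0.61, 0.87, 0.86, 0.91, 0.95],
        "rec_test": [0.80, 0.35, 0.69, 0.56, 0.37, 0.42, 0.35, 0.68, 0.80],
    },
    index=pd.Index(SUBJECTS, name="subject"),
)

#: CST protocol: validation/test accuracy for both feature cases.
CST = pd.DataFrame(
    {
        "case1_val": [86.47, 57.61, 79.55, 77.50, 67.35, 71.90, 75.50, 73.88, 93.96],
        "case1_test": [70.41, 52.63, 72.05, 60.34, 59.15, 57.28, 51.52, 61.64, 84.21],
        "case2_val": [88.79, 62.29, 82.18, 81.00, 56.89, 76.16, 74.66, 86.91, 94.50],
        "case2_test": [83.43, 56.14, 88.82, 60.34, 57.93, 68.93, 60.61, 77.36, 91.45],
    },
    index=pd.Index(SUBJECTS, name="subject"),
)


def sst_test_accuracies() -> tuple[np.ndarray, np.ndarray]:
    """Per-subject SST test accuracies for (case 1, case 2)."""
    return SST_CASE1["acc_test"].to_numpy(), SST_CASE2["acc_test"].to_numpy()


def cst_test_accuracies() -> tuple[np.ndarray, np.ndarray]:
    """Per-subject CST test accuracies for (case 1, case 2)."""
    return CST["case1_test"].to_numpy(), CST["case2_test"].to_numpy()
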