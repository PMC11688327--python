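"""Published benchmark confusion matrices used to validate the metric suite.

Five-class confusion matrices (rows = actual, columns = predicted, stage order
W, N1, N2, N3, REM) reported by a multimodal EEG/EOG sleep-staging benchmark
on three public cohorts (Sleep-EDF-20, Sleep-EDF-78, SHHS) and one clinical
cohort of obstructive-sleep-apnea patients.  The metric functions in
:mod:`somnostage.metrics` must recover the benchmark's printed accuracy,
macro-F1, kappa and per-class precision/recall/F1 from these counts alone.
"""

from __future__ import annotations

import numpy as np

REFERENCE_CONFUSIONS: dict[str, np.ndarray] = {
    "sleep_edf_20": np.array(
        [
            [8186, 283, 75, 31, 109],
            [293, 1328, 477, 12, 561],
            [89, 275, 15361, 576, 650],
            [9, 1, 503, 4915, 3],
            [64, 207, 408, 4, 6666],
        ],
        dtype=np.int64,
    ),
    "sleep_edf_78": np.array(
        [
            [61287, 2366, 446, 75, 349],
            [2910, 11441, 6342, 61, 2132],
            [3799, 2766, 72533, 365, 2096],
            [31, 7, 2195, 15451, 2],
            [328, 1503, 2763, 32, 26450],
        ],
        dtype=np.int64,
    ),
    "shhs": np.array(
        [
            [42853, 1030, 1317, 171, 848],
            [1488, 5547, 260, 113, 2896],
            [517, 36, 25041, 4264, 267],
            [45, 1008, 4072, 50673, 4355],
            [998, 2296, 4, 3633, 59022],
        ],
        dtype=np.int64,
    ),
    "osa_clinical": np.array(
        [
            [3267, 254, 124, 6, 55],
            [342, 1510, 619, 18, 165],
            [130, 515, 6347, 234, 295],
            [5, 5, 141, 1104, 0],
            [73, 147, 197, 1, 1385],
        ],
        dtype=np.int64,
    ),
}
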