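"""Published reference cross-tabulations of manual vs automated staging.

Two pooled epoch-by-epoch agreement tables from a clinical validation of
differential-EOG staging, reported as row percentages with row epoch
totals: one for subjects with normal breathing or mild sleep-disordered
breathing, one for moderate/severe SDB.  They serve as worked-example
inputs for :func:`eogstage.agreement.reconstruct_counts` and as the
regression fixture for the per-stage kappa computation (the printed
kappas are listed alongside).

Stage order everywhere: W, N1, N2, N3, R (rows = manual, columns =
automated).
"""

from __future__ import annotations

import numpy as np

NORMAL_MILD_ROW_PCT = np.array(
    [
        [79.7, 9.2, 7.7, 0.8, 2.6],
        [24.7, 25.1, 38.4, 0.6, 11.2],
        [6.2, 7.6, 77.7, 6.0, 2.4],
        [1.8, 0.0, 13.5, 83.9, 0.9],
        [4.9, 6.6, 12.4, 1.4, 74.6],
    ]
)
NORMAL_MILD_ROW_TOTALS = np.array([7342, 5436, 18167, 4234, 5462])
NORMAL_MILD_KAPPA = (0.67, 0.21, 0.60, 0.76, 0.72)
NORMAL_MILD_AUTO_TOTALS = np.array([8663, 3793, 18019, 4817, 5349])

MODERATE_SEVERE_ROW_PCT = np.array(
    [
        [71.1, 16.9, 8.1, 0.3, 3.6],
        [18.9, 30.0, 40.3, 0.4, 10.5],
        [8.6, 14.1, 70.5, 4.1, 2.7],
        [7.1, 0.0, 26.7, 65.0, 1.1],
        [4.5, 10.8, 15.9, 1.4, 67.4],
    ]
)
MODERATE_SEVERE_ROW_TOTALS = np.array([9086, 6955, 10205, 1077, 2615])
MODERATE_SEVERE_KAPPA = (0.60, 0.17, 0.48, 0.60, 0.58)
MODERATE_SEVERE_AUTO_TOTALS = np.array([8851, 5349, 11430, 1204, 3104])

GROUPS = {
    "normal_mild": (NORMAL_MILD_ROW_PCT, NORMAL_MILD_ROW_TOTALS, NORMAL_MILD_KAPPA),
    "moderate_severe": (
        MODERATE_SEVERE_ROW_PCT,
        MODERATE_SEVERE_ROW_TOTALS,
        MODERATE_SEVERE_KAPPA,
    ),
}
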