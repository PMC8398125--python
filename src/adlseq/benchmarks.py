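"""Published benchmark confusion matrices for the CASAS Aruba testbed.

These row-normalized 9-class confusion matrices were reported for a
Bi-LSTM-with-temporal-context ADL recognizer evaluated on the Aruba
single-resident dataset (balanced 60-samples-per-class design, stratified
10-fold cross-validation averaged over five sample sets).  They serve as
fixed numeric inputs: under the equal-prevalence convention the full metric
suite (precision, recall, specificity, F1, accuracy, error) is recomputable
from the printed matrices alone, which makes them an exact cross-check for
:func:`adlseq.evaluation.metrics_from_confusion`.

Rows are true classes, columns predictions, both in
:data:`adlseq.preprocessing.CLASS_ORDER`.
"""

import numpy as np

from .preprocessing import CLASS_ORDER

__all__ = [
    "ARUBA_CV_WITH_CONTEXT",
    "ARUBA_CV_WITHOUT_PREV",
    "ARUBA_HOLDOUT",
    "ARUBA_SEQUENTIAL",
    "CLASS_ORDER",
]

#: Cross-validation with both external features (previous activity + begin
#: hour); macro F1 of the recomputed metrics is 0.917.
ARUBA_CV_WITH_CONTEXT = np.array([
    [0.913, 0.007, 0.040, 0.010, 0.000, 0.027, 0.000, 0.000, 0.003],
    [0.010, 0.833, 0.000, 0.013, 0.133, 0.010, 0.000, 0.000, 0.000],
    [0.047, 0.000, 0.937, 0.010, 0.000, 0.003, 0.003, 0.000, 0.000],
    [0.023, 0.003, 0.010, 0.900, 0.013, 0.047, 0.000, 0.000, 0.003],
    [0.003, 0.173, 0.003, 0.000, 0.817, 0.003, 0.000, 0.000, 0.000],
    [0.040, 0.010, 0.010, 0.047, 0.020, 0.873, 0.000, 0.000, 0.000],
    [0.000, 0.000, 0.003, 0.000, 0.000, 0.000, 0.990, 0.000, 0.007],
    [0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 0.000, 1.000, 0.000],
    [0.000, 0.003, 0.000, 0.000, 0.000, 0.000, 0.007, 0.003, 0.987],
])

#: Cross-validation without the previous-activity feature (begin hour only);
#: recomputed macro F1 is 0.734.
ARUBA_CV_WITHOUT_PREV = np.array([
    [0.870, 0.000, 0.020, 0.037, 0.000, 0.073, 0.000, 0.000, 0.000],
    [0.007, 0.617, 0.000, 0.003, 0.360, 0.013, 0.000, 0.000, 0.000],
    [0.143, 0.000, 0.793, 0.033, 0.000, 0.027, 0.003, 0.000, 0.000],
    [0.073, 0.017, 0.003, 0.827, 0.010, 0.060, 0.007, 0.000, 0.003],
    [0.007, 0.343, 0.000, 0.000, 0.630, 0.020, 0.000, 0.000, 0.000],
    [0.037, 0.023, 0.010, 0.123, 0.020, 0.787, 0.000, 0.000, 0.000],
    [0.000, 0.000, 0.003, 0.000, 0.000, 0.000, 0.973, 0.020, 0.003],
    [0.007, 0.003, 0.003, 0.000, 0.000, 0.000, 0.023, 0.653, 0.310],
    [0.003, 0.003, 0.000, 0.000, 0.000, 0.000, 0.067, 0.457, 0.470],
])

#: Evaluation on the imbalanced remainder (instances not drawn into the
#: balanced sets); the headline macro Recall (diagonal mean) is 0.923.
ARUBA_HOLDOUT = np.array([
    [0.880, 0.000, 0.003, 0.034, 0.000, 0.082, 0.000, 0.000, 0.001],
    [0.000, 0.860, 0.000, 0.008, 0.132, 0.000, 0.000, 0.000, 0.000],
    [0.040, 0.000, 0.946, 0.006, 0.001, 0.007, 0.001, 0.000, 0.000],
    [0.053, 0.005, 0.006, 0.915, 0.009, 0.008, 0.000, 0.000, 0.004],
    [0.001, 0.161, 0.000, 0.005, 0.825, 0.008, 0.000, 0.000, 0.000],
    [0.021, 0.008, 0.000, 0.045, 0.029, 0.896, 0.000, 0.000, 0.000],
    [0.000, 0.000, 0.001, 0.000, 0.000, 0.000, 0.997, 0.000, 0.001],
    [0.000, 0.000, 0.000, 0.000, 0.001, 0.000, 0.000, 0.998, 0.000],
    [0.002, 0.002, 0.001, 0.002, 0.000, 0.001, 0.003, 0.000, 0.990],
])

#: Weekly sequential (real-time) evaluation where the previous-activity
#: feature is the recognizer's own previous prediction; macro Recall 0.927.
ARUBA_SEQUENTIAL = np.array([
    [0.977, 0.000, 0.000, 0.000, 0.000, 0.023, 0.000, 0.000, 0.000],
    [0.000, 0.969, 0.000, 0.000, 0.031, 0.000, 0.000, 0.000, 0.000],
    [0.030, 0.000, 0.965, 0.003, 0.003, 0.000, 0.000, 0.000, 0.000],
    [0.018, 0.007, 0.007, 0.958, 0.008, 0.002, 0.000, 0.000, 0.000],
    [0.001, 0.282, 0.000, 0.001, 0.714, 0.003, 0.000, 0.000, 0.000],
    [0.000, 0.041, 0.000, 0.065, 0.045, 0.850, 0.000, 0.000, 0.000],
    [0.000, 0.000, 0.000, 0.007, 0.000, 0.000, 0.966, 0.000, 0.028],
    [0.000, 0.000, 0.000, 0.002, 0.000, 0.000, 0.019, 0.970, 0.009],
    [0.000, 0.002, 0.000, 0.000, 0.000, 0.002, 0.019, 0.005, 0.972],
])
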