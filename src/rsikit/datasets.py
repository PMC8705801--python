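"""Bundled example data.

A seven-subject validation cohort: per-method resilience-index values,
per-channel baseline-vs-final-phase rank correlations, and questionnaire
totals.  Used by the validation examples, the regression tests and the
acceptance report.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_rsi_example", "load_phase_correlation_example"]

_SUBJECTS = ["v1", "v2", "v3", "v4", "v5", "v6", "v7"]

#: Questionnaire totals, ordered by rank (smallest first).
_SCORES = [106, 138, 142, 148, 152, 159, 162]

_RSI = {
    "edpca": [0.2175, 0.5728, -0.0133, 0.2853, 0.4129, 0.0998, 0.1633],
    "md": [0.2420, 0.2562, 0.2024, 0.2249, -0.5933, 0.2200, -0.1718],
    "cvid": [0.0137, 0.6317, 0.1203, 1.0000, -0.1771, -0.0230, 0.0081],
    "edkpca": [0.0813, 0.0075, -0.0090, 0.0232, -0.0151, 0.0490, 0.0318],
}

#: Published coefficient assignment for the example cohort (the normality
#: gate on seven points is variant-sensitive, so replays force it).
RSI_EXAMPLE_ASSIGNMENT = {
    "edpca": "pearson",
    "cvid": "pearson",
    "md": "spearman",
    "edkpca": "spearman",
}

_PHASE_CORR = {
    "subject_id": ["p1", "p2", "p3", "p4", "p5", "p6", "p7"],
    "EMG": [-0.45, 0.00, -0.03, -0.31, -0.09, -0.10, -0.11],
    "HR": [0.25, 0.27, -0.09, 0.08, 0.24, 0.15, 0.04],
    "BR": [-0.27, 0.11, -0.02, 0.16, 0.14, 0.02, 0.03],
    "SC": [0.92, 0.99, 0.88, 0.96, 0.99, 0.99, 0.99],
    "PT": [-0.99, 0.87, 0.94, -0.35, -0.82, -1.00, -1.00],
    "mean": [-0.11, 0.45, 0.34, 0.11, 0.09, 0.01, -0.01],
    "score": [159, 148, 138, 152, 106, 142, 162],
}


def load_rsi_example() -> tuple[pd.DataFrame, pd.Series]:
    """Seven-subject RSI table (subjects x methods) and questionnaire totals."""
    rsi = pd.DataFrame(_RSI, index=pd.Index(_SUBJECTS, name="subject_id"))
    scores = pd.Series(_SCORES, index=rsi.index, name="score")
    return rsi, scores


def load_phase_correlation_example() -> pd.DataFrame:
    """Per-channel baseline-vs-final-phase correlations for seven subjects.

    Columns: five channel coefficients, their row mean, and the subject's
    questionnaire total.
    """
    return pd.DataFrame(_PHASE_CORR).set_index("subject_id")
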