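"""Reference cohort summary statistics.

Per-group (n, mean, SD) triples describing a 60-participant Go/NoGo
response-inhibition cohort (30 abstinent individuals with a history of
alcohol use disorder, 30 healthy controls): demographics, alcohol and
substance use profile, task performance, and BIS-11 impulsiveness
scores.  Shipped so the summary-statistic t-test machinery can be
demonstrated and validated without raw per-subject data.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_cohort_summaries"]

# variable, group, n, mean, sd
_ROWS = [
    ("age_years", "aud", 30, 41.42, 7.32),
    ("age_years", "control", 30, 27.44, 4.74),
    ("education_years", "aud", 30, 11.93, 2.35),
    ("education_years", "control", 30, 15.77, 1.87),
    ("alcohol_onset_age", "aud", 30, 15.77, 2.58),
    ("alcohol_onset_age", "control", 12, 20.50, 3.80),
    ("alcohol_quantity_heavy", "aud", 30, 11.0, 7.66),
    ("alcohol_quantity_heavy", "control", 12, 3.0, 1.60),
    ("alcohol_frequency_heavy", "aud", 30, 20.0, 9.01),
    ("alcohol_frequency_heavy", "control", 12, 4.0, 4.09),
    ("alcohol_quantity_6mo", "aud", 30, 3.0, 6.61),
    ("alcohol_quantity_6mo", "control", 18, 3.0, 1.98),
    ("alcohol_frequency_6mo", "aud", 30, 4.0, 8.02),
    ("alcohol_frequency_6mo", "control", 18, 3.0, 3.62),
    ("abstinence_days", "aud", 30, 672.93, 844.94),
    ("abstinence_days", "control", 18, 57.0, 149.76),
    ("tobacco_quantity_6mo", "aud", 20, 10.0, 5.80),
    ("tobacco_quantity_6mo", "control", 6, 2.0, 1.63),
    ("tobacco_frequency_6mo", "aud", 20, 28.0, 4.83),
    ("tobacco_frequency_6mo", "control", 6, 14.0, 13.82),
    ("marijuana_frequency_6mo", "aud", 10, 99.0, 91.38),
    ("marijuana_frequency_6mo", "control", 4, 19.0, 27.61),
    ("nogo_accuracy_pct", "aud", 30, 85.21, 15.84),
    ("nogo_accuracy_pct", "control", 30, 94.42, 11.85),
    ("go_accuracy_pct", "aud", 30, 91.25, 9.44),
    ("go_accuracy_pct", "control", 30, 88.83, 8.03),
    ("reaction_time_ms", "aud", 30, 349.85, 31.15),
    ("reaction_time_ms", "control", 30, 324.47, 32.27),
    ("bis11_nonplanning", "aud", 28, 24.57, 5.25),
    ("bis11_nonplanning", "control", 30, 19.80, 4.61),
    ("bis11_motor", "aud", 27, 25.15, 5.24),
    ("bis11_motor", "control", 30, 19.30, 3.28),
    ("bis11_attentional", "aud", 28, 15.79, 4.13),
    ("bis11_attentional", "control", 30, 12.57, 3.19),
    ("bis11_total", "aud", 27, 65.44, 11.51),
    ("bis11_total", "control", 30, 51.67, 8.60),
]


def load_cohort_summaries() -> pd.DataFrame:
    """Long-format summary table with columns
    (variable, group, n, mean, sd); the AUD group rows come first for
    each variable, so group differences are AUD minus control."""
    return pd.DataFrame(_ROWS, columns=["variable", "group", "n", "mean", "sd"])
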