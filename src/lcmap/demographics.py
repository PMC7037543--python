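"""Reference demographic-table verification.

The motivating clinical cohort published its demographic and self-report
comparisons only as printed counts and summary statistics.  Binary rows
(sex, race/ethnicity) are *fully determined* by their counts — a pooled
t-test on 0/1 indicators reproduces their p-values exactly — and the
continuous self-report rows can be recomputed from the printed
means/SDs/ns.  A 2x2 chi-square without continuity correction is provided
as the alternative categorical test.  This module carries those printed
inputs and recomputes every row, which doubles as a worked-example check of
the statistics layer.
"""

from __future__ import annotations

from typing import Dict

from .cohort_stats import StatResult, binary_t_from_counts, chi_square_2x2, \
    t_from_summary

N_HC = 14
N_PT = 15

#: binary rows: (positives in HC, positives in PT)
BINARY_ROWS: Dict[str, tuple] = {
    "male": (10, 6),
    "white_caucasian": (6, 7),
    "black_african_american": (6, 4),
    "hispanic_latino": (1, 4),
    "undisclosed": (1, 0),
}

#: continuous rows: (mean_hc, sd_hc, mean_pt, sd_pt)
SUMMARY_ROWS: Dict[str, tuple] = {
    "age": (39.9, 9.0, 38.7, 10.2),
    "masq_general_distress": (11.4, 2.4, 23.4, 10.0),
    "masq_anhedonic_depression": (29.1, 8.9, 37.8, 7.0),
    "masq_anxious_arousal": (12.6, 1.5, 19.7, 10.3),
    "atq_activation": (38.9, 6.2, 31.9, 9.8),
    "atq_attentional": (30.1, 6.3, 18.0, 6.8),
    "atq_inhibitory": (38.3, 6.4, 30.1, 7.7),
}


def verify_demographics() -> Dict[str, StatResult]:
    """Recompute every demographic-table test from the printed inputs.

    Returns a mapping row -> StatResult; binary rows get both the pooled
    indicator t-test (``<row>``) and the uncorrected chi-square
    (``<row>_chi2``).
    """
    out: Dict[str, StatResult] = {}
    for name, (k1, k2) in BINARY_ROWS.items():
        out[name] = binary_t_from_counts(k1, N_HC, k2, N_PT)
        out[f"{name}_chi2"] = chi_square_2x2(k1, N_HC - k1, k2, N_PT - k2)
    for name, (m1, s1, m2, s2) in SUMMARY_ROWS.items():
        out[name] = t_from_summary(m1, s1, N_HC, m2, s2, N_PT, variant="pooled")
    return out
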