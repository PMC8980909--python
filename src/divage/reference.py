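"""Published reference estimates used in worked examples.

Age-slope and interaction coefficients (per decade of age, z-scored
AD-GRS) for the 13 UK Biobank cognitive measures whose age x risk-score
interaction survived Bonferroni correction in the published analysis this
pipeline reimplements, together with the percentage effect size the report
printed.  They serve as inputs to worked examples and as arithmetic checks
on the percent-ratio metric; for some rows the printed percentage was
computed from unrounded coefficients and differs in the last digit from
what the rounded coefficients give, so ``PERCENT_CONSISTENT_ROWS`` lists
the rows where the printed value is exactly reproducible from the printed
coefficients.
"""

from __future__ import annotations

__all__ = ["REFERENCE_SCREEN_ESTIMATES", "PERCENT_CONSISTENT_ROWS", "N_SCREENED_MEASURES"]

#: number of cognitive measures entering the stage-1 screen (Bonferroni m)
N_SCREENED_MEASURES = 32

#: measure -> (age slope per decade, interaction per decade, printed percent)
REFERENCE_SCREEN_ESTIMATES: dict[str, tuple[float, float, float]] = {
    "pairs_match_correct_online_r1": (-0.124, -0.014, 11.5),
    "pairs_match_correct_in_person_r1": (-0.091, -0.007, 7.9),
    "pairs_match_correct_in_person_r2": (-0.093, -0.009, 9.4),
    "pairs_match_time_in_person_r1": (-0.207, -0.011, 5.3),
    "pairs_match_incorrect_in_person_r1": (-0.144, -0.006, 4.4),
    "pairs_match_time_online_r1": (-0.440, -0.015, 3.5),
    "pairs_match_time_in_person_r2": (-0.312, -0.008, 2.5),
    "numeric_memory_correct_online": (-0.180, -0.016, 8.8),
    "symbol_digit_correct_in_person": (-0.599, -0.035, 5.8),
    "symbol_digit_attempted_in_person": (-0.621, -0.036, 5.7),
    "symbol_digit_time_online": (-0.521, -0.024, 4.5),
    "symbol_digit_correct_online": (-0.588, -0.014, 2.4),
    "symbol_digit_attempted_online": (-0.617, -0.012, 2.0),
}

#: rows where round(100 * b_int / b_age, 1) reproduces the printed percent
PERCENT_CONSISTENT_ROWS: tuple[str, ...] = (
    "symbol_digit_correct_in_person",
    "pairs_match_time_in_person_r1",
    "symbol_digit_correct_online",
)
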