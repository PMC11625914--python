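"""Reference cohort summary statistics used by the summary-table utilities.

Printed (n, mean, SD) cells of a 48-patient ALS cohort stratified by
progression speed (slow / fast / very fast progressors, 27/13/8), plus the
32-subject healthy-control comparison.  These triplets are inputs to
:func:`nvcoupling.stats.pooled_mean` and
:func:`nvcoupling.stats.anova_from_summary`, which reconstruct the pooled
column and the one-way ANOVA F statistics that such a table reports.
"""
from __future__ import annotations

from .stats import SummaryGroup

#: 12-month ALSFRS-R follow-up cells, per progression subgroup (SP, FP, VFP)
ALSFRS_12M_SUBGROUPS: dict[str, list[SummaryGroup]] = {
    "total": [SummaryGroup(27, 36.67, 4.82), SummaryGroup(13, 27.77, 5.35),
              SummaryGroup(8, 0.00, 0.00)],
    "bulbar": [SummaryGroup(27, 10.63, 2.40), SummaryGroup(13, 6.23, 3.63),
               SummaryGroup(8, 0.00, 0.00)],
    "upper_limbs": [SummaryGroup(27, 7.56, 3.42), SummaryGroup(13, 6.62, 4.13),
                    SummaryGroup(8, 0.00, 0.00)],
    "lower_limbs": [SummaryGroup(27, 7.56, 2.90), SummaryGroup(13, 5.62, 2.69),
                    SummaryGroup(8, 0.00, 0.00)],
    "respiratory": [SummaryGroup(27, 11.00, 1.44), SummaryGroup(13, 9.31, 2.84),
                    SummaryGroup(8, 0.00, 0.00)],
}

#: printed pooled ALS column for the same rows (mean over all 48 patients)
ALSFRS_12M_POOLED: dict[str, float] = {
    "total": 28.15,
    "bulbar": 7.67,
    "upper_limbs": 6.04,
    "lower_limbs": 5.77,
    "respiratory": 8.71,
}

#: printed one-way ANOVA F statistics for the same rows
ALSFRS_12M_F: dict[str, float] = {
    "total": 196.50,
    "bulbar": 53.52,
    "upper_limbs": 15.81,
    "lower_limbs": 25.95,
    "respiratory": 112.39,
}

#: age cells, ALS vs HC (printed F = 3.79)
AGE_GROUPS = [SummaryGroup(48, 60.65, 9.62), SummaryGroup(32, 55.06, 16.00)]
AGE_F = 3.79

#: sex contingency table (male/female) x (ALS/HC); printed chi-squared = 2.14
SEX_TABLE = [[29, 19], [14, 18]]
SEX_CHI2 = 2.14

#: printed mean 12-month ALSFRS-R change of the fast-progressor cluster and
#: its monthly rate
FP_DELTA_MEAN = -13.85
FP_MONTHLY_RATE = -1.15
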