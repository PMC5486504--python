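"""Generate a calibrated metric-mode cohort and run the statistics stage.

Draws the default 72-aneurysm cohort (41 ruptured / 31 unruptured, split
into narrow- and wide-necked strata) from the group-calibrated metric
distributions, then produces the four comparison tables, the univariate
screen and the backward stepwise logistic regression for rupture.
"""

from hemoshear import CohortConfig, cohort_to_frame, sample_metric_cohort
from hemoshear.stats import (
    HEMODYNAMIC_PARAMS,
    backward_stepwise_logistic,
    build_comparison_tables,
    univariate_screen,
)

frame = cohort_to_frame(sample_metric_cohort(CohortConfig(seed=1)))
print(frame.groupby(["rupture_label", "neck_category"]).size(), "\n")

tables = build_comparison_tables(frame)
print("ruptured vs unruptured within the narrow-necked stratum:")
print(tables["narrow"][["parameter", "test", "p"]].to_string(index=False), "\n")

frame["ruptured"] = (frame["rupture_label"] == "ruptured").astype(int)
screened = univariate_screen(frame, HEMODYNAMIC_PARAMS)
print("univariately significant (p < 0.05):", screened)
if screened:
    fit = backward_stepwise_logistic(frame, screened)
    print("stepwise-retained predictors:", fit.retained)
    print("removal trace:", fit.trace)
# p-values vary with the seed: the cohort is a stochastic draw from the
# calibrated group distributions, not a copy of any patient data.
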