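"""Clean a cohort and decide whether the reference interval needs
partitioning by sex and/or age.

The filter cascade excludes records whose covariates (folate, B12,
liver/renal/thyroid panel) are outside their reference limits; the
equal-weighted subsample balances sex and age bands; iterative Box-Cox
Tukey filtering removes analyte outliers per subgroup.  The partition
decision compares standard-deviation ratios (between-group SD over
residual SD) against the conventional 0.375 threshold.
"""

import refmine as rm
from refmine import cleaning

records, _ = rm.generate_cohort(rm.CohortConfig(n_total=10_000, seed=1))

cleaned, report = cleaning.apply_filter_cascade(
    records, cleaning.default_filter_rules())
print("cleaning waterfall:")
print(report.to_frame().to_string(index=False))

sub = cleaning.equal_weight_subsample(cleaned, seed=2,
                                      policy="take_all_smaller")
sub = sub.copy()
sub["age_group"] = cleaning.age_band(sub["age"].to_numpy())
ds1, tukey = cleaning.iterative_tukey_filter(sub, ["sex", "age_group"])
print(f"\nafter subgroup Tukey: {tukey['n_before']} -> {tukey['n_after']}")

decision = rm.decide_partition(ds1)
print(f"\nstandardized beta (sex): {decision.betas['sex']:.3f}")
print(f"SDR sex = {decision.sdr_sex:.3f}, SDR age = {decision.sdr_age:.3f} "
      f"(threshold {decision.threshold})")
print(f"partition by sex: {decision.partition_by_sex}, "
      f"by age: {decision.partition_by_age}")
# SDR > 0.375 means the between-group spread is large enough relative to
# residual scatter that separate reference intervals are warranted.
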