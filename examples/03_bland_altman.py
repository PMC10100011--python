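"""Bland-Altman agreement analysis from a difference summary.

Given the mean +/- SD of paired per-subject differences between two
segmentation methods, compute the bias confidence interval, the 95% limits
of agreement (LoA), and exact confidence limits for each LoA from the
noncentral-t construction.
"""

from carotiq import DiffSummary, bias_confidence_interval, exact_loa_confidence_limits, limits_of_agreement

# carotid volume, 49 subjects, differences manual - automated (ml)
summary = DiffSummary(n=49, mean_diff=1.33, sd_diff=2.06)

bias_lo, bias_hi = bias_confidence_interval(summary)
loa_lo, loa_hi = limits_of_agreement(summary)
(lower_ci, upper_ci) = exact_loa_confidence_limits(summary)

print(f"bias {summary.mean_diff:.2f} ml (95% CI {bias_lo:.2f} to {bias_hi:.2f})")
print(f"limits of agreement {loa_lo:.2f} to {loa_hi:.2f} ml")
print(f"lower LoA 95% CI: {lower_ci[0]:.2f} to {lower_ci[1]:.2f}")
print(f"upper LoA 95% CI: {upper_ci[0]:.2f} to {upper_ci[1]:.2f}")

# About 95% of between-method volume differences are expected inside the
# LoA; the outer confidence limits bound how far the LoA themselves may sit
# given only 49 subjects.
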