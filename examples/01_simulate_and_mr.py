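"""Simulate a two-sample MR study and run the estimator battery.

The generator mirrors a design of 328 instruments from a large
continuous-trait exposure GWAS against a case-control outcome GWAS.
Here we plant a true causal effect of 0.1 (log-odds per exposure SD)
and no pleiotropy, so every estimator should land near 0.1.
"""

from crossmr import SyntheticMRConfig, simulate_mr_study, harmonize_datasets
from crossmr.mr import mr_report, f_statistic

cfg = SyntheticMRConfig(true_beta=0.1, seed=1)
exposure, outcome, truth = simulate_mr_study(cfg)
instruments, exclusions = harmonize_datasets(exposure, outcome, mode="strict")

print(f"instruments retained: {len(instruments)} "
      f"(excluded: {exclusions.counts()})")
print(f"mean per-SNP F: {f_statistic(instruments):.1f} "
      "(>> 10: weak-instrument bias negligible)")
print()
report = mr_report(instruments)
cols = ["method", "estimate", "se", "pvalue", "intercept", "q_stat", "tau2"]
print(report[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print()
print(f"true causal effect was {truth['true_beta']}; each estimate above "
      "should fall within ~2 SEs of it, and the Egger intercept near 0 "
      "(no directional pleiotropy was planted).")
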