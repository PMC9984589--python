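"""Run the complete repeatability study and the statistical comparison.

Simulates a small cohort for both muscles, computes the per-level metric
table and tests whether the amount of included muscle volume affects each
metric (normality-gated repeated-measures ANOVA or Friedman, with
Bonferroni-corrected post hoc pairs).
"""

from segrepeat import NoiseModel, StudyConfig, run_study

config = StudyConfig(
    mode="synthetic",
    muscles=["gluteus_medius", "iliopsoas"],
    n_subjects=5,
    n_repeats=3,
    noise=NoiseModel(belly_sigma_mm=0.5, extremity_sigma_mm=3.0,
                     correlation_length_mm=8.0, seed=0),
    seed=123,
)
result = run_study(config)

print(result.summary.to_string(index=False))
print()
for muscle, by_metric in result.reports.items():
    for metric, report in by_metric.items():
        sig = "significant" if report.omnibus_p < report.alpha else "n.s."
        print(f"{muscle:>16s}  {metric:<12s} {report.omnibus_test:<8s} "
              f"stat={report.omnibus_stat:8.2f}  p={report.omnibus_p:.3g}  ({sig})")
# A significant omnibus p means the sub-volume level changes that metric:
# with extremity-weighted noise, agreement degrades as more muscle is included.
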