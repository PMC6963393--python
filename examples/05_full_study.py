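"""Run the full in-silico agreement study and print the report tables.

40 noisy phantom subjects with IPH contrast ratios uniform on (1.3, 3.0) are
segmented by the level-set manual proxy and the three thresholds; ICCs of the
total IPH volume are estimated against the manual arm and compared pairwise.
"""

from iphquant import StudyConfig, export_comparison_plot_data, run_study

result = run_study(StudyConfig(seed=1))

print("ICC of IPH volume vs the manual proxy (two-way absolute agreement):")
for label, est in result.icc_table.items():
    print(f"  manual vs {label:4s}: {est.value:.3f} "
          f"({est.ci_low:.3f}, {est.ci_high:.3f})  {est.band}")

print("\nOne-sided Fisher-z comparisons (Bonferroni m = 2):")
for name, comp in result.comparison_table.items():
    print(f"  {name}: z = {comp.statistic:.4f}, adj. p = {comp.p_adjusted:.4g}")

table = export_comparison_plot_data(result)
print(f"\nper-subject long table: {len(table)} rows "
      f"({result.provenance['n_subjects']} subjects x 4 methods)")
print(table.head(8).to_string(index=False))
# Lower thresholds agree better with the contrast-based manual proxy because
# high thresholds zero out low-contrast hemorrhages entirely.
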