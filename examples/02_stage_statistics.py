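"""Compare lesion metrics across clinical stages.

Generates a synthetic cohort at the study conditions (stage counts
3/16/4; stage-separated MBV medians, stage-independent uptake-ratio
medians) and runs the stage comparison: per-stage median [IQR],
Kruskal-Wallis omnibus, Steel-Dwass all-pairs post hoc.
"""

from bonequant import CohortSpec, generate_cohort, stage_comparison_report
from bonequant.stats import report_to_markdown

truth, _ = generate_cohort(CohortSpec(seed=7))
report = stage_comparison_report(
    truth, metrics=("mbv_cm3", "rsuv_mean"), alpha=0.05
)
print(report_to_markdown(report))
print(
    "MBV separates the stages (small omnibus p), while the uptake ratio\n"
    "rSUVmean - generated with stage-independent medians - does not;\n"
    "adjusted pairwise p-values identify which stages differ."
)
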