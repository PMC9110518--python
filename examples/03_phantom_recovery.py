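"""Parameter recovery on digital phantoms with known ground truth.

Renders one synthetic cohort as single-lesion phantom volumes (8-mm
FWHM smoothing, Poisson-like noise), runs threshold segmentation and
metric extraction on each, and scores recovered against true values.
"""

from scipy.stats import spearmanr

from bonequant import CohortSpec, generate_cohort, recover_and_score

spec = CohortSpec(seed=42)
truth, phantoms = generate_cohort(spec, with_phantoms=True)
scored = recover_and_score(phantoms, truth)

cols = ["stage", "true_mbv_cm3", "recovered_mbv_cm3", "mbv_rel_error"]
print(scored[cols].round(2).to_string(index=False))

rho = spearmanr(scored.true_mbv_cm3, scored.recovered_mbv_cm3).statistic
print(f"\nSpearman(true, recovered MBV) = {rho:.3f}")
print(
    "Recovered MBV systematically overshoots the true volume (the\n"
    "histogram threshold sits well below the half-maximum of the\n"
    "smoothed lesion edge), but the ordering of lesion sizes is\n"
    "preserved, which is what the stage comparison relies on."
)
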