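"""Quantify one hot lesion: activity volume -> SUV map -> VOI -> metrics.

Builds a small digital phantom in raw activity units (Bq/mL), converts
it to an SUV map with the body-weight normalisation, segments the lesion
with the histogram threshold, and prints the per-lesion metrics.
"""

import numpy as np

from bonequant import (
    AcquisitionMeta,
    ImageVolume,
    SeedRegion,
    compute_ratio_metrics,
    compute_suv_map,
    compute_voi_metrics,
    define_control_voi,
    segment_lesion_voi,
)

# --- a 32^3 activity volume at the scanner's 3.90 mm isotropic grid ----
shape, spacing = (32, 32, 32), (3.9, 3.9, 3.9)
origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
vol = ImageVolume(
    data=np.zeros(shape), spacing=spacing, origin=origin, units="activity_Bq_per_mL"
)
centers = vol.voxel_centers()
inside = np.sum(centers**2, axis=-1) <= 15.0**2  # 15 mm radius hot sphere
vol = vol.with_data(np.where(inside, 60_000.0, 2_000.0))  # Bq/mL

# --- SUV normalisation: 740 MBq administered to a 60 kg patient --------
meta = AcquisitionMeta(
    administered_activity_bq=740e6, body_weight_g=60_000, patient_id="EX01"
)
suv = compute_suv_map(vol, meta)  # percent scale

# --- threshold segmentation from a target range drawn over the lesion --
target = SeedRegion("box", (0, 0, 0), half_extents_mm=(20, 20, 20))
voi = segment_lesion_voi(suv, target)
est = voi.threshold_used
print(f"threshold: mode={est.mode_value:.2f} base={est.base_value:.2f} "
      f"SD={est.sd:.2f} -> threshold={est.threshold:.2f} SUV%")

# --- metrics and control-normalised ratios -----------------------------
control = SeedRegion("sphere", (-45, 0, 0), radius_mm=10, role="control")
lesion_m = compute_voi_metrics(suv, voi)
control_m = compute_voi_metrics(suv, define_control_voi(suv, control))
ratios = compute_ratio_metrics(lesion_m, control_m)

print(f"SUVmax  = {lesion_m.suv_max:.1f} %   (hottest voxel of the VOI)")
print(f"SUVmean = {lesion_m.suv_mean:.1f} %   (mean over {lesion_m.voxel_count} voxels)")
print(f"MBV     = {lesion_m.mbv_cm3:.2f} cm^3 (supra-threshold volume)")
print(f"TBU     = {lesion_m.tbu:.1f}       (MBV x SUVmean)")
print(f"rSUVmax = {ratios.rsuv_max:.2f}, rSUVmean = {ratios.rsuv_mean:.2f}, "
      f"rTBU = {ratios.rtbu:.2f}  (lesion / unaffected-bone control)")
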