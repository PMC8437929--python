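"""Retest reproducibility: two noisy sessions of the same phantom.

Simulates two repeat acquisitions at Rician SNR 20, reconstructs the
uncrossed DRT in each, renders streamline densities, warps them to template
space and reports the z-resolved congruence: slice-wise centre-of-gravity
(COG) distance and Dice at 2 streamlines/voxel, aggregated over the
stereotactically relevant z range [-27, 16] mm.
"""

from drteval import (MetricParams, PhantomSpec, SelectionSpec, TrackingParams,
                     congruence_profile, fit_tensor_lls, make_session_pair,
                     render_density, select_drt, track, warp_density)

s1, s2, gt = make_session_pair(PhantomSpec(snr=20, seed=7))
densities = []
for i, dwi in enumerate((s1, s2), start=1):
    field = fit_tensor_lls(dwi)
    tg = track(field, gt.masks["WM"], TrackingParams())
    sel = select_drt(tg, gt.masks, SelectionSpec(variant="uncrossed"))
    print(f"session {i}: {len(sel)} DRTu streamlines")
    native = render_density(sel, gt.masks.shape, gt.affine)
    densities.append(warp_density(native, gt.warp))

metrics = MetricParams()
res = congruence_profile(densities[0], densities[1], metrics)
agg = res.aggregate()
print(f"retest COG distance: mean {agg['cog_mean_mm']:.2f} mm, "
      f"median {agg['cog_median_mm']:.2f} mm over {agg['n_defined_cog']} "
      f"defined z levels")
print(f"retest Dice (threshold {metrics.dice_threshold:g}): "
      f"mean {agg['dice_mean']:.3f}")
for name, z in metrics.eval_levels.items():
    lvl = res.at_level(z)
    print(f"  level {name:7s} (z = {z:+.0f} mm): "
          f"COG {lvl['cog_distance_mm']:.2f} mm, Dice {lvl['dice']:.3f}")
# Sub-voxel COG distances mean the uncrossed tract's cross-section is
# stable between sessions at this noise level.
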