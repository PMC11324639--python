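"""Coronary territory assignment and vessel-specific regional perfusion.

Simulates a phantom whose LAD, LCx and RCA territories perfuse at 1.0,
1.5 and 2.0 mL/min/g, measures the voxel-wise perfusion map, re-assigns
territories from the coronary centerlines by geodesic minimum-cost path,
and prints the per-territory mean perfusion and tissue mass. The regional
means should recover the per-territory ground truth, and the mass-weighted
mean of the territories equals the whole-heart P_ave.
"""

from svperf import PhantomConfig, measure_study, simulate_study
from svperf.core import MyocardiumSample
from svperf.territory import assign_territories, regional_perfusion

truth = {"LAD": 1.0, "LCx": 1.5, "RCA": 2.0}
config = PhantomConfig(territory_truth=truth)
study = simulate_study(config)
result = measure_study(study.bolus, study.volume_scan, study.myo_mask,
                       study.aorta_mask, study.t_scan_s,
                       config.voxel_volume_ml)

tmap = assign_territories(study.myo_mask, study.centerlines,
                          config.voxel_size_mm, metric="geodesic")
sample = MyocardiumSample(study.myo_mask, config.voxel_volume_ml)
table = regional_perfusion(result.voxel_map, tmap, sample)

print(table.round(4))
for artery, row in table.iterrows():
    print(f"{artery}: measured {row['mean_perfusion_ml_min_g']:.3f} "
          f"vs truth {truth[artery]:.3f} mL/min/g "
          f"({row['mass_g']:.2f} g of tissue)")
weighted = (table.mean_perfusion_ml_min_g * table.mass_g).sum() / table.mass_g.sum()
print(f"mass-weighted regional mean {weighted:.4f} "
      f"== whole-heart P_ave {result.p_ave_ml_min_g:.4f} mL/min/g")
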