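# svperf — single-volume dynamic CT myocardial perfusion

`svperf` quantifies myocardial blood flow in mL/min/g from the minimum
possible dynamic CT data: the low-dose bolus-tracking samples that every
contrast-enhanced cardiac acquisition already records, plus **one**
contrast-enhanced whole-heart volume scan acquired near the peak of aortic
enhancement. Because only a single diagnostic volume is needed, the
technique avoids the motion-misregistration artifacts and the 5–15 mSv
doses of conventional multi-volume CT perfusion, and the same volume doubles
as a coronary CT angiogram. The package is aimed at researchers developing
or validating quantitative cardiac CT perfusion methods.

## The model

The whole myocardium (left + right ventricular walls) is treated as a
single compartment during the first pass of contrast. Assuming no contrast
mass has yet left the compartment, average perfusion is

```
P_ave = M_T^(-1) · C_IN^(-1) · dM_c/dt        [mL/min/g]
```

- **M_T** — myocardial tissue mass: segmented voxel count × voxel volume ×
  density (1.053 g/mL).
- **dM_c** — whole-compartment contrast mass change (HU·mL): the mean
  myocardial enhancement between the non-enhanced bolus-tracking frames and
  the volume scan, times segmented volume. Divided by the integration time
  dt it gives the accumulation rate.
- **C_IN** — average aortic input concentration (HU): the aortic
  enhancement curve is reconstructed by fitting a gamma-variate
  `C(t) = baseline + A·((t−t0)/(αβ))^α · e^(α−(t−t0)/β)` to the sparse
  bolus-tracking samples plus the volume-scan aortic value; C_IN is the
  closed-form area under the fitted curve from contrast arrival to scan
  time, divided by dt.

Voxel-wise maps distribute P_ave proportionally to per-voxel enhancement;
coronary territories (LAD/LCx/RCA) are assigned per voxel by
minimum-cost-path (geodesic) distance to the extracted coronary
centerlines, giving vessel-specific regional perfusion.

A seeded digital cardiac phantom simulates the entire acquisition protocol
(80-HU bolus-tracking trigger, scan delay of half the injection duration
plus 2 s, first-pass enhancement with known ground-truth perfusion) so
every stage of the pipeline can be validated against exact ground truth.
Repeatability statistics (regression, Spearman ρ, RMSE/RMSD, Bland-Altman
limits of agreement, exact Wilcoxon signed-rank) and CT dosimetry
(SSDE, effective dose) round out the toolkit.

## Worked example

```python
from svperf import PhantomConfig, simulate_study, measure_study

config = PhantomConfig()                 # uniform 0.92 mL/min/g rest truth
study = simulate_study(config)           # simulated acquisition
result = measure_study(study.bolus, study.volume_scan, study.myo_mask,
                       study.aorta_mask, study.t_scan_s,
                       config.voxel_volume_ml)
print(study.truth_mean_perfusion, result.p_ave_ml_min_g)
```

Running `python examples/simulate_and_measure.py` prints:

```
trigger fired at 9.00 s; volume scan at 13.71 s (delay 4.715 s)
ground-truth mean perfusion : 0.9200 mL/min/g
recovered P_ave             : 0.9201 mL/min/g
myocardial mass M_T         : 5.45 g
input concentration C_IN    : 181.4 HU over dt = 7.37 s
```

The bolus tracking triggered when the simulated aortic enhancement crossed
80 HU above baseline; the scan followed 5.43/2 + 2 = 4.715 s later; and the
compartment model recovered the ground-truth perfusion to 0.01% — on
noiseless data the only error source is refitting the input function from
its own sparse samples. The other scripts in `examples/` demonstrate AIF
fitting, territory assignment with regional perfusion, the repeatability
battery, and dose/timing arithmetic, each printing and explaining its
numbers.

A thin CLI mirrors the library:
`svperf simulate | fit-aif | measure | territories | dose | delay | repro`
(see `svperf --help`).

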