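# Methods

## First-pass compartment model

The myocardium (left and right ventricular walls combined) is one
well-mixed compartment. During the first pass of a contrast bolus, no
contrast mass is assumed to have left the compartment, so the tissue
enhancement at any time is proportional to the cumulative arterial input
delivered per gram of tissue:

    HU_myo(t) − HU_myo(0) = (P/60) · ρ · ∫[t_arr, t] (C_ao(τ) − C_ao(0)) dτ

with P perfusion in mL/min/g (the factor 60 converts minutes to seconds),
ρ tissue density in g/mL, and C_ao the aortic attenuation. Solving for P
at the volume-scan time and aggregating over the segmented myocardium
gives the implemented estimator

    P_ave = 60 · (dM_c / dt) / (M_T · C_IN)

where dM_c is mean myocardial enhancement × voxel count × voxel volume
(HU·mL), dt the integration time from fitted contrast arrival to the scan,
M_T = voxel count × voxel volume × ρ, and C_IN the time-averaged aortic
enhancement over [arrival, scan]. C_IN is defined as the *time average*
(AUC/dt) rather than the raw AUC: this is the only reading under which the
estimator is dimensionally a flow per mass, and it makes P_ave reduce to
60·ΔHU_mean/(ρ·AUC) — independent of segmentation size, as a specific flow
must be.

Assumptions and consequences:

- **No venous outflow during the measurement.** Valid only when the scan is
  acquired during the first pass; the protocol's trigger + short delay is
  designed to guarantee this. Late scans would underestimate perfusion.
- **Spatially homogeneous pre-contrast attenuation.** The pre-contrast
  myocardial value is a single scalar (mean of the myocardial samples in
  the first non-enhanced bolus-tracking frames, default 3). Infarct scar or
  cardiomyopathy violates this.
- **Enhancement is linear in iodine concentration** — standard for CT.

The voxel map distributes P_ave proportionally to per-voxel enhancement
above the scalar baseline, so the masked mean of the map equals P_ave by
construction. Noise can make individual voxels negative; they are kept in
the stored map (preserving the mean identity) and clipped to zero only on
export when requested.

## Aortic input function

The AIF is a peak-normalized gamma-variate

    C(t) = baseline + A · ((t−t0)/(αβ))^α · e^(α−(t−t0)/β),   t > t0,

chosen so A is the peak enhancement above baseline (HU) and the peak sits
at t0 + αβ. The area above baseline has the closed form
A·e^α·β^(α+1)·Γ(α+1)/(αβ)^α · [P(α+1, (t−t0)/β)] between window bounds,
with P the regularized lower incomplete gamma function; tests verify it
against adaptive quadrature to 1e-8 relative on random parameter draws.

Fitting: unweighted nonlinear least squares over (A, α, β, t0) with the
baseline fixed at the mean of the pre-arrival tracking samples.
Initialization uses the 10-HU threshold crossing of the raw samples for
t0, α = 3, and β from the observed peak-time guess; bounds are
α ∈ (0.1, 10], β ∈ (0.1, 20] s. Because samples that have *just* started
enhancing can sit below the 10-HU detection threshold and contaminate the
baseline mean, the pre-arrival window is refined after each fit (samples
earlier than the fitted t0) and the fit repeated until the window is
stable (at most 4 passes). On noiseless data this recovers generating
parameters to machine precision.

Contrast arrival is the first time the fitted curve exceeds a configurable
ε = 1 HU above baseline. A second-derivative "inflection" criterion is
unusable here because the curve leaves baseline with zero slope for α > 1;
the ε-crossing is within ~0.5 s of t0 across realistic parameters and
biases the AUC window by well under 0.1%. One consequence: P_ave is
invariant to rescaling all enhancements only up to the fixed ε (relative
changes ~1e-4 at 2.5×), since ε does not scale with the data.

Identifiability: the tracking series contains only the rising edge up to
the 80-HU trigger plus the single volume-scan point. With a fast AIF the
enhanced samples can number fewer than the four free parameters and the
fit becomes degenerate (a family of curves passes exactly through the
data). The phantom's default AIF (A = 400 HU, α = 2.5, β = 4 s, i.e. a
10-s upslope, typical of a peripheral-injection first pass) yields four
enhanced tracking samples before the trigger and a well-posed fit.

## Digital phantom

The phantom emulates the acquisition, not a patient image: an ellipsoidal
left-ventricular shell (optional second shell), a cylindrical descending
aorta, and epicardial coronary centerlines laid on the shell surface at
equally spaced azimuths. Arrays are indexed (z, y, x), world coordinates =
index × voxel size, defaults 0.50 × 0.468 × 0.468 mm (the protocol's
reconstruction voxel). The default geometry is a miniature (~3 cm) heart —
5.5 g of myocardium rather than a few hundred — which leaves the
mathematics unchanged (every quantity is per-gram) while keeping
simulations fast; grid and geometry scale freely through the config.

Protocol emulation: the aorta is sampled every 0.75 s (one cardiac cycle
at the 80-bpm rest heart rate) from injection start; the trigger is the
first sample ≥ 80 HU above the blood baseline; the volume scan follows
after half the injection duration (default 5.43 s, a 54.3-kg subject at
0.5 mL/kg and 5 mL/s) plus 2 s. If no sample reaches the trigger before
the bolus peak the simulation raises a protocol-failure error, mirroring
false-triggering exclusions in practice. At least three pre-arrival frames
are required so a baseline exists.

Myocardial voxels enhance by (P_truth/60)·ρ·AUC(t0 → t_scan) — the exact
first-pass relation the estimator inverts, so noiseless recovery errors
isolate the AIF refit. The tracking table's myocardial column uses the
mask-mean truth perfusion. Noise is additive i.i.d. Gaussian in HU (per
voxel and per sample) from a single seeded generator; identical configs
and seeds are bit-identical. Not emulated: photon/Poisson noise, beam
hardening, cardiac/respiratory motion, partial-volume effects, contrast
recirculation, chaser-phase right-heart physics. Passing phantom tests
therefore demonstrates correctness of the estimator and pipeline, not
robustness to these real-data effects. Under 5-HU Gaussian noise the
sparse nonlinear AIF refit introduces a small upward bias in recovered
perfusion (a few percent at default settings), visible in the noisy
replicate numbers the acceptance script reports.

Ground-truth perfusion is constant per coronary territory
(artery → mL/min/g in the config; default 0.92 everywhere, a typical rest
value); territories come from the package's own geodesic assignment on the
generated centerlines, so truth and measurement share one definition of a
territory.

## Territory assignment

"Nearest artery" is implemented as geodesic distance: multi-source
Dijkstra over the 26-connected voxel graph restricted to the myocardial
mask plus the voxels containing centerline points, edge weights equal to
the physical step length in mm (metric weights avoid grid-direction bias).
Centerlines are resampled to half the smallest voxel spacing before
snapping to voxels so sparse polylines cannot skip seeds. Each voxel takes
the label of the artery with the smallest path cost; exact ties break in
fixed LAD < LCx < RCA order, making the labeling independent of input
order. Straight-line Euclidean distance is available as an alternative
metric, and is the per-component fallback (with a warning) when a mask
component is unreachable from every seed — e.g. islands created by noise
in a segmentation. Tests verify exact agreement with an independent
networkx shortest-path implementation on random grids.

## Repeatability statistics

Paired measurements (second vs first acquisition) are summarized by OLS
regression of second on first (directional, matching how such pairs are
reported) with t-based 95% CIs; Spearman ρ with a Fisher-z CI
(SE = 1/√(n−3)); RMSE about the regression line (n denominator); RMSD
defined as the within-pair repeatability deviation √(Σd²/2n), which is the
single-measurement SD under pure repeat variability and satisfies
RMSD ≤ RMSE on typical data; Bland-Altman bias ± 1.96·SD(d) limits of
agreement (n−1 SD); and a two-sided Wilcoxon signed-rank test. The
Wilcoxon null distribution is exact for ≤ 25 non-zero differences — a
dynamic program over average ranks doubled to integers, so ties are
handled exactly — and a normal approximation with continuity and tie
corrections beyond; zero differences are dropped, and an all-zero input
returns p = 1 with a warning. The exact branch is verified against full
2^n enumeration, and the large-n branch holds 4.8% empirical type-I error
at n = 34, α = 0.05.

## Dosimetry

Pure arithmetic, kept explicit for auditability: scan delay =
injection/2 + 2 s; effective dose = DLP × k with the chest factor
k = 0.014 mSv/(mGy·cm); SSDE = CTDI_vol × size factor. The AAPM-204 size
factor table is *not* embedded — the factor depends on patient effective
diameter, which callers must supply.

## Problem sizes and numerical choices

Default simulations use a 64³ grid (~47k myocardial voxels, ~1 s
end-to-end); unit tests use a 40³ variant. Oracle comparisons run on
random ≤ 25³ grids (50 in the test suite, 25 in the acceptance script) —
sizes chosen so exhaustive graph oracles remain exact and fast. Statistics
simulations use n = 68 pairs × 1,000 replicates (regression) and n = 34 ×
10,000 (test calibration). Optimizer tolerances are 1e-14 (xtol/ftol/gtol)
so noiseless fits terminate at machine precision; AUC uses the incomplete
gamma function rather than quadrature everywhere in the pipeline.

## Known limitations

- Perfusion accuracy under noise inherits the conditioning of a 4-parameter
  fit to few enhanced samples; protocols whose trigger fires very early
  (large A) leave the fit under-determined and the `converged`/rss fields
  should be inspected.
- The scalar pre-contrast baseline cannot represent spatially heterogeneous
  pre-contrast attenuation.
- Territory assignment quality depends entirely on the supplied
  centerlines; no automatic centerline extraction is provided.
- The phantom makes no attempt at realistic image texture, artifacts or
  motion; it is a ground-truth generator, not an image simulator.
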