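# Methods

This note documents the models implemented in `fractalperf`, the choices
made where the published method descriptions leave room, and what the
synthetic phantom does and does not emulate.

## Blanket fractal dimension in 4D

The blanket (Minkowski-sausage) estimator surrounds the intensity
hypersurface f(i, j, k, t) with an upper and a lower envelope that expand by
one intensity unit and one morphological dilation/erosion per iteration ε.
The normalized enclosed hypervolume V(ε) = Σ(u_ε − b_ε)/2ε shrinks with ε
for rough textures; the least-squares slope of log V(ε) on log ε over
ε = 1..ε_max gives FD = 4 − slope. Implementation choices:

- **Neighborhood.** |y − x| ≤ 1 is read as the Chebyshev ball (the full 3⁴
  kernel, "diameter three in each of the four dimensions"). An axial
  (faces-only) reading is retained as `neighborhood="axial"`.
- **Initialization.** u₀ = b₀ = f, the standard blanket convention.
- **Scales.** ε_max = 4 by default (fit over ε = 1..4), configurable. Larger
  ε ranges weight coarser structure; the local-kernel maps change little
  beyond ε ≈ 4 because the kernel is only 3 voxels wide.
- **Local maps.** Blankets are propagated over the full volume; per-voxel
  V(ε) sums u − b over the centered 3⁴ kernel (replicate padding). A
  per-kernel-restricted propagation cannot support ε > 1, so global
  propagation with local summation is the only consistent reading.
- **Slope fit.** Both log ε and log V are centered before the fit, so a
  constant region yields slope exactly 0.0 and FD exactly 4.0 in floating
  point. R² of the fit is kept per voxel.
- **Intensity scale.** The blankets advance ±1 intensity unit per iteration,
  which ties FD to the intensity units of the input. `intensity_gain`
  (default 80 units per mg I/mL) maps iodine concentration onto the
  algorithm's intensity grid; it is a calibration constant fixed once
  against the phantom (below), not a physical quantity.
- **Anatomy edges.** The step edges at the endocardial and epicardial
  borders (blood pool ~+300 HU, surrounding tissue ~−40 HU) dominate the
  blankets within ε + 1 voxels of the wall and would drive segment FD far
  below 4. Before FD mapping, voxels outside the myocardium are therefore
  replaced by their nearest myocardial value (`fill_outside_mask`), which
  removes the anatomy edges and leaves in-wall texture untouched. This
  corresponds to reading FD maps on the myocardium only.
- **Temporal window.** Tissue enhancement keeps growing through a
  washout-free first pass, so late frames carry ever larger texture
  amplitude and, through the 4D blankets, depress FD read-outs at earlier
  frames. The pipeline computes the FD map on the first-pass crop (frames
  up to the AIF peak + 2) and collapses it over the peak window (the last
  three frames of the crop) by arithmetic mean. A plain all-frame mean is
  available as `fd_collapse="all"`; it dilutes the read-out with
  pre-contrast frames whose FD is essentially the noise floor.

## Maximum-upslope blood flow

MBF = max dC_tissue/dt ÷ max C_arterial × 6000, in mL/100 mL/min; the
factor 6000 converts a per-second fractional uptake to per-100-mL-per-min.
Choices:

- The upslope search is restricted to the first pass (bolus start to AIF
  peak + 2 frames) to exclude recirculation.
- A centered 3-point moving-average smoother is available but **off by
  default**: at 1 s sampling it systematically underestimates the peak
  slope of a smooth gamma-variate by ~3%, which is larger than the noise
  it removes once curves are ROI-averaged.
- Segment MBF is estimated from the ROI-mean tissue curve, not from the
  ROI-mean of the voxelwise map: maximizing noisy per-voxel differences is
  biased upward, while averaging first is unbiased and identical in the
  noise-free limit. The voxel map is still produced for display.
- The AIF ROI is eroded by the same 1 mm margin as myocardial ROIs before
  curve extraction. The spatial filters mix blood-pool boundary voxels with
  surrounding tissue; without the margin the AIF peak drops ~10% and every
  MBF inflates correspondingly.
- Remote flow is the highest included segment MBF (excluded segments are
  ineligible); relative MBF divides by it, so exactly the remote segment
  attains 1.0 (ties break to the lowest segment index).

## Preprocessing

- 3×3×3 median filter per frame, then a bilateral filter per frame with
  σ_domain = 2 voxels and σ_range = 1.96 × SD of unenhanced LV myocardium.
  Filters act on the spatial dimensions only; temporal filtering would
  distort the upslopes. The bilateral kernel is truncated at 2σ_domain.
- "Unenhanced" frames are detected as those before bolus arrival on the
  mean curve of the top-1% enhancing voxels (arterial blood enhances first);
  at least the first frame is always used.
- HU → mg I/mL is linear: (HU − per-voxel baseline)/slope, with slope
  25 HU/(mg I/mL) at 80 kV and 30 at 70 kV. These slopes are documented
  calibration constants of the conversion model, configurable per scanner.

## AHA segment machinery

Segments follow the 17-segment model; the conventional coronary assignment
is LAD {1, 2, 7, 8, 13, 14, 17}, RCA {3, 4, 9, 10, 15},
LCX {5, 6, 11, 12, 16}, overridable in configuration. ROIs keep ≥ 1 mm from
the endo/epicardial borders via erosion of the myocardium mask by
ceil(margin/spacing) voxels per axis, intersected with each segment so that
segment–segment borders are preserved. A segment is excluded when a
delayed-enhancement mask covers ≥ 25% of it (the published rule states only
"showing" enhancement; the fraction is configurable); vessels with all
segments excluded and patients with all vessels excluded cascade.

## Classification and statistics

Segment FD: obstructive ≤ 4.31 < microvascular ≤ 4.41 < normal (boundaries
inclusive on the diseased side). Relative MBF ≤ 0.674 is positive for
obstructive CAD. Vessel class is the most severe included segment; the
vessel ROC score is the worst (minimum) segment statistic — the mean is a
config alternative. Patient class takes precedence obstructive >
microvascular > normal; for the binary relative-MBF method any positive
vessel makes the patient positive.

Statistics: Clopper–Pearson exact intervals for proportions (percentages
rounded half-away-from-zero to integers for reporting); Mann–Whitney AUC
with DeLong variance and the paired DeLong test (validated to 1e−6 against
an independent R implementation on a frozen fixture); McNemar's chi-square
without continuity correction by default (correction available); Youden
cutoffs scan observed score values under the "≤ cutoff positive" rule with
ties broken toward higher specificity; Cohen's κ with asymptotic CI.
Remote-flow strata use sample tertiles (ties to the lower group) or the
published preset (low ≤ 135, high ≥ 172 mL/100 mL/min).

## The synthetic phantom

The phantom emulates a ~30 s dynamic stress acquisition at one frame per
second: a gamma-variate AIF (peak 12 mg I/mL, onset 3 s, time-to-peak 6 s,
i.e. a compact first-pass bolus), a digital short-axis LV (hollow cylinder,
outer radius 18 mm, wall 8 mm, ellipsoidal apex cap) with analytic AHA
labels, and cumulative-uptake tissue curves C(x, t) = MBF(x)/6000 ∫₀ᵗ AIF,
discretized left-rectangle so that the sampled maximum upslope encodes the
true flow exactly. Iodine maps to HU at 25 HU/(mg I/mL) (80 kV); i.i.d.
Gaussian HU noise is added. All randomness derives from one seed.

Ground-truth flow is base territory flow (default 160 mL/100 mL/min at
stress) times two multiplicative fields:

- **Physiological texture** (all myocardium): a white-spectrum symmetric
  Gaussian field, relative SD 0.5, clipped at 5% of the mean. Real
  myocardial flow heterogeneity is scale-invariant with large relative
  dispersion at small aggregates; its amplitude scales with local flow,
  which is exactly the signal the blanket FD reads. The symmetric (not
  log-normal) form keeps local median = local mean, so the median filter
  does not bias ROI-mean flow.
- **Ischemia pattern** per territory: obstructive = uniform ×0.4 (optional
  endo→epi gradient); microvascular = spatially correlated log-normal
  reduction, mean ×0.65, relative SD 0.2, correlation length 6 mm — patchy
  and irregular rather than uniform.

A per-voxel bolus arrival jitter (SD 0.6 s) adds flow-scaled *temporal*
texture that spatial denoising cannot remove, emulating transit-time
dispersion.

**Calibration.** Voxel size (0.75 × 0.75 × 1.5 mm), texture dispersion,
arrival jitter, noise SD (1.5 HU) and `intensity_gain` were fixed once, as
a set, so that after the full pipeline the territory-mean FD of the three
conditions lands inside the three published cutoff bands
(obstructive ≈ 4.22, microvascular ≈ 4.34, normal ≈ 4.44) and segment MBF
is recovered with ~2–3% median error. The FD *ordering*
obstructive < microvascular < normal is robust across seeds; the absolute
cutoff placement is a property of this calibration, not evidence about
clinical data. Segment-level FD spreads ±0.05 around the territory means,
so worst-segment vessel calls land one band lower than the territory mean
in a minority of vessels — on phantom cohorts, threshold-free scores (AUC)
or cohort-derived Youden cutoffs are the right operating points.

**What the phantom does not emulate:** CT noise spectra and beam hardening,
cardiac/respiratory motion and registration error, shuttle-mode frame
timing (uniform 1 s intervals stand in for every-other-heartbeat sampling;
jitter is configurable), washout/recirculation (uptake is cumulative),
partial-volume blur at borders beyond the voxel grid itself, and any
anatomical variability of the LV or of coronary territories. Passing
phantom tests therefore demonstrates internal consistency of the pipeline
and the separability mechanism, not clinical performance.

## Degenerate inputs and numerical conventions

Non-finite volumes, non-monotone frame times, empty masks and
single-class ROC inputs raise `InvalidInputError`; a noise-free baseline
(zero SD) raises `DegenerateInputError` with guidance to set σ_range
explicitly; converting an already-converted volume raises `UnitError`.
Empty post-erosion ROIs are flagged, not errors. All filters and blankets
use replicate padding. Voxel indexing is 0-based; world coordinates live in
the NIfTI affine. Volumes are written as NIfTI-1 with a JSON sidecar for
frame times, kV and intensity unit.

## Known limitations

- FD depends on the intensity gain and on the temporal read-out window;
  both are documented calibration constants here, whereas a clinical
  deployment would fix them against scanner-specific reference data.
- The cumulative-uptake tissue model is only valid through the first pass;
  analyses beyond the AIF peak window require a washout term.
- The phantom's cutoff-band placement is calibrated, so phantom-based
  contingency tables at the published cutoffs understate the separation
  that the ordering and AUC results show.
- Vessel-level score reduction (minimum vs mean segment statistic) is not
  uniquely determined by the published description; the minimum is the
  default here.
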