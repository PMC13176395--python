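# Methods

`respigate` is a simulation-testable toolkit for respiratory gating of PET
list-mode data. It covers the full chain: breathing-waveform synthesis,
breath-cycle detection, list-mode event simulation, two quiescent-period
gating algorithms, breathing-regularity metrics (tvar, overlap fraction,
spectral R value), a motion-blurred image-quality phantom, NEMA-style image
metrics (CR/BV/CNR, liver SNR, SUVmax), and a multi-arm statistical
comparison harness. This note records the models, the defaults and why,
the numerical choices, and the limits of what the simulations demonstrate.

## Breathing-waveform model

A trace is a uniformly sampled (default 25 Hz) superior–inferior
displacement in mm; larger values are inspiration, and cycle minima are
end-expiration — the quiescent part of the breath. The simulator
concatenates single-breath pulses:

- Cycle period `T_i ~ Normal(mean_period, period_jitter_sd)`, truncated
  below at `0.5·mean_period` (no non-physical ultra-short breaths).
- Breath depth `A_i ~ Normal(amplitude, amplitude_jitter_sd)` truncated at
  0; `amplitude` is the half peak-to-peak excursion, default 15 mm, i.e. a
  ±15 mm motion about the mid-position — the conventional platform setting
  for abdominal-organ motion studies.
- Within a cycle the displacement rises from 0 to `2·A_i` over a **fixed
  inspiratory time** `insp_fraction·mean_period` (default 0.4) as a
  raised-cosine half-wave and falls back over the remainder of the cycle.
  Putting all period variability into the expiratory limb mirrors real
  breathing, where inspiratory duration is comparatively stable and the
  expiratory phase/pause stretches; it also means consecutive inspiration
  peaks are spaced exactly one cycle period apart, so a peak-based cycle
  segmentation recovers the injected period statistics without bias. A
  mid-cycle-peaked `symmetric_cosine` and a `triangular` shape are
  available behind the `shape` flag.
- Per-sample white measurement noise (`noise_sd`) and a random-walk
  baseline drift (`baseline_drift_sd`) are added last.

Two presets define the study conditions: `TYPICAL_WAVEFORM` (period jitter
0.15 s, depth jitter 0.5 mm, light noise) and `IRREGULAR_WAVEFORM` (period
jitter 1.0 s, depth jitter 3 mm), both 4 s mean period, ±15 mm, 360 s.

What the generator does **not** emulate: hysteresis (inhale/exhale paths
identical by construction), apnoea episodes, baseline shifts from bulk
patient motion, and the spectral colour of real tracker noise. Passing
tests therefore demonstrate algorithmic correctness and the direction of
physical effects, not clinical performance on patient waveforms.

## Cycle detection, segmentation and tvar

Inspiration peaks are local maxima with a minimum prominence (default 20%
of the trace dynamic range, to exclude noise and artifacts) and a minimum
spacing of 10 ms. The 10 ms spacing is kept literal even though it is far
smaller than any breath — prominence does the real filtering; a 1 s
`SANITY_MIN_PEAK_DISTANCE` preset exists but is never applied silently.
A flat trace yields an empty peak list ("no respiration detected") rather
than an error.

Cycles span consecutive peaks (half-open `[peak_i, peak_{i+1})`), so the
end-expiration trough is interior to the cycle — the natural anchor for
amplitude-driven gating — and cycle durations are the inter-peak
intervals, the same quantity a trigger-based gating system measures.
`min_amp_time` is the lowest-amplitude sample in the cycle, ties broken
toward the earlier sample.

`tvar` is the dispersion of cycle durations over a scan. The default mode
is the **sample standard deviation** (units s); a `var` mode (s²) is
provided because both conventions appear in practice, and every report
states the mode used. tvar is invariant to amplitude scaling and time
translation, needs at least two cycles, and recovers the injected period
jitter of the simulator to well within ±30% at ~100 breaths.

## Gating methods

Both methods retain a target duty fraction (default 0.5: half the counts,
the standard quiescent-period compromise between noise and motion).

**Method 1 — fixed-offset quiescent-period gating.** Every cycle retains
the same phase window `[offset, offset+duty)` (defaults 0.3 and 0.5) of
the cycle. The window is anchored to the inspiration-peak trigger and its
placement never adapts to the waveform amplitude — the defining property
of fixed-offset gating. By default the fractions apply to each cycle's own
duration, which keeps the retained fraction of in-cycle time exactly at
the duty setting for any breathing pattern; a `scan_mean` variant places a
fixed absolute window `offset·T̄` to `(offset+duty)·T̄` (scan-mean period
T̄) clipped to the cycle, which under-retains on short cycles and is kept
for comparison.

**Method 2 — cycle-specific amplitude-driven gating.** Each gate seeds at
the cycle's minimum-amplitude sample and grows one trace sample at a time
toward whichever neighbouring sample has the lower amplitude (ties to the
earlier side), stopping at the first window that holds at least the duty
fraction of that cycle's counts. The stopping rule can overshoot by at
most one sample's counts, and the achieved scan-level fraction is always
reported. On unimodal cycles this greedy expansion provably returns the
minimal contiguous window containing the minimum (fewest samples, then
lowest maximum amplitude, then earliest start), which the test suite
verifies against an exhaustive search. An `amplitude-threshold` variant
(retain the lowest-amplitude samples regardless of contiguity) sits behind
the `mode` flag. A cycle with no events contributes an empty window and a
logged warning. The 50% target is enforced per cycle — the gate is defined
cycle by cycle — and the scan-level fraction is reported for verification.

**Edge handling.** Both methods also gate the partial breaths before the
first and after the last detected peak (Method 1 extrapolates the window
of the unobserved edge cycles using the scan-mean period; Method 2 treats
the edge segments as partial cycles). Without this, scan-edge data is
systematically discarded and the scan-level retained fraction undershoots
the duty setting by 1–2 percentage points on a 120 s acquisition;
`include_edges=False` restores the strict per-detected-cycle behaviour.

With the default offset, both methods straddle end-expiration on a regular
breather and select nearly the same counts. Under period jitter the trough
drifts in phase relative to the fixed window, the two selections diverge,
and within-gate residual motion grows faster for Method 1 — the mechanism
behind the two headline behaviours the suite checks: the overlap fraction
falls with tvar, and Method 2 leaves less residual displacement on
irregular breathers.

**Overlap** is the number of events retained by both methods divided by
the geometric mean of the two retained counts — symmetric, in [0, 1],
equal to `intersection/|A|` for equal-size selections, and still defined
when duty fractions differ.

**R value.** The exact commercial formula for the respiration-trigger
metric is not public, so the package defines a documented surrogate: R is
the percentage of total (DC-excluded) periodogram power carried by the
single strongest bin in the respiration band (0.1–0.4 Hz). A coherent
breathing signal concentrates power in one line and scores far above the
clinical trigger threshold (kept at R > 15); broadband noise spreads power
over hundreds of bins and scores near zero. A ratio-to-median surrogate
was rejected: the maximum of tens of exponentially distributed periodogram
ordinates sits hundreds of percent above their median even for pure noise,
which would make a fixed threshold meaningless. Traces must be ≥ 30 s for
usable spectral resolution.

## Phantom and reconstruction-arm emulation

The image-quality phantom is a simplified body: a cylinder (default radius
150 mm, length 160 mm) of unit background activity holding six coplanar
hot spheres (10, 13, 17, 22, 28, 37 mm diameter; 4:1 contrast) on a
57.2 mm ring, on a 2.7 mm isotropic voxel grid with a 5 mm FWHM Gaussian
PSF. The true phantom shell, lung insert and elliptical cross-section are
deliberately omitted; sphere and ROI positions are configurable. The body
radius is larger than the physical phantom so that twelve background ROIs
of every sphere diameter fit on a ring with ≥15 mm clearance from the
spheres and the body edge.

Motion and counts are emulated in image space:

1. **Residual displacement pdf** — the histogram (bin width = half a
   voxel) of trace amplitude over the retained samples (all samples when
   ungated). Its spread is the residual motion left by a gate.
2. **Motion blur** — 1-D convolution of the volume with the mean-centred
   pdf along the motion axis (default z). Mean-centring makes gating
   change blur *width*, not image *position*; registration/attenuation
   mismatch is out of scope. The grid carries a 20 mm axial margin so blur
   never pushes activity off-grid, and activity is conserved to <0.1%.
3. **Count noise** — voxel activities are scaled to expected counts
   (`activity × budget × retained_fraction × counts_per_unit`, default
   100 counts per unit activity per voxel, chosen to put background
   variability in the few-percent range typical of IQ-phantom scans),
   Poisson sampled, and rescaled (unbiased). `counts_per_unit=None` gives
   the noiseless limit.

Reconstruction-algorithm differences (BSREM vs OSEM vs deep-learning
enhancement) are **not** modelled. Arms differ only in count budget,
gating, and an optional post-smoothing FWHM standing in for a denoising
enhancement, so the six study arms map onto four physically
distinguishable configurations; `six_study_arms()` documents the mapping.

## Image-quality metrics

Per sphere j: `CR_j = ((C_H/C_B − 1)/(a_H/a_B − 1))·100`,
`BV_j = (SD_j/C_B)·100`, `CNR_j = CR_j/BV_j` (reported as undefined, not
infinity, when BV = 0). Hot ROIs are circles of the sphere's inner
diameter on its central slice; `C_B` averages the twelve same-diameter
background ROI means. `SD_j` is by default the SD **across** the twelve
ROI means (the NU-2 convention); a `voxelwise` mode pools all
background-ROI voxels instead, and is the right choice when a single
realisation must estimate the noise level tightly (the √2 count-scaling
checks use it). Liver-like noise is mean/SD over a 30 mm spherical VOI in
the uniform background, `SNR = mean/SD`; SUVmax is the maximum voxel in a
lesion VOI, in activity-relative units (no dose/weight normalisation
exists in the simulator).

## Statistical comparison harness

`run_experiment` sweeps waveforms × repeats (default 3 repeats, matching
the acquisition protocol it emulates), simulates every scan and arm fully
seeded (per-condition sub-seeds from one `SeedSequence`), and aggregates
per-scan regularity metrics and per-arm IQ tables. The comparison
procedure is: Kruskal–Wallis omnibus per metric; pairwise tests only when
the omnibus is significant at 0.05 (gatekeeping, disable-able) —
Wilcoxon signed-rank (exact below n=25 when there are no zero
differences) for ordinal-like metrics and SUV, paired t for liver noise;
Bonferroni adjustment `min(1, p·m)` with the family defaulting to all
pairs tested (15 for six arms). The procedure's type-I error is the
omnibus rejection rate, calibrated to 5% ± 2% under the null in the
acceptance suite; gatekept Bonferroni pairwise claims are strictly more
conservative. OLS of overlap on tvar reports slope and R²; stratification
splits scans at tvar 1.5 with boundary values assigned to the regular
cohort.

## Problem sizes used by the test and acceptance runs

Retention and overlap checks use 120 s scans at 1000 events/s (~1.2×10⁵
events); tvar recovery uses 200 seeds of ~105 breaths; the greedy-window
oracle check uses 1000 random unimodal cycles of 5–40 samples; phantom
checks use the default ~115×115×78 grid with 20 seeds per count budget;
null calibration uses 1000 replicates of 4 arms × 15 observations. These
sizes make every Monte-Carlo tolerance in the suite comfortable while
keeping a full run in tens of seconds.

## Known limitations

- Event displacement is 1-D; no sinogram/projection physics, scatter,
  randoms, attenuation or decay.
- Gating quality is bounded by peak detection; traces whose prominence
  structure defeats the 20%-of-range default need an explicit threshold.
- The tvar/overlap magnitudes of the simulator are not calibrated to any
  particular commercial tracker; cross-study comparisons should rely on
  ordering and trends, not absolute values.
- The R surrogate shares only the band and threshold semantics with
  vendor implementations, not the numeric scale.
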