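# respigate

Respiratory motion blurs PET images: a lesion that moves ±15 mm with the
breathing cycle is smeared over its excursion, lowering apparent uptake and
contrast. Quiescent-period gating answers this by keeping only the counts
acquired near end-expiration — typically half the data — at the cost of
noisier images. `respigate` is a toolkit for studying that trade-off. It is
aimed at PET physicists and methods researchers who want to compare gating
algorithms and acquisition protocols quantitatively without scanner time:
every input (breathing traces, list-mode events, phantom volumes) can be
simulated, seeded, and scored.

## What it implements

**Gating.** Two quiescent-period methods operating on detected breath
cycles (inspiration-peak to inspiration-peak):

- *Method 1, fixed-offset gating*: every cycle retains the same phase
  window `[offset, offset + duty)` (defaults 0.3 and 0.5), anchored to the
  breath trigger and blind to the waveform amplitude.
- *Method 2, amplitude-driven gating*: each gate seeds at the cycle's
  amplitude minimum and greedily expands toward the lower-amplitude
  neighbour until it encompasses the duty fraction (default 50%) of that
  cycle's counts.

**Breathing-regularity metrics.**

- `tvar` — the standard deviation of cycle durations over a scan;
- *overlap* — the fraction of counts selected by both gating methods
  (geometric-mean normalised), near 1 for metronomic breathing and falling
  as breathing becomes irregular;
- *R value* — a spectral respiration metric (in-band peak power fraction)
  with the clinical trigger rule R > 15.

**Image-quality pipeline.** A NEMA-IQ-style phantom (six hot spheres
10–37 mm at 4:1 contrast in a warm cylinder) rendered with a Gaussian PSF,
blurred along the motion axis by the residual displacement distribution of
the retained data, and Poisson-resampled at an arm-specific count budget.
Scoring follows the NU-2 conventions:

```
CR_j  = (C_H/C_B − 1)/(a_H/a_B − 1) × 100   [%]
BV_j  = SD_j / C_B × 100                    [%]
CNR_j = CR_j / BV_j
SNR   = mean(VOI) / SD(VOI)                 (30 mm liver-like VOI)
```

**Comparison harness.** Sweeps waveforms × repeats × reconstruction arms
with full seeding, then applies Kruskal–Wallis omnibus tests, gatekept
Wilcoxon/paired-t pairwise comparisons with Bonferroni correction, an
overlap-on-tvar regression, and a tvar-threshold stratification (1.5,
boundary to "regular").

See `docs/methods.md` for the models, defaults, and limitations.

## Worked example

```python
import respigate as rg

params = rg.WaveformParams(mean_period=4.0, period_jitter_sd=1.0,
                           duration=120.0, seed=42)
trace = rg.simulate_trace(params)                      # irregular breather
events = rg.simulate_events(trace, rate=1000.0, seed=43)
cycles = rg.analyze_trace(trace)
print(f"{cycles.n_cycles} breaths, tvar(sd) = {cycles.tvar:.2f} s")

m1 = rg.gate_method1_qpg(cycles, events)
m2 = rg.gate_method2_adaptive(cycles, trace, events)
overlap = rg.compute_overlap(m1, m2, events)
r = rg.compute_r_value(trace)
print(f"Method 1 retained {m1.retained_fraction:.1%}, "
      f"Method 2 retained {m2.retained_fraction:.1%}")
print(f"overlap = {overlap.overlap:.3f}, R = {r.r:.1f} "
      f"(gating triggered: {r.passes_threshold})")

spec = rg.PhantomSpec()
arm = rg.ReconArmSpec("method2_gated", gating="method2")
volume = rg.simulate_arm(spec, trace, events, arm, gate_mask=m2, seed=7)
print(rg.analyze_image_quality(volume, spec, arm=arm.label)
      .table.round(2).to_string(index=False))
```

prints

```
29 breaths, tvar(sd) = 0.79 s
Method 1 retained 50.1%, Method 2 retained 50.5%
overlap = 0.940, R = 31.2 (gating triggered: True)
          arm  sphere_mm    CR   BV   CNR
method2_gated       10.0 30.06 3.42  8.80
method2_gated       13.0 42.35 2.39 17.72
method2_gated       17.0 55.40 2.75 20.17
method2_gated       22.0 70.32 1.92 36.59
method2_gated       28.0 76.82 1.23 62.36
method2_gated       37.0 86.06 1.33 64.70
```

Both gates kept half the counts on a visibly irregular breather
(tvar 0.79 s); the strong in-band breathing signal (R = 31 > 15) would
trigger gating clinically, and the two methods still selected 94% of the
same counts. In the gated reconstruction, contrast recovery climbs from
~30% for the 10 mm sphere (partial-volume dominated) to ~86% for the
37 mm sphere, with background variability of 1–3.5%.

The same pipeline is scriptable from the shell (`respigate
simulate-trace`, `simulate-events`, `cycles`, `gate`, `overlap`,
`phantom-sim`, `iq-analyze`, `compare`); `respigate --help` lists the
commands.

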