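# flowdissect

Vessel-diameter-resolved analysis of sensory-evoked cerebral blood flow,
combining depth-resolved OCT angiography (OCT-A) with a concurrent diffuse
correlation spectroscopy (DCS) flow channel.

## What it does

Diffuse optical flow monitors (DCS) report a single blood-flow waveform from
a large tissue volume; OCT-A resolves flow vessel by vessel. To ask *which
vessels a diffuse signal actually represents*, this package implements the
full computational chain used to dissect stimulus-evoked cortical blood
flow by vessel caliber:

1. **Angiography** — repeated complex B-scans (32 per composite frame) are
   collapsed to a flow-contrast image by the average absolute difference of
   consecutive repeat magnitudes, `(1/(N-1)) Σ | |Sᵢ₊₁| − |Sᵢ| |`; static
   tissue cancels, flowing blood decorrelates and lights up. Optional
   subpixel axial motion correction and depth-ROI cropping.
2. **Segmentation** — multilevel Otsu thresholding plus connected-component
   sizing splits the angiogram into vessel classes by equivalent-circle
   diameter: small (< 10 µm), medium (10–20 µm), large (> 20 µm); the small
   class is the non-zero-flow area that overlaps no resolved vessel.
3. **Response extraction** — masked per-frame sums, normalized to the
   pre-stimulus baseline (first ~4 s), averaged over the 10 stimulus
   presentations of a trial.
4. **Response modeling** — each evoked waveform is fit (bounded
   least squares, multi-start) with the canonical double-gamma hemodynamic
   response function

   HRF(t) = A ( t^{α₁−1} β₁^{α₁} e^{−β₁ t} / Γ(α₁) − c · t^{α₂−1} β₂^{α₂} e^{−β₂ t} / Γ(α₂) ),

   gated at R² > 0.9, and summarized by peak/undershoot amplitudes, times
   and baseline-crossing-delimited integrals.
5. **En-face survey** — the coarse 25×25×65-frame response video used to
   locate the activation centroid.
6. **Group statistics** — per-condition means ± SD across animals,
   Kolmogorov–Smirnov normality checks, two-tailed paired t-tests, and
   Pearson correlation of DCS against per-class OCT-A waveforms on a common
   time grid.

Because raw in-vivo recordings of this kind are not public, the package
ships a first-class **synthetic acquisition generator**: static speckle
parenchyma with embedded vessel cross-sections whose inter-repeat
decorrelation scales with instantaneous flow, flow driven by known
double-gamma ground truth, the exact trial structure (65 composite frames
over 30 s, stimulus at 5 s for 4 s, frames ~11–20), and a 4.4-Hz diffuse
channel sharing the response. Every pipeline stage is tested against this
known ground truth; see `docs/methods.md` for the forward model and its
limits.

## Worked example

```python
import numpy as np
import flowdissect as fd

protocol = fd.make_protocol()                 # 65 frames / 30 s, stim at 5 s
resp = fd.design_response(2.19, 0.86)         # 2.19 % peak, 0.86 % undershoot

# noise-free evoked waveform on the composite-frame grid
w = fd.FlowWaveform(times=protocol.frame_times,
                    values=1 + resp.curve(protocol.frame_times - 5.0),
                    baseline_window=protocol.baseline_window,
                    stim_window=protocol.stim_window)
fit = fd.fit_hrf(w)
m = fd.quantify_response(fit)
print(f"R2={fit.r_squared:.3f} peak {m.peak_amplitude:.2f}% at "
      f"{m.peak_time:.2f}s, undershoot {m.undershoot_amplitude:.2f}% at "
      f"{m.undershoot_time:.2f}s")
```

prints

```
R2=1.000 peak 2.19% at 7.30s, undershoot -0.86% at 15.00s
```

i.e. the fit recovers the designed response exactly: a 2.19 % relative-flow
peak 7.3 s after stimulus onset followed by a 0.86 % undershoot at 15 s.
The full simulated experiment (11 animals × 10 presentations through
angiography, segmentation, extraction and fitting) is one call:

```python
group = fd.run_group_experiment(seed=1)
print(group.grand_mean("small", "peak_amplitude"))   # ~2.0 (% rel. flow)
```

A command-line surface wraps the same stages
(`flowdissect simulate|angio|segment|extract|fit|survey|correlate|run|report`);
`flowdissect run --out results/` writes a full results bundle (metric,
group-summary and correlation tables plus the config snapshot).

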