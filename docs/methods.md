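# Methods

This note documents the models, conventions and design choices behind
`flowdissect`: what the pipeline computes, what the synthetic generator
emulates, and where the genuinely open choices were settled.

## Acquisition model

All timing flows from one `AcquisitionProtocol` (defaults in parentheses):
a 30-s acquisition per stimulus presentation; a train of 12 electrical
pulses at 3 Hz (4 s) starting 5 s in; 65 composite frames at 0.46 s/frame,
each built from 32 repeated B-scans; a diffuse (DCS-like) channel at 4.4 Hz
(132 samples); 10 presentations per trial. Frames are timestamped at their
centers, `(i + 1/2) · 0.46 s` — the acquisition does not define a
convention, and centers minimize the worst-case timing error. The first 9
frames (~4 s) are the normalization baseline. With frame starts indexed
from 0, the stimulus spans frames 11–19, conventionally reported 1-based as
"frames ~11 to 20".

## Angiogram contrast

The angiogram is the average absolute difference of consecutive repeat
magnitudes. "Average absolute difference over all B-scans of a set" is
ambiguous between adjacent pairs and all N(N−1)/2 pairs; adjacent pairs are
the default (standard in speckle-variance processing, O(N) cost), and an
all-pairs mode is available (`pairs="all"`) for sensitivity analysis.
Differences are taken between magnitudes, `| |S₂| − |S₁| |`, not magnitudes
of complex differences. The contrast is invariant to a global magnitude
offset and scales linearly with gain, so only baseline-normalized relative
flow is ever interpreted.

Axial motion correction estimates one axial shift per repeat from the
cross-correlation of laterally averaged depth profiles against the first
repeat, refines the peak by quadratic interpolation, clips shifts to ±10 px,
and applies them by linear interpolation to the real and imaginary parts.
All-zero repeats get a zero shift and a warning. It is off by default for
synthetic data (no drift is simulated by default).

## Vessel segmentation

Masks are built once from the time-averaged baseline angiogram (all
presentations, frames 0–8) and then applied to every frame: the per-frame
alternative exists (`segment_vessels` on any frame) but temporal response
extraction requires fixed masks to be meaningful, and the averaged baseline
has far better contrast statistics.

Three-class Otsu thresholding (256-bin histogram) yields a lower and an
upper threshold. Pixels above the upper threshold are resolved vessel
cores; 8-connected components are sized by equivalent-circle diameter
`d = 2·sqrt(area·px²/π)` (cross-sections are compact punctae, so an
equivalent circle fits better than a caliper width) and binned as medium
(10 ≤ d ≤ 20 µm, closed interval so edge ties resolve into medium) or
large (d > 20 µm). The small class is everything above the *lower*
threshold — a noise-floor gate standing in for "non-zero flow", since
detector noise makes literal zero meaningless — that does not touch the
resolved masks. A guard ring (binary dilation of medium ∪ large, default
2 px) is excluded from the small mask: a resolved vessel's partial-volume
halo reaches ~0.5 px beyond its disk, and with only a 1-px ring those halo
pixels leak a measurable fraction (~16 % in a dedicated test) of a large
vessel's response into the small-class waveform. A quantile-based gate
(`min_flow_quantile`) is available instead of the lower Otsu threshold.
Constant or empty frames yield empty masks with a warning.

## Response extraction and fitting

Per class and frame, angiogram values inside the mask are summed; each
presentation's 65-point series is divided by its mean over the baseline
window (per trial and class — normalization is idempotent and gain-
invariant), presentations are averaged pointwise (SEM retained), and the
grand waveform is fit with the double-gamma response

    HRF(t) = A [ g(t; α₁, β₁) − c · g(t; α₂, β₂) ],

`g` a gamma density, on the post-onset segment only, in percent change
(`(value − 1)·100`) with `t` re-referenced to stimulus onset. Axis
conventions (post-onset, percent) are not dictated by the data and are
configurable at the waveform level.

Double-gamma least squares is multimodal, so fits start from a small grid
(α₁ ∈ {3, 6}, α₂ ∈ {8, 12}, β = 1 s⁻¹, c ∈ {0.2, 0.8}, A from the observed
maximum scaled by the start's peak height) and the best R² wins. Bounds
keep the curve zero at onset and finite: A > 0, c ∈ [0, 5], α ∈ (1, 30],
β ∈ (0, 10] s⁻¹; the bounded trust-region-reflective solver is used (the
classical Levenberg–Marquardt iteration does not accept bounds; on interior
solutions the two coincide). R² = 1 − SS_res/SS_tot over the fitted segment
only, and a fit is *accepted* only if R² > 0.9; unaccepted waveforms are
excluded from group metrics, mirroring the standard fit-quality criterion
for this kind of data.

Metrics come from a dense 1-ms evaluation of the fitted curve on
[0, t_max = 25 s]: peak and undershoot as the extrema, lobe boundaries as
baseline crossings located by sign change plus bisection, and lobe areas by
trapezoidal integration split at the crossings (metrics shift < 1e-4 when
the grid is refined to 0.1 ms). If the curve never goes negative the
undershoot fields are null and the negative integral is 0. Undershoot
amplitudes are stored signed (negative) and reported as magnitudes in
summary tables.

## En-face survey

Per B-scan location: average angiogram frames over presentations; sum
pixels in 10 (width) × 100 (depth) blocks, reducing 250 A-scans to a
25-vector (block summation conserves total signal); normalize each of the
65 vectors elementwise to the mean of the first nine; expand the 10 coarse
locations to 25. The expansion method is unspecified in the source
procedure; linear interpolation at uniform coordinates is the default, with
a nearest-neighbor mode. Baseline frames average to exactly 1 per pixel by
construction.

## Statistics

Group summaries use sample SD (n−1), a one-sample Kolmogorov–Smirnov
normality check on standardized values, and two-tailed Student's t-tests
against the 1-mA reference condition — paired within animal by default,
since every animal is measured at every current (`paired=False` available;
which variant the original analysis used is not stated). No multiple-testing
correction is applied by default. Degenerate cases (zero variance,
identical samples) are flagged rather than tested. DCS-vs-OCT-A agreement
is the Pearson correlation of the full 30-s waveforms after linearly
resampling the 4.4-Hz diffuse channel onto the 65 composite-frame centers —
the coarser grid is the target so no OCT-A samples are invented.

For correlation-recovery studies, pairs with a prescribed population
correlation ρ are built as signal-plus-noise with
`σ² = var(signal)·(1/ρ² − 1)`, divided by the variance fraction that
i.i.d. noise retains under linear resampling (`(1−w)² + w²` averaged over
the target grid); the construction is verified by brute-force simulation in
the test suite.

## Synthetic data: what it emulates, and what it does not

Each pixel's complex signal per repeat is

    S_r = (1 − cov)·P + Σ_v cov_v · d_v · flow_v · w_{v,r} + σ_n · n_r

with `P` a static complex speckle field (fixed per scene), `cov` the
subpixel disk coverage (4×4 supersampling), `d_v` the vessel's baseline
decorrelation amplitude, `w_{v,r}` unit circular complex Gaussian speckle
redrawn every repeat (blood speckle fully refreshed between repeats), and
`n_r` circular complex detector noise. The expected angiogram value inside
a vessel grows as `sqrt((cov·d·flow)² + σ_n² + …)` — monotone in flow and,
away from the noise floor, locally *proportional* to it, so the
baseline-normalized masked sum is a faithful relative flow measure (local
log-slope `σ_d²/(σ_d² + σ_n²) ≈ 0.98` at defaults). An earlier candidate —
partial re-mixing of the vessel field with rate m(flow) = 1 − exp(−k·flow) —
was rejected because its contrast grows like sqrt(m), capping the readout's
local log-slope at 0.5 for every k and thus systematically halving
recovered amplitudes.

Ground-truth flow is `1 + HRF_true(t − onset)` per vessel, with
`design_response(peak %, undershoot %, t_peak, t_under)` solving
numerically for double-gamma parameters whose dense-grid extrema match the
request (α₁ = 8, α₂ = 12 fixed; β₁, β₂, c, A solved; ~0.01 s accuracy).

Generator defaults (the simulated study conditions):

| parameter | default | rationale |
|---|---|---|
| field | 100 × 250 px at 4 µm/px | 0.4-mm-deep ROI × 1-mm B-scan; axial scale set equal to lateral absent a stated depth scale |
| vessels | 200 small (6–8 µm), 18 medium (15–18 µm), 10 large (24–32 µm) disks | cortical capillary beds are dense; counts put class-sum speckle SNR in the regime where the R² > 0.9 gate accepts most animals, as it does for real class-summed B-scans |
| decorrelation amplitude | 0.45 small, 0.9 medium/large | sub-resolution vessels contribute weaker contrast, which is what lets intensity separate the small class |
| parenchyma speckle SD | 0.3 | mid-range static background |
| detector noise SD | 0.05 | ~10× below vessel contrast; sets the angiogram noise floor |
| 1-mA ground truth | 2.19/0.86 % (small), 1.30/1.50 % (medium), 0.92/1.96 % (large), 3.37/3.04 % (DCS), peak 7.3 s, undershoot 15 s | design-condition amplitudes; the 3/4-mA columns scale them with the qualitative current dependence (small-vessel and diffuse peaks grow most) |
| DCS sample noise | 0.005 | residual noise of a trial-averaged diffuse waveform; keeps fits in the R² > 0.9 regime |
| animal-to-animal scatter | ×N(1, 0.1) on response amplitude | biological variability; mean-1 so grand averages stay centered |

One "animal" is an independent scene (layout + static speckle) and seed;
group experiments default to n = 11.

**Not emulated:** physical interferometry (no k-space, dispersion, depth
roll-off or phase noise), bulk lateral motion, vessel elongation or
branching (cross-sections are disks), arterial/venous identity, photon
statistics of the diffuse channel (the g2 module is a deliberate toy:
`g2 = 1 + β·exp(−2γτ)` with γ ∝ flow index, invertible by least squares).
Passing tests therefore demonstrate the *processing chain* — contrast
formation, segmentation geometry, normalization, fitting, statistics — not
robustness to optics-level artifacts in real recordings.

Consequences worth knowing: recovered amplitudes carry a small (~2–10 %)
multiplicative attenuation from the detector-noise floor and from
partial-coverage pixels inside masks, comfortably inside the design
dispersion; the medium class, with the fewest mask pixels and mid-size
amplitudes, sits near the R² gate and is rejected more often than small or
large — a faithful consequence of the gate, not a pipeline failure.

## Problem sizes

Unit tests run on small scenes (60×80 to 80×120 px, 2–12 vessels). The
end-to-end recovery checks and `scripts/acceptance.py` simulate the full
design — 11 animals × 10 presentations × 65 frames × 32 repeats on the
100 × 250 px scene (≈4 min), the 10-location survey at one presentation per
location (≈30 s), 11 diffuse waveforms, and 200–300 correlation pairs —
sizes chosen so a complete run stays in the minutes range on one CPU while
preserving the study's sample sizes where they matter (animals,
presentations, frames, repeats).
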