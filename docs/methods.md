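# Methods

This note records the models, parameter choices and numerical decisions
behind `hybridqc`, and what the synthetic test surface does and does not
establish about real measurements.

## Forward models

**TRS.** The time-domain diffuse reflectance of a homogeneous semi-infinite
medium is evaluated with the extrapolated-boundary image-source solution
(see README for the formula). Constant prefactors are dropped: the absolute
amplitude of a photon-counting histogram depends on laser power, detection
efficiency and integration time, so every fit carries a free scale and only
the curve shape is informative. Absorption enters solely through the
Beer–Lambert factor `exp(-μa·v·t)` — an exact identity of the closed form
that the tests verify to 1e-12 relative.

The diffusion coefficient is `D = 1/(3μs′)` (absorption-independent
convention). The boundary coefficient A uses the effective-reflection
polynomial approximation in the relative index; at the default
n_tissue = 1.4 / n_outside = 1.0 it evaluates to A ≈ 3.25. The device never
publishes its tissue index; 1.4 is the accepted soft-tissue value and is
configurable.

**DCS.** The correlation-diffusion Green's function with the same boundary
treatment, Brownian dynamics only (`⟨Δr²⟩ = 6·BFI·τ`); the random-flow
variant is excluded. g₁ is normalized by its τ = 0 value. Source–detector
separations: 3.0 cm for TRS (the emulated device's stated interfiber
distance), 2.5 cm for DCS (the device does not state it; 2.5 cm is typical
for cerebral DCS probes and configurable).

**Heterogeneity.** Heterogeneous probed volumes (hematoma under cortex,
layered tissue) are mimicked by intensity-weighted mixtures
`g₁ = Σ wᵢ g₁(BFIᵢ)`. This reproduces the observable signatures — a
secondary slower decay and a non-zero tail — without claiming to be a
layered transport solution.

## Instrument model

- DTOF grid: 0–10 ns in 4096 uniform bins (~2.44 ps), resolving sub-100-ps
  IRFs while keeping convolution cheap; convolution is linear (FFT-based),
  truncated to the grid, never circular.
- IRF: unimodal symmetric Gaussian, default FWHM 0.4 ns (typical for this
  instrument class; the device IRF is not tabulated), default peak at 3 ns
  so that a pre-pulse background window of several hundred bins exists.
- DTOF noise: independent Poisson counts per bin around the convolved,
  rescaled model plus a flat background. Detector dead time, pile-up and
  gating are out of scope.
- g₂ grid: 60 log-spaced delays over 1e-7–1e-2 s, emulating a multi-tau
  correlator. Noise is zero-mean Gaussian with per-point standard deviation
  `0.5/√(count_rate·duration·channels)` — a deliberate simplification of
  full correlator-noise formulas, adequate for exercising QC thresholds but
  not for noise-spectroscopy claims. Afterpulsing is an additive
  `amp·exp(-τ/τ_ap)` term, which inflates g₂ at short delays and therefore
  any β read off the plateau.
- Averaging follows device convention (a hundred consecutive acquisitions;
  DCS additionally over detection channels), implemented as the pointwise
  mean with bookkeeping summed.

## Inverse problems

**TRS fit.** Nonlinear least squares of `scale·(model ⊛ IRF)` against the
background-subtracted counts, Poisson-weighted (σ = √max(counts,1)), with
the scale solved analytically at every iterate. Fit range: rising edge at
80% of the peak down the falling edge to 1% of the peak (the reference
practice shows this region only graphically; both bounds are arguments).
Bounded optimization: μa ∈ (0.001, 1), μs′ ∈ (1, 30) 1/cm, initialized at
(0.1, 10). A histogram whose peak is less than one decade above the mean
pre-pulse background is refused ("insufficient dynamic range") rather than
fitted: the tail slope carrying μa is unresolved and any result would be a
fiction. Wavelengths are fitted independently; μs′ is not shared.

**Hemodynamics.** Exact 2×2 solve of
`μa(λ) = ln10·[ε_HbO₂(λ)·C_HbO₂ + ε_HHb(λ)·C_HHb]` using a packaged
extinction table (standard in-vitro hemoglobin compilation, base-10
convention, cm⁻¹/M). Water and lipids are excluded — StO₂ here is a
hemoglobin-only quantity. Negative concentrations are returned as-is with a
`physical=False` flag, never clipped.

**DCS fit.** Sequential: β first, then BFI.

- β is the zero-delay intercept of the plateau (τ < 3e-7 s). The intercept
  is fitted on the √(g₂−1) scale, where the early decay is linear in τ to
  high accuracy; this keeps the estimate essentially bias-free even at high
  BFI, where a plain plateau mean under-reads β by several percent and
  propagates into the flow index. When the plateau contrast is non-positive
  (noise-dominated curves) a plain linear intercept is used instead.
- BFI is fitted (bounded, on log₁₀ BFI) to `g₁ = √((g₂−1)/β)` over the
  leading run of points with g₁ ≥ 0.3. The cutoff excludes the deep tail,
  where the √ transform turns symmetric correlator noise into a positively
  biased, heteroscedastic quantity.
- Refusal ("insufficient decay sampled"): β not estimable, β < 0.05, or
  fewer than 5 leading points above the cutoff. The β floor is this
  package's operationalization of "no resolvable coherence plateau": with
  g₂ contrast below 0.05 the normalized field correlation is undefined in
  practice, which is exactly the signature of a noise-dominated acquisition.
- Flags: BFI < 3e-10 cm²/s → "unreliable" (ergodicity bound); RMS g₁
  residual > 0.015 → "poor model agreement" (the homogeneous model misfits,
  e.g. two-component curves).

## Figures of merit and classifier

FWHM is measured between linearly interpolated half-maximum crossings.
rFWHM and ΔFWHM are the ratio and difference of DTOF and IRF widths. SNR is
the DTOF maximum over the standard deviation of the pre-pulse background
window (all bins earlier than IRF peak − 5·IRF FWHM); a zero-variance
window raises a configuration error instead of returning infinite SNR.
Dynamic range is `log₁₀(peak / max(mean background, 1))`, the 1-count floor
avoiding division by zero on clean simulations.

The g₁ **tail plateau** is estimated over the final portion of the curve
(2e-3–1e-2 s) as `√(max(m − 2·SEM, 0)/β)` with m the window mean of g₂−1.
Two choices matter here: averaging before the square root avoids the strong
positive bias `√(max(noise,0))` takes on zero-mean noise, and subtracting
two standard errors makes the estimate a lower bound, so a plateau is only
reported when resolved above the correlator noise. The window sits at the
end of the grid rather than at 1 ms because a slow *homogeneous* decay
(BFI of a few 1e-9) legitimately crosses 1 ms still above zero; a genuine
plateau from a slow second component persists to 1e-2 s.

**Secondary-decay detection** compares nested fits: one component versus
`w·g₁(BFI_fast) + (1−w)·g₁(BFI_slow)`, with presence declared when the
mixture cuts the squared residual by ≥ 50% and the slow weight is ≥ 0.15
(both configurable; no published numeric threshold exists for either).
Both models carry a free amplitude so that small errors in the β
normalization cannot masquerade as a second component, and residuals are
inverse-variance weighted when a noise level is supplied — the √ transform
otherwise lets the meaningless tail dominate the comparison.

**Classifier.** Hard failures (label `reject`): SNR < 10, dynamic range
< 3 decades, count rate below 0.5 kHz, a refused fit. Plausibility failures
(label `suspect`): β outside [0.35, 0.55], BFI outside [1e-9, 8e-8] cm²/s
or below the 3e-10 unreliability bound, tail plateau > 0.05, secondary
decay present, StO₂ outside [50, 75]%, rFWHM ≤ 1, ΔFWHM ≤ 0, DTOF peak
delay < 0.7 ns, count rate above 200 kHz (the conservative end of the
200–300 kHz saturation range). The split mirrors bedside practice: hard
failures are conditions under which no values should be reported at all;
plausibility failures mark values that exist but should be distrusted.
Every violation is enumerated in the verdict, so the label is reproducible
from the reasons alone, and improving any single metric never worsens the
label (a property the tests check).

## Case presets

Preset parameters printed in the bedside report are carried verbatim
(H0: μa = 0.14 1/cm at 687 nm, μs′ 10–12, StO₂ ≈ 67%, β = 0.49, ≥ 90 kHz;
case 3: 24 kHz; case 5: μa 0.09–0.10; case 6: μa 0.07–0.10, μs′ ≈ 6, high
StO₂; case 8: 14 kHz). All other numbers are design choices marked
`design` in each preset's provenance map, chosen so the preset robustly
exhibits its qualitative signature:

- H0's per-wavelength absorptions derive from one hemoglobin pair
  (THC ≈ 66 µM at 67% saturation) through the packaged extinction table, so
  the TRS and hemodynamic anchors are mutually consistent.
- Case 1 gives the 687-nm channel ~800 detected photons over a 2-counts/bin
  background, keeping its dynamic range well below one decade so the fit
  refusal is deterministic across seeds; its DCS runs at BFI = 2e-10,
  below the unreliability bound.
- Case 4's g₂ is afterpulsing plus noise with no decay on the correlator
  grid (component BFI 1e-4 cm²/s decorrelates before the first delay);
  at 0.3 kHz even a 20-minute integration leaves no resolvable plateau,
  exercising the "insufficient decay sampled" path.
- Case 5 adds afterpulsing (amp 0.2, τ_ap 1 µs) on a β = 0.42 curve; the
  estimated β lands near 0.6, above the plausibility window.
- Cases 6–8 are two-component mixtures (slow weights 0.25/0.5/0.2, slow
  BFI 1e-10–5e-10) producing detectable secondary decays and, for 6 and 7,
  non-zero tails.
- Cases 2 and 3 (swollen extracerebral tissue, μs′ 5–7) genuinely produce
  short DTOF peak delays (~0.45–0.6 ns), so their expected TRS verdict is
  `suspect` via the 0.7-ns delay rule — consistent with the caution that
  such acquisitions look healthy but may not sample the brain.
- Case 5 keeps the printed μa anchors (0.10/0.09); under the packaged
  extinction table those imply StO₂ ≈ 64%, so the preset's TRS verdict is
  acceptable and the case's "high StO₂" narrative is not encoded — the
  printed absorptions took priority over the qualitative saturation remark.
- DCS integration is 300 s (the 5-minute steady-state protocol) over 4
  channels.

Expected verdicts carry two reason lists: `reasons_all` (tags that must
appear at every seed) and `reasons_any` (at least one must appear) — the
marginal tail/secondary flags of cases 6–8 trade places across noise
realizations while the suspect label itself is stable.

## Synthetic cohort

`generate_cohort` samples tissue compositions at the packaged Table-2
frequencies, maps each composition to the case family that emulates it
(hemorrhage codes → 5/6-like, air → 8-like, swollen tissue → 2/3-like,
CSF → 7-like, otherwise healthy), applies 8% lognormal jitter per ROI, and
recomputes StO₂ from the jittered absorptions so the table is internally
consistent. Table values come from ground truth rather than from running
242 fits — the long table is schema plumbing, not a fitting benchmark — and
full curve bundles are generated only on request. Seeds propagate
hierarchically (cohort seed → per-ROI child seeds below 2³¹).

The packaged 121-ROI cohort fixture is *synthetic*: only the published
marginal counts (23:98 surgery, 108:13 skull, 27:9 gender, cohort sizes,
age 41 ± 15) are reproduced; the joint distribution across ROIs is a
deterministic construction, not patient data. The published composition
table accounts for 11 no-bone ROIs among its 118 classified entries plus
one confirmed no-bone ROI without a CT, which reaches 12 of the printed 13
skull-absent acquisitions; the fixture assigns a second CT-less ROI as
bone-absent to match the printed 108:13 marginal.

## What passing tests show — and what they do not

The suite establishes internal consistency: the inverse problems invert the
forward models (noiseless round trips within 1%, Poisson/correlator noise
within 5–10%), the figures of merit encode the guideline thresholds, and
the classifier reproduces each preset's expected verdict across seeds.
Because generator and fitter share the same forward model and the noise
models are simplified, these results bound neither the accuracy on real
heads (model mismatch from layered anatomy, probe coupling, detector
non-idealities) nor the clinical validity of the thresholds — the presets
mimic published signatures, they do not replay patient data.

## Numerical notes and limitations

- Percentages in cohort summaries are rounded half away from zero to
  integer percent; composition counts key on the canonical string.
- The Siegert inversion `√((g₂−1)/β)` loses the 1e-12 identity below
  g₁ ≈ 0.05 to floating-point cancellation; tests assert the tight bound
  only above that level.
- Curve files store 15 significant digits so a text round trip is lossless
  at 1e-12 relative.
- `ModelCurve` enforces g₁(0) = 1 only when the grid actually contains
  τ = 0; log-spaced grids begin after a small real decay.
- Multi-layer and Monte-Carlo forward models, moments-based TRS analysis,
  gated detection, full correlation-noise models and any handling of real
  patient recordings are out of scope.
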