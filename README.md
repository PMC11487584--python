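# hybridqc

Simulation, model fitting and quality control for **hybrid diffuse optical
neuromonitoring**: time-resolved near-infrared spectroscopy (TRS) paired with
diffuse correlation spectroscopy (DCS).

Bedside hybrid devices measure two signals on the injured adult head:

- **TRS** records the distribution of photon times of flight (DTOF) of
  picosecond pulses at 687 and 830 nm. Fitting the DTOF — the diffusion model
  convolved with the instrument response function (IRF) — separates the
  absorption coefficient μa from the reduced scattering coefficient μs′; the
  two-wavelength absorptions yield oxy-/deoxyhemoglobin concentrations and
  the tissue oxygen saturation StO₂ = 100·HbO₂/(HbO₂+HHb).
- **DCS** records the intensity autocorrelation g₂(τ) of coherent 785-nm
  speckle. Through the Siegert relation g₂ = 1 + β|g₁|², the field
  autocorrelation g₁ is fitted with the correlation-diffusion model under
  Brownian scatterer dynamics (⟨Δr²(τ)⟩ = 6·BFI·τ) to give a blood-flow
  index (BFI, cm²/s) and the coherence parameter β.

On severely injured heads — craniectomies, hematomas, CSF pockets, trapped
air — blindly fitting these curves produces numbers that look plausible but
do not reflect the brain. `hybridqc` implements the forward models, the
inverse problems, and a rule-based trustworthiness classifier built on
simple figures of merit (SNR, dynamic range, rFWHM/ΔFWHM broadening, DTOF
peak delay, count-rate window, β and BFI plausibility windows, g₁ tail
level, secondary-decay detection), together with a seeded generator of nine
case presets (a healthy head H0 and eight pathology-mimicking scenarios)
that serve as the classifier's test surface.

## Core models

Semi-infinite homogeneous medium, extrapolated-boundary image sources:

```
R(ρ,t) ∝ t^(-5/2) exp(-μa·v·t - ρ²/(4Dvt)) [ z₀ e^(-z₀²/4Dvt) + (z₀+2z_b) e^(-(z₀+2z_b)²/4Dvt) ]
G₁(τ) ∝ e^(-K(τ)r₁)/r₁ - e^(-K(τ)r_b)/r_b ,  K(τ)² = 3μaμs′ + μs′²k₀²·6·BFI·τ
```

with D = 1/(3μs′), z₀ = 1/μs′, z_b = 2AD (A from the effective-reflection
boundary approximation), v = c/n, k₀ = 2πn/λ. Units package-wide: μa, μs′ in
1/cm, ρ in cm, TRS time in ns, DCS delay in s, BFI in cm²/s.

## Worked example

```python
from hybridqc.io import evaluate_case
from hybridqc.synthetic import generate_case

report = evaluate_case(generate_case("H0", seed=1))
print(report["trs"]["687"]["fit"])      # {'mua': 0.1397, 'musp': 10.97, ...}
print(report["hemodynamics"])           # {'sto2_pct': 67.1, 'thc_uM': 66.3, ...}
print(report["dcs"]["fit"])             # {'bfi': 1.20e-08, 'beta': 0.482, ...}
print(report["trs"]["label"], report["dcs"]["label"])   # acceptable acceptable
```

The healthy preset simulates μa = 0.14/0.135 1/cm (687/830 nm),
μs′ = 11 1/cm, StO₂ = 67%, β = 0.49 at 90 kHz; the pipeline recovers
μa = 0.1397 and 0.1346 1/cm, μs′ ≈ 10.97 1/cm, StO₂ = 67.1%,
BFI = 1.17×10⁻⁸ cm²/s, and both verdicts come out *acceptable* with no
violated rules. Running the same pipeline on `"case6"` (a subdural
hemorrhage mimic) returns *suspect* with reasons `sto2_high`,
`g1_tail_not_zero` and `secondary_decay_present` — the g₁ curve's slow
second component (weight ≈ 0.25) is detected and the BFI is flagged as not
trustworthy.

The `examples/` directory holds one short narrative script per capability
(forward models, simulate+fit, quality control, case presets, cohort
tables). A thin CLI wraps the same functions:

```bash
hybridqc simulate --case H0 --seed 1 --out-dir curves/
hybridqc fit-trs curves/dtof_687.tsv curves/irf.tsv
hybridqc fit-dcs curves/g2.tsv --mua 0.138 --musp 11
hybridqc qc config.yaml
hybridqc generate --n-rois 121 --seed 7 --out-dir cohort/
hybridqc dataset summarize cohort/dataset.csv
```

Curves travel as two-column TSV with JSON metadata sidecars; QC rules are
YAML; reports are JSON.

## Dataset schema

`hybridqc.schema` implements the tissue-composition grammar
(`"SST+CB+CSF/NB"`: outer→inner layers joined by `+`, intermixed components
by `/`; codes ST, SST, CB, NB, A, CSF, SAH, EH, ICH, IT, BC), circular
15-mm-radius ROI records, and the long-format dataset table with one row per
(ROI, wavelength) — 121 ROIs make 242 rows. Packaged fixtures provide the
32-category composition frequency table and a synthetic 121-ROI cohort that
reproduces the published summary marginals (19% surgery, 89% skull
presence, 27:9 gender, ages 41 ± 15).

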