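# Methods

## Forward model

Transmitted intensity follows the Beer–Lambert law for a non-scattering
medium. For a narrowband channel at wavelength λ,

    I(t) = Is · 10^(−[ε_static(λ)·L + (Σ_s ε_s(λ)·C_s) · ΔL · p(t)]),

with source intensity `Is` (ADC units), baseline optical path `L` (mm),
pulsatile path modulation `ΔL` (mm), hemoglobin species concentrations
`C_s` (g/L; oxy-, reduced, met- and carboxyhemoglobin, fractions summing
to 1) and a lumped static-tissue absorbance per unit path `ε_static`.
The attenuation exponent carries a minus sign: transmitted light must
decrease with absorbance (A = lg(Is/I₀) ≥ 0). The pulse waveform
p(t) ∈ [0, 1] is 0 at end-diastole and 1 at the systolic peak, so the
analytic ground truth per channel is

    I_DC = I at p = 1 (cycle minimum of transmitted intensity),
    I_AC = I at p = 0 − I at p = 1,
    ratio = I_AC / I_DC = 10^((Σ_s ε_s C_s)·ΔL) − 1,

strictly increasing in hemoglobin on every channel with nonzero extinction.
The broadband channel is the emission-weighted sum of per-grid-wavelength
responses — the discrete form of integrating the LED spectrum against the
transmission — and degenerates exactly to a narrowband channel when the
spectrum is a single grid line.

The pulse is two Gaussian lobes in phase (systolic primary at 0.16 of the
period, width 0.09; dicrotic sub-wave at 0.52, width 0.10, amplitude 0.35),
wrapped across period boundaries and normalized to [0, 1] per period. This
gives the two local maxima per period characteristic of a peripheral pulse.

### Extinction curves

The bundled extinction table is a synthetic default, not a literature
digitization: reduced hemoglobin peaks near 650–660 nm and decays into the
NIR; oxyhemoglobin rises sigmoidally toward 880–940 nm; met- and
carboxyhemoglobin are smaller, broad terms; static tissue is flat with a
mild water-like bump near 980 nm. Magnitudes are chosen so that a
physiological hemoglobin range (80–160 g/L) with ΔL = 0.1 mm yields AC/DC
ratios of 1–3% — a realistic perfusion index. Every correctness claim in
the package depends only on orderings and monotonicity of these curves,
never on their absolute values.

### Study conditions (cohort generator)

Chosen once as the synthetic stand-in for a clinical acquisition series and
then left alone:

| parameter | value | why |
|---|---|---|
| record length | 6400 samples at 500 Hz (12.8 s) | one acquisition of the emulated front end |
| heart rate | 1.2 Hz default; cohort uniform 1.1–1.4 Hz | 66–84 bpm, matching the packaged cohort's recorded heart rates |
| hemoglobin | uniform 80–160 g/L | spans anemic to high-normal adults |
| path / modulation | L = 10 mm ± 10%, ΔL = 0.1 mm ± 5% per subject | fingertip geometry; ΔL jitter bounds achievable accuracy |
| contact pressure | mean uniform 1.5–2.5, coupling 0.5 to ΔL | perfusion changes under the clip make mean pressure an informative ninth feature |
| good records | noise SD 0.2% of DC, drift 1% at 0.25 Hz, 0.02 artifacts/s | clean bedside acquisition |
| poor records | noise SD 2%, drift 5%, 0.6 artifacts/s | motion-corrupted acquisition; exactly ⌊mix·n⌋ per cohort |

Motion artifacts are Poisson-timed half-sine bursts (0.2–0.6 s, 1–4× the
channel's AC, random sign) hitting all channels simultaneously, as finger
motion does.

What the generator does **not** emulate: photon scattering, melanin and
temperature effects, inter-subject variation of the extinction spectra,
venous pulsation, probe repositioning between repeated visits, and any
nonlinearity of the analog front end. Passing tests therefore demonstrate
internal consistency of the algorithms (the extractor recovers what the
forward model encodes; the regression recovers the concentration the
simulator used), not clinical accuracy on real fingers.

## Filtering chain

* Sliding average: centered boxcar, default 11 samples (22 ms at 500 Hz),
  shrinking at the edges. A wider 50 ms window was rejected because it
  attenuates the systolic lobe by ~1.5%, which is material against the 2%
  extraction-accuracy contract; 22 ms still averages everything far above
  the 10 Hz band edge.
* Band-pass: linear-phase FIR designed with a Dolph–Chebyshev window
  (5501 taps at fs = 500 Hz, 50 dB window attenuation, design edges at
  0.45/11.0 Hz so the nominal 0.6–10 Hz band sits on the flat top).
  Measured response: −43.9 dB at 0.3 Hz, −72.7 dB at 15 Hz, passband ripple
  < 1%. "Chebyshev FIR" is inherently ambiguous (Chebyshev IIR filters are
  not FIR); the windowed linear-phase design honors both the FIR and the
  equiripple-stopband readings, and only the attenuation contract matters
  downstream. Group delay is compensated by reflect-padding half the filter
  length on each side and trimming, so one causal pass yields an aligned
  trace; on signals shorter than the filter the tap count is reduced and
  stop-band attenuation degrades gracefully.
* Landmarks: local extrema with prominence ≥ 0.25× the trace inter-quartile
  range and separation ≥ 0.33 s (≈180 bpm). The morphological detector the
  method calls for is parameter-free in its description; extremum logic with
  a prominence floor is the standard reading. The dicrotic sub-wave is
  usually suppressed by the separation constraint; when it is not, the
  alternation repair (drop the lesser of two same-type landmarks) and the
  larger-half amplitude truncation downstream absorb it.

## AC/DC extraction

Windowed statistics use the population mean/variance over Δn elements with
an O(1) running-sum update, validated against direct summation (the
printed recursive variance form divides a (Δn+1)-element window by Δn; the
direct-summation definition is taken as the contract and any algebraically
equivalent update is acceptable).

AC: amplitude sets A (peak − preceding trough) and B (peak − following
trough); each sorted descending and truncated to its larger half (floor
division, minimum 2) — systolic and diastolic amplitude counts are close to
1:1 when sub-waves are detected, so the kept half is the systolic one —
then the minimum-variance window (half the kept length, minimum 2, ties to
the lowest start) supplies each set's mean. The two means are combined
with weights 1/(variance + 10⁻¹²); the floor only matters for exactly
constant windows. `min_window_variance`, normalized by DC², is the
scale-free quality feature.

DC: trough values on the mean-filtered trace, sorted descending, one
minimum-variance window of half the count; its mean is the static level.
Using the baseline-preserving trace is forced: the band-pass removes the
static component entirely.

Degenerate inputs raise a quality error rather than returning numbers:
fewer than 4 alternating landmarks, fewer than 2 troughs, flat traces, and
channels whose band-passed inter-quartile range is below 10⁻⁹ of the
baseline level (numerical ripple, not pulse).

Scale equivariance (intensity × k ⇒ AC, DC × k; ratio unchanged) holds to
floating-point round-off (~10⁻⁷ relative): FFT-based convolution and the
variance floor perturb the last digits.

## Quality classification

AdaCost with the cost-adjustment function β = 0.5 − 0.5c on a correct
classification and 0.5 + 0.5c on an error; learner weight
α = ½ ln((1+r)/(1−r)) from the cost-weighted margin r = Σ D·y·h·β; weight
update D ∝ D·exp(−α·y·h·β), renormalized each round. With all costs zero
β ≡ 0.5 and the dynamics reduce to AdaBoost's up to the constant margin
scale. Default costs: poor 0.8, satisfactory 0.2 — letting a poor signal
into the regression is the expensive mistake. Weak learners are depth-2
decision trees with weighted-Gini splits; boosting stops early on a
degenerate learner (weighted error ≥ 0.5). Quality features are pooled per
record as the worst channel's (largest normalized minimum window variance);
channels that fail extraction contribute a sentinel (variance 1, zero
landmarks) and dominate the pooling. The ensemble serializes to a versioned
JSON document (flattened trees + α's + costs) so scoring needs no fitted
estimator state.

## Regression protocol

Seeded 7:3 split (test = round(0.3·n), so 56 → 39/17). Grid search scored
by mean 10-fold CV R² on the training set; grids are 1–10 estimators ×
depth 1–6 for the tree ensembles and activation {identity, logistic, tanh,
relu} × solver {lbfgs, sgd, adam} at 10 000 iterations for the
two-hidden-layer network (default sizes (16, 8); unspecified in the
protocol and kept modest for ~40 training rows). The activation "real" and
the solvers "blogs"/"sad" in the protocol text are treated as typos for
relu / lbfgs, sgd. Ties in CV score go to the smaller model (fewer
estimators, then shallower; earlier grid order for the network). The
winning configuration is refit on the whole training set and scored on the
held-out test set with R², MSE, MAE, and Bland–Altman limits
mean(d) ± 1.96·SD(d) using the population SD. The network wraps input and
target standardization around the MLP (tree families need neither); a
network that fails to converge is reported with a warning. Zero-variance
validation folds report R² as missing and are excluded from the CV mean.

The Pearson matrix is computed pairwise-complete with a minimum of 3
common rows per pair, so the packaged clinical table's missing covariates
(only 16 of 56 subjects have blood pressure, creatinine and urea) shrink
individual pairs rather than the whole table.

## Known limitations

* The AC/DC ratio is linear in hemoglobin only through ΔL; inter-subject ΔL
  variation is a hard noise floor for any ratio-only regression, which is
  why the contact-pressure feature (coupled to ΔL in the generator) earns
  its place as the ninth input.
* On the synthetic cohort the good/poor quality classes separate almost
  perfectly, so cost-free and cost-sensitive boosting can both reach recall
  1.0; the cost-sensitivity test asserts the ordering, which is the
  property the quality index relies on, not a specific gap.
* The clinical table ships as transcribed, including its quirks: the
  blood-pressure pairs are stored with the larger printed value as systolic;
  no anemia flag is derived (the stated thresholds do not reproduce the
  summary count); hemoglobin decimals are kept as printed, in g/L.
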