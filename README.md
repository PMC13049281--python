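# ogsekit

Oscillating-gradient diffusion MRI probes tissue at millisecond time
scales: sweeping the gradient oscillation frequency makes the measured mean
kurtosis (MK) frequency dependent, and that dependence carries two distinct
microstructural signals — short-range structural disorder along neurites
(caliber variation, beading) and water exchange across cell membranes.
`ogsekit` implements the complete computational chain of such a study for
people designing OGSE protocols or fitting exchange models to ROI-level
kurtosis data: waveform construction and spectral analysis, the adiabatic
Kärger forward model, bounded L1 parameter estimation, Cramér–Rao protocol
ranking, synthetic ground-truth studies, and agreement metrics.

## The model

For a linear-tensor-encoding waveform with dephasing trajectory
q(t) = γ∫G dt and diffusion weighting b = ∫q²dt, the predicted mean
kurtosis separates as

    MK = K̄var · h[q] + K∞

* **K̄var** — direction-averaged two-compartment kurtosis without exchange:

      K̄var = ∫₀¹ dξ · 3 f(1−f) · [ (α_D + α_C·V_ω) ξ²/(1−ξ²) + (1−f) ]⁻²

  where f is the intra-neurite signal fraction, α_D = D∞∥/D∞⊥ the
  extracellular tortuosity, α_C = c/D∞⊥ the structural-disorder strength
  (ms^1/2), and V_ω = (1/b)∫dν |q_ν|²√ν the waveform's spectral dispersion
  factor (√-frequency moment of the encoding power spectrum, ms^-1/2).
  Absolute diffusivities cancel: MK is scale invariant.

* **h[q]** — exchange attenuation, h = 2∫₀ᵀ e^(−t/tex) q₄(t) dt with
  q₄(t) = (1/b²)∫q²(t′)q²(t′+t)dt′ and 2∫q₄ = 1, so h ∈ (0, 1] and
  h → 1 without exchange.

* **K∞** — residual kurtosis from non-exchanging partial-volume
  compartments (e.g. CSF).

Waveforms are trapezoidal-cosine OGSE: two blocks of N oscillation cycles
(quarter-lobe, 2N−1 alternating half-lobes, quarter-lobe; 1.6 ms ramps)
separated by a mixing time tM that hosts the refocusing pulse.  The
two-burst interference makes the spectral peak and its side lobes depend on
tM, which is optimized by a peak-to-side-lobe criterion.  Fitting minimizes
the summed absolute MK misfit over the protocol subject to box bounds
(tex ∈ [1,200] ms, f ∈ [0.01,0.99], α_D ∈ [1,10], α_C ∈ [0.01,20] ms^1/2,
K∞ ∈ [0.01,1]), with tissue-class starting points.  Protocol quality is
quantified by CRLB coefficients of variation √CRLBᵢ/|θᵢ| and a weighted
ranking of waveform subsets.

## Worked example

```python
import ogsekit as ok

protocol = ok.study_protocol()          # six-waveform protocol, b = 2 ms/um^2
print(protocol.derived_table().round(3).to_string(index=False))
```

```
  label  input_frequency_hz  n_oscillations  mixing_time_ms  total_time_ms  peak_frequency_hz  gradient_mT_per_m  b_ms_per_um2  v_omega_sqrt_per_ms
90Hz-N3                90.0               3            10.1         79.967             88.749            467.579           2.0                0.292
65Hz-N2                65.0               2            15.2         79.938             63.003            327.970           2.0                0.246
30Hz-N1                30.0               1             7.4         77.267             23.941            136.913           2.0                0.165
40Hz-N1                40.0               1            30.9         84.100             34.738            213.536           2.0                0.188
50Hz-N1                50.0               1            24.7         67.900             43.147            303.342           2.0                0.209
60Hz-N1                60.0               1            20.4         56.933             51.658            406.690           2.0                0.228
```

Total times, peak frequencies and amplitudes land on the published protocol
(80.0/79.9/77.3/84.1/67.9/56.9 ms; 88.3/62.5/23.2/34.0/42.2/51.6 Hz within
1 Hz; 137…465 mT/m within 1%).  The forward model at the gray-matter median
tissue point separates the two mechanisms per waveform:

```python
gm = ok.PRESETS["GM_median"].params     # tex=13.76 ms, f=0.43, aD=1.70, aC=10.22
pred = ok.predict_mk(protocol, gm)
for lab, kv, h, mk in zip(pred.labels, pred.kvar_bar, pred.h, pred.mk):
    print(f"{lab:>8}: Kvar_bar={kv:.3f}  h={h:.3f}  MK={mk:.3f}")
```

```
 90Hz-N3: Kvar_bar=0.562  h=0.290  MK=0.563
 65Hz-N2: Kvar_bar=0.588  h=0.297  MK=0.575
 30Hz-N1: Kvar_bar=0.644  h=0.314  MK=0.602
 40Hz-N1: Kvar_bar=0.627  h=0.326  MK=0.604
 50Hz-N1: Kvar_bar=0.611  h=0.362  MK=0.621
 60Hz-N1: Kvar_bar=0.599  h=0.395  MK=0.636
```

Reading the two regimes off these numbers: across the fixed-duration series
(30 Hz-N1 → 65 Hz-N2 → 90 Hz-N3, T ≈ 80 ms) MK falls (0.602 → 0.575 → 0.563)
because the structural-disorder term K̄var falls while h barely moves;
across the one-oscillation series (30 → 60 Hz) MK rises (0.602 → 0.636)
because shorter waveforms suppress exchange attenuation (h 0.314 → 0.395)
faster than K̄var decays.  Fitting a synthetic noiseless ROI generated at
this tissue point recovers all five parameters exactly
(`ok.fit_roi(...).summary()`), and `ok.generate_mk_study` +
`ok.batch_fit` run the full simulate→filter→fit loop; see
`ogsekit run --config` for the one-command pipeline with a manifest.

A command-line interface mirrors the library:
`ogsekit protocol | waveform | tm-optimize | simulate | fit | crlb | report | run`.

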