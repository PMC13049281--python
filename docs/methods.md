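# Methods

This note records the model, the numerical choices and the open design
decisions behind `ogsekit`, in the package's own terms.

## Waveform construction

A trapezoidal-cosine OGSE waveform is parameterised by input frequency f0,
oscillation count N, mixing time tM, and ramp time tR (default 1.6 ms,
amplitude independent).  Each encoding block is: ramp-up (tR), quarter-lobe
plateau p1 = 1/(4f0) − 1.5 tR, then 2N−1 half-lobe plateaus
p2 = 1/(2f0) − 2 tR of alternating sign joined by linear transitions of
2 tR, a trailing quarter-lobe plateau p1, and a ramp-down (tR).  This gives
block duration N/f0 + tR exactly, hence total time T = 2(N/f0 + tR) + tM,
and each block's signed area is identically zero.  The vendor's exact lobe
layout is not public; this layout is the simplest one consistent with the
published derived quantities (total times to ≤ 0.04 ms, spectral peaks to
≤ 1 Hz), and the package treats those derived quantities as its validation
surface.

The refocusing pulse is modelled purely as a sign flip inside the mixing
interval.  The physically played second block is the inverted copy of the
first, so the *effective* gradient repeats the first block and q(t) is two
identical bursts.  The alternative (effective second block inverted) shifts
the spectral fringes by half a period and is inconsistent with the published
peak frequencies by ~9 Hz, which is what fixes the convention here.

q(t) is integrated analytically from the piecewise-linear breakpoints (q is
piecewise quadratic), so the refocusing balance holds to float rounding
rather than raster resolution.  Sampled quantities use a 10 μs raster;
halving it moves b, the peak frequency and V_ω by < 0.05%.

## Spectral analysis

The encoding spectrum |q_ω|² is a zero-padded FFT with 0.125 Hz resolution
(8 s equivalent duration); the peak is refined by 3-point parabolic
interpolation, matching the 0.1 Hz precision of the published table.  The
b-value is reported in ms/μm² with γ = 2.6752×10⁸ rad s⁻¹ T⁻¹, and the
time-domain and spectral (Parseval) routes agree within 0.1%.

**Dispersion factor convention.**  V_ω = (1/b)∫dν |q_ν|² √ν with ν the
*cyclic* frequency in 1/ms (so an ideal cosine at ν₀ gives V_ω → √ν₀).  The
√-frequency moment could equally be taken over angular frequency, which
rescales the disorder coefficient α_C by √(2π); the two conventions are
indistinguishable for fitting.  Cyclic was chosen because, at the reported
median tissue parameters, it is the convention under which the forward
model reproduces the observed monotonic gray-matter kurtosis increase
across the one-oscillation series — i.e. it is consistent with the
convention under which those medians were estimated.

## Mixing-time optimization

The objective is the ratio of the main spectral peak of |q_ω|² to its
largest side lobe, the main lobe being delimited by the local minima
flanking the global peak.  Because the effective gradient is two identical
bursts, |Q(f)|² = |B(f)|² · 2(1 + cos 2πfΔ) with B the single-block
spectrum and Δ = block + tM; the search evaluates this factorisation (one
FFT per waveform family, O(grid) per candidate), which a test verifies
against full-waveform FFTs.

The grid search (0.1 ms steps over the scanner-feasible window, default
7.4–45 ms) returns the largest *interior* local maximum of the ratio, ties
toward smaller tM.  The raw maximum is unusable at low frequencies: below
~50 Hz the fringes merge at short mixing times into one wide "main lobe"
with vanishing side lobes, and the raw ratio diverges toward the lower
bound without producing a single-fringe spectrum.  The interior-maximum
rule reproduces all six published optimized mixing times to ≤ 0.1 ms
(41.7, 30.9, 24.7, 20.4, 15.2, 10.1 ms).

## Forward model

Two exchanging Gaussian compartments with the adiabatic approximation:
compartmental diffusivities vary slowly enough with frequency to be treated
as constants inside the kurtosis formula.  Intra-neurite transverse
diffusivity is neglected (thin neurites), the extracellular transverse
diffusivity keeps its long-time value, and the parallel diffusivities of
the two spaces are equal (degeneracy avoidance) — under which all absolute
diffusivities cancel into α_D and α_C.

* K̄var: 64-node Gauss–Legendre quadrature over the direction cosine
  ξ ∈ (0,1); the integrand vanishes at ξ→1 and nodes never touch it, so no
  special casing.  Agrees with 10⁶-sample Monte-Carlo direction averaging
  within 0.1%.
* q₄: FFT autocorrelation of q²(t) on the waveform raster, clipped at the
  negative round-off floor; the normalization identity 2∫q₄ = 1 holds to
  10⁻⁴ (exactly, in the discrete sense, because q vanishes at both ends).
* h: trapezoidal integration of e^(−t/tex) q₄(t) on the same raster;
  agrees with direct O(n²) double integration within 10⁻⁶ for all protocol
  waveforms and tex ∈ {5, 14, 50, 141} ms.  h is direction independent for
  linear encoding, so it multiplies the direction-averaged K̄var.

The regime decomposition evaluates K̄var(f) and h(f) separately: fixed-N
builds one-oscillation waveforms over an input-frequency grid with
per-frequency optimized tM reset to the scanner minimum (7.4 ms) whenever
the optimum leaves [7.4, 40] ms — this clip produces a genuine
discontinuity in the curves near 30 Hz, the same one visible in practice;
fixed-T evaluates the three realizable T ≈ 80 ms waveforms exactly and
interpolates components with a natural cubic spline (the spline is a
visualisation device; only the anchors are model evaluations).  Component
curves exclude K∞; the full MK curve includes it.

## Fitting

Per ROI, the estimator minimises Σ|MK_pred − MK_meas| under box bounds,
starting from the tissue-class point (WM: tex 150 ms, f 0.7, α_D 2.5, α_C 5,
K∞ 0.1; GM: tex 20 ms, f 0.4, α_D 2, α_C 10, K∞ 0.4).  The optimization is
derivative free (the L1 objective is non-smooth): multi-start Nelder–Mead
in a sigmoid-transformed unconstrained space (3 starts: the class point ±
10%-of-range jitter, seeded), a bounded Powell polish, and finally a
bounded least-squares descent accepted only if it lowers the L1 objective.
The last stage matters: the likelihood valley is nearly flat along
combinations of (f, α_D, α_C) — they enter only through the one-dimensional
family K̄var(V_ω) sampled over a narrow V_ω range (0.165–0.292 ms^(−1/2)) —
and simplex steps alone stall ~10⁻⁴ above the optimum.  With it, noiseless
generate-then-fit round trips recover all five parameters to < 10⁻⁶
relative at both tissue points.

Per-waveform V_ω and q₄ are parameter independent and cached in a forward
operator shared across ROIs; the q₄ kernels are compressed into 2048
mass- and first-moment-preserving lag bins, making one objective evaluation
O(bins) with ≤ 7×10⁻⁵ relative error in h at the shortest admissible
exchange time (tex = 1 ms) and ~10⁻⁹ at long tex.

**Identifiability.**  The near-collinearity above is a property of the
six-waveform design, not of the optimizer: the Cramér–Rao coefficients of
variation at the median tissue points with MK noise σ = 0.02 are ~0.5–1 for
tex but 10²–10³ for f, α_D, α_C individually.  Estimates of these three
parameters scatter along the degenerate valley under noise (bounded by the
fitting box), while their combination — the predicted MK curve — is tightly
determined.  Users should interpret single-ROI α_D/α_C point estimates with
caution and rely on the CRLB report that `summary()` prints.

## Protocol precision and ranking

Fisher information I = JᵀJ/σ² with J by central finite differences
(relative step 10⁻⁴, verified against Richardson extrapolation to 10⁻⁴
relative); K∞ is held fixed (it carries no frequency dependence) and the
four remaining parameters are ranked.  σ defaults to 0.02 (the scale of the
fit residuals) and affects absolute cv only — rankings are σ invariant.
All C(M,k) subsets are scored per parameter: cv ascending, top 10 weighted
10…1, accumulated over ROIs, ties lexicographic.  Subsets whose Fisher
matrix is numerically singular (condition > 10¹⁵ or non-positive variance
bound) are excluded from that ROI's ranking.  A full-protocol cv is never
above any subset cv (information monotonicity), which the tests assert.

## Synthetic data

The generator emulates the analysis product of an in vivo study — one
median MK per ROI per waveform — not the study itself.  Per-ROI truths are
truncated-Gaussian draws around a tissue preset (WM/GM median parameter
points; K∞ presets are the fitting start values, as median K∞ values are
not published); default per-parameter relative dispersion is 10%, chosen to
give ROI spread comparable to reported interquartile ranges without
asserting unpublished values.  MK noise is additive Gaussian with σ = 0.02
(ROI medians over many voxels are approximately Gaussian; σ matches the
fit-residual scale).  Values leaving the physiological range [0, 3] are
excluded, as the upstream voxel filter would do.

A signal-level route exists for testing the estimator chain: powder-averaged
two-shell signals from the cumulant form ln S = −bD + (1/6)b²D²K with
per-direction Rician noise, and the closed-form two-shell (D, K) inversion.
Default MD values (0.8 WM, 1.1 μm²/ms GM) are configuration defaults, not
literature claims.

What the generator does *not* emulate: directional kurtosis-tensor
structure, spatial correlation between ROIs, subject-level repeated
measures, preprocessing residuals (Gibbs, eddy currents, gradient
nonlinearity), or Rician bias at the ROI-median level.  Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to real-data violations of
them.

## Problem sizes and determinism

Default problem sizes: 10 μs raster (≈ 6–8×10³ samples per waveform),
0.125 Hz spectra, 64 quadrature nodes, 2048 lag bins, 50 ROIs per class for
recovery studies, 20 ROI draws for subset ranking.  All randomness flows
through explicit integer seeds; identical seeds give bit-identical studies,
fits and pipeline outputs (the run manifest records config, seed and
package version for exact reruns).

## Known limitations

* The lobe layout and mixing-time side-lobe rule are reconstructions
  validated only through published derived quantities.
* Only linear-tensor cosine OGSE; no PGSE, sine-OGSE or b-tensor encoding.
* The extracellular transverse diffusivity is frequency independent by
  assumption; soma compartments are absorbed into K∞.
* ROI-level fitting only; no voxel-wise maps, no hierarchical pooling
  across subjects.
* α_D/α_C/f are individually ill-determined at realistic noise (see
  Identifiability) — a protocol with a wider V_ω spread would be needed to
  break the collinearity.
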