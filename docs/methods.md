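# Methods

## Overview

`specdag` implements a frequency-resolved directed-connectivity analysis for
multi-channel neural recordings in which each brain parcel is represented by a
small block of component time series (typically the three strongest SVD
components of its source signals). The chain is:

1. segment continuous trials into overlapping epochs;
2. estimate the multitaper cross-spectral density (CSD) over all channels;
3. factorize each parcel pair's joint CSD with Wilson's algorithm;
4. compute the Geweke blockwise Granger causality (GC) spectra in both
   directions and the directed asymmetry index (DAI);
5. test DAI at the group level with dependent-samples t statistics and
   cluster-based permutation correction, summarize significant edges per
   canonical band, and compute node strength;
6. quantify envelope–parcel coupling with Gaussian-copula mutual information
   (GCMI) at a fixed lag, and correlate coupling with connectivity across
   participants.

Because suitable raw recordings are privacy-restricted, the package ships a
first-class synthetic generator that produces multivariate autoregressive
(MVAR) networks with known frequency-specific directed structure; every stage
is validated against that ground truth and against closed-form oracles.

## Spectral estimation

Continuous trials are cut into windows of `win_s` = 4 s advancing by
`win_s − overlap_s` (overlap 0.5 s); trailing partial windows are dropped, so
a 60 s trial yields 17 epochs. Each epoch is demeaned per channel and
multiplied by `K = floor(2·T·W) − 1` discrete prolate spheroidal tapers with
half-bandwidth `W` = 2 Hz (15 tapers for 4 s windows); the CSD is the average
of one-sided FFT outer products over tapers and epochs, scaled as a one-sided
spectral density (units²/Hz) on the natural FFT grid 0…fs/2 at 1/`win_s`
resolution. Hermitian symmetry is enforced by construction. Demeaning is a
package choice (it suppresses DC leakage); the taper-count rule is the
standard concentration trade-off.

The sampling rate is a free configuration parameter throughout (synthetic
defaults use 256 Hz, giving a 0.25 Hz grid with 4 s windows).

## Wilson spectral factorization

Nonparametric GC requires the factorization S(f) = H(f) Σ H(f)\* with H
causal (minimum-phase) and Σ the innovation covariance. The one-sided density
is first converted to the two-sided `H Σ H*` convention (undoing the one-sided
doubling and the 1/fs scaling — this keeps the Hermitian-extended spectrum
smooth across DC/Nyquist and returns Σ in signal units), then refined by the
classic fixed-point iteration

    psi_{k+1} = psi_k · [ psi_k^{-1} S psi_k^{-H} + I ]_+

where `[·]_+` keeps non-negative lags, with the lag-0 coefficient halved and
upper-triangularized to pin the unitary freedom of the factor. The iteration
starts from the upper Cholesky factor of the lag-0 covariance.

Numerical choices:

* convergence target `tol` = 1e−9 maximum relative reconstruction residual,
  `max_iter` = 100. Analytic (closed-form) spectra of low-order VAR systems
  converge to this tolerance in ~30 iterations. Estimated multitaper spectra
  hit a finite-lag representability floor (typically 1e−5…1e−4 relative) —
  the iteration detects the stall, stops, and flags non-convergence with the
  achieved residual (logged, never silent). Such factorizations are still
  accurate far beyond what GC needs.
* bins are checked for positive semi-definiteness; a slightly negative
  smallest eigenvalue triggers diagonal loading of `1e−8 × mean diagonal
  power`, anything worse raises an error naming the offending bin.
* Σ = A₀A₀ᵀ where A₀ is the real lag-0 coefficient of the converged factor,
  and H(f) = ψ(f)A₀⁻¹.

Verified invariants: scale equivariance (c·S → c·Σ, H unchanged), channel
permutation equivariance, and the Kolmogorov identity for one channel
(Σ equals the geometric mean of the two-sided PSD within 1 %).

## Blockwise Granger causality and DAI

For a pair of blocks X (source) and Y (target) of the jointly factorized
two-parcel system, the Geweke block-spectral measure is

    F_{X→Y}(f) = ln det S_YY(f) − ln det( S_YY(f) − H_YX(f) Σ_{X|Y} H_YX(f)* )

with the partial innovation covariance Σ_{X|Y} = Σ_XX − Σ_XY Σ_YY⁻¹ Σ_YX.
Values are clipped at 0 from below (numerical floor); bins with a singular
target spectrum are flagged NaN, excluded from statistics, and recorded.

The DAI for a pair (A, B) is

    DAI(f) = (F_{A→B}(f) − F_{B→A}(f)) / (F_{A→B}(f) + F_{B→A}(f)) ∈ [−1, 1],

antisymmetric under direction swap by construction. Bins where the
denominator falls below `1e−10 × median total GC` are undefined (NaN), never
silently zeroed.

Design choices:

* pairs are treated bivariately (block-pairwise), not conditionally on the
  remaining parcels — the analysis concerns each pair's own joint system;
* every pair is refactorized from its own 2k×2k CSD (an exact submatrix of
  the full CSD). Slicing a factorization of the full system would not be a
  valid factorization of the pair;
* the analysis range defaults to 0–100 Hz;
* a parametric reference, `parametric_gc_spectrum`, evaluates the same block
  formula on the analytic transfer function of known VAR coefficients. It is
  used exclusively as an independent oracle in validation, never as the
  production path.

## Group statistics

The observed statistic is a paired t across participants at every
(pair, frequency-bin) cell: DAI against zero, or the per-participant
difference between two conditions. Cells with |t| above the two-sided
cluster-forming threshold (α_form = 0.05 on the t distribution with per-cell
df) are grouped into frequency-contiguous, same-sign clusters within each
pair; cluster mass is the summed t. The null flips each participant's map
sign at random (the exact null for paired symmetric distributions; for the
between-condition contrast the flip acts on the condition difference, which
equals swapping the condition labels within participant). Family-wise error
across frequencies and parcels is controlled by pooling the maximum |mass|
over all pairs and bins per permutation; p = (1 + #{null ≥ |mass|}) / (1 +
n_perm) with n_perm = 5000 by default.

Canonical bands: Delta/Theta 0–7, alpha 7–13, beta 15–30, gamma 30–60, high
gamma 60–90 Hz. Testing runs separately within each band's bins and is not
corrected across bands. Band membership is inclusive at both edges, so a bin
on a shared boundary (e.g. 7 Hz) belongs to both neighboring bands, and a
cluster spanning a boundary is summarized in both — the documented overlap
rule. Adjacency is frequency-contiguity only; no parcel-pair neighborhood
graph is imposed (correction across pairs comes from the pooled maximum).

`band_summary` converts significant clusters to directed edges (positive DAI
cluster on pair (A,B) → edge A→B) weighted by mean |t| over the overlapping
bins; multiple same-direction clusters in one band merge into one edge.
`node_strength` counts outgoing vs incoming significant edges per node and
band; totals balance per band by construction.

## Envelope coupling (GCMI)

Brain features per parcel are the real and imaginary parts of the three
components' complex multitaper spectral estimates (2 s windows, 50 % overlap,
±2 Hz smoothing, taper-averaged) averaged over the bins of a band (theta
4–8 Hz for coupling, 9 bins on the 0.5 Hz grid); the envelope contributes the
real and imaginary parts of its own spectral estimate at the same bins. The
envelope is advanced by a fixed lag (130 ms default) relative to the brain
signal before windowing, implemented by trimming both signals to their common
support, so the brain lags the speech.

MI is estimated with the Gaussian copula: each feature column is
rank-transformed (average ranks for ties) and mapped through the inverse
standard normal CDF; MI is then 0.5·ln(det Cx · det Cy / det Cxy) on the
transformed data, with the analytic small-sample bias of the three Gaussian
entropy terms (digamma form) subtracted so values are comparable across
participants with different window counts. Corrected estimates can be
slightly negative for independent data; the per-parcel coupling score clips
them at 0 (the raw value remains available). Band aggregation averages the
complex spectra across bins *before* MI — the simplest reading consistent
with a single MI value per parcel.

The correlation stage computes Pearson r across participants between
connectivity (e.g. per-band mean DAI toward a fixed target) and coupling,
converts to t, and corrects across parcels by permuting the participant
pairing and pooling the maximum |t| (parcels have no adjacency, so clusters
are singletons). Results are per band and not corrected across bands.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes:
parcels × components driven by a stable VAR, participant-level variability,
condition differences confined to edge strengths, and an envelope-driven
parcel for the coupling stage.

* **Edges.** A directed edge (source, target, strength, f0, bandwidth) turns
  the source components it uses into damped AR(2) resonators with the pole
  pair at f0 (radius r = exp(−π·bw/fs)) and adds a lag-1 cross-regression of
  block gain `strength` (normalized by source-component count). The
  transmitted influence — and hence the directed GC spectrum — peaks at the
  resonance. The resonance must live in the source *dynamics* because a
  two-tap cross term alone contributes only numerator zeros and cannot place
  a spectral peak; one consequence is that all edges leaving a component
  share one band (different bands are routed through different components),
  and a zero-strength edge is exactly a no-op. Closed-form spectra
  S(f) = H(f) Σ H(f)\*/fs follow from the coefficients and serve as oracles.
* **Intrinsic dynamics** are a mild low-pass AR(2) (a₁ = 0.5, a₂ = −0.1),
  identical across channels, so parcels without edges are independent by
  construction.
* **Stability** is enforced via the companion-matrix spectral radius; an
  unstable specification raises an error naming the radius. Burn-in of
  10 × model order × fs samples is discarded per trial. Innovations are
  Gaussian (matching the Gaussianity assumptions behind GC and the GCMI bias
  correction).
* **Envelope**: low-pass-filtered (≤ 8 Hz Butterworth, zero-phase) rectified
  noise, z-scored — mimicking the slow amplitude-modulation spectrum of
  continuous speech. Injection adds `sqrt(snr · var(x)) · env(t − lag)` to
  each component of the designated parcel, with `snr` the injected-to-
  intrinsic variance ratio.
* **Cohorts**: per participant, edge strengths are jittered multiplicatively
  (`strength · (1 + sd·z)`, default sd = 0.1–0.15); unstable draws are
  resampled up to a bounded retry count. Conditions share the layout and
  differ only in strengths. A truth table (condition, source, target, band,
  strength) accompanies the data. Defaults mirror the study geometry: 30
  participants, 3 components per parcel, 60 s trials; the effective SNR and
  inter-participant variability of real recordings are unknown, so these are
  exposed parameters, not estimates.

What the generator does **not** emulate: sensor physics and field spread,
head movement, 1/f background with realistic exponents, nonstationary or
burst-like coupling, volume-conduction-induced zero-lag correlations, and
real speech acoustics. Passing tests therefore demonstrate the correctness
and calibration of the estimators under their own assumptions, not robustness
to these real-data complications.

## Problem sizes in the test and validation runs

Chosen as the package's own desk-scale defaults: the factorization oracle
uses 512-bin analytic spectra of 2- and 6-channel systems; the GC oracle ~510
epochs of a unidirectional VAR(2); the frequency-reversal cohort 30
participants × 2 × 60 s trials with 5000 permutations; the null-calibration
runs 200 repetitions (120 in the standalone validation script) of a reduced
cohort (12 participants, 2 single-component parcels, 128 Hz, 30 s trials,
500 permutations); GCMI closed forms n = 10 000; the coupling-correlation
construction 24 participants. The end-to-end demo uses 8–12 participants.

## Known limitations

* Pairwise (not conditional) GC cannot distinguish direct from indirect
  routes in networks with more than two parcels.
* Blockwise GC on taper-smoothed spectra inherits the smoothing bias: very
  narrow-band couplings are underestimated at their peak (the oracle
  comparisons use bandwidths ≳ 8 Hz where the bias is within a few percent).
* The cluster-forming threshold, sidedness, and the absence of a spatial
  adjacency graph are explicit package defaults for an underdetermined
  design space; conclusions about cluster extent are conditional on them.
* GCMI is a lower bound on MI; the estimator is exact only for dependencies
  captured by the Gaussian copula of the chosen features.
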