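# Methods

## Signal model

Two continuous-time models are supported. A *Dirac stream*
`x(t) = Σ_{k=1}^K a_k δ(t − t_k)` with strictly increasing, distinct `t_k`
(distinctness is what makes the Prony roots distinct and the recovery
unique), and a *decaying-exponential stream*
`x(t) = Σ_k a_k e^{−α(t−t_k)} 1_{t≥t_k}` with a common, known decay
`α = 1/τ_ca > 0`. Both are finite-rate-of-innovation signals: K events in a
window of duration τ contribute 2K degrees of freedom, an innovation rate
of 2K/τ.

The calcium model is the exponential stream with equal jump amplitude A:
fluorescence jumps instantaneously at each action potential and relaxes
exponentially; the recorded trace adds i.i.d. Gaussian noise. The SNR
convention throughout is `10·log10(mean(clean²)/σ²)` over the analysed
samples (per-sample power; the literature often leaves this undefined).
The generator emits a zero baseline: baseline estimation on real data is a
preprocessing concern (median subtraction is adequate for sparse firing)
and is deliberately out of scope of the model.

## Acquisition

The acquisition device filters with `h(t) = φ(−t/T)` and samples at `nT`,
equivalently `y_n = ⟨x(t), φ(t/T − n)⟩`. For Dirac streams this collapses
to kernel evaluations `y_n = Σ_k a_k φ(t_k/T − n)`; for exponential streams
the inner product is integrated by composite 24-point Gauss–Legendre
quadrature with pieces split at the kernel knots and at event times, so
every piece is smooth and the result is accurate to ~10⁻¹¹ (validated
against a dense Riemann sum in the tests). The default sample range is the
minimal set with kernel overlap, extended along exponential tails until
they decay by e⁻⁸.

## E-spline kernels and their evaluation

The E-spline of order P is the convolution of P+1 zero-order factors
`e^{α_m t} 1_[0,1)`; its transform is `Π_m (1 − e^{α_m − iω})/(iω − α_m)`
and its support is `[0, P+1)`. Purely imaginary exponents `α_m = iω_m` on a
symmetric equispaced grid `ω_m = −λP/2 + λm` make the kernel real-valued.
The default grid for an N-sample window uses `λ = 2π/N`, which keeps the
root phase `λ t_k / T` inside one period for any location in the window, so
the mapping from Prony roots to times is unambiguous on `[0, NT)`.

Kernels are evaluated in closed form rather than by numerical convolution
of the factors: the transform's numerator is expanded as the polynomial
`Π_m (1 − e^{α_m} z^{−1})` and the rational part is partial-fractioned
(with multiplicities, so repeated exponents — e.g. a convolution with an
extra box — are exact), expressing φ as a finite sum of one-sided terms
`(t−j)^p e^{α(t−j)} 1_{t≥j}`. These terms cancel massively (the residues
grow like `λ^{−P}` while the kernel stays O(1)), so the sum is accumulated
in 80-bit extended precision and rounded once; the resulting pointwise
accuracy is ~10⁻¹³ even for P = 13 windows, which is what lets
critical-rate recovery reach ~10⁻¹¹ location error. Removable
singularities of the transform factors (`iω → α_m`) are evaluated by their
series below |iω − α_m| < 10⁻⁸.

The Gaussian kernel is truncated where its amplitude falls below 10⁻¹²
(≈ ±7.4σ at σ = 1) so discrete reproduction sums are finite.

## Reproduction coefficients

For a Strang–Fix kernel the exact coefficients are
`c_{m,n} = e^{iω_m n}/φ̂(ω_m)`; the truncated sum over `n ∈ [n₀, n_f]`
reproduces `e^{iω_m t}` exactly on `[n₀ − 1 + s_hi, n_f + 1 + s_lo)` for a
kernel supported on `[s_lo, s_hi)`. The truncation range is configuration
(figures in the literature do not state one); the validation benchmarks use
ranges just covering the sample support.

For kernels that satisfy the conditions only approximately (Gaussian), the
*constant least squares* coefficient is the projection weight
`c_{m,0} = φ̂(ω_m)* / Σ_l |φ̂(ω_m + 2πl)|²`, obtained by minimising the
periodised reproduction error over one period. It reduces exactly to
`1/φ̂(ω_m)` when the aliases vanish, and leaves a residual governed by the
alias magnitudes — ~2·10⁻⁸ for σ = 1 at ω = ±0.1π. (The simpler weight
`φ̂(ω_m)` sometimes quoted for this scheme leaves a residual of
`1 − |φ̂(ω_m)|²`, several percent in this regime, and is not used.)

## Recovery

Moments `s_m = Σ_n c_{m,n} y_n` are annihilated by a length-K recurrence;
the package solves the annihilating system with **all** available rows
(least squares), which coincides with the minimal square system at the
critical rate and is strictly better conditioned beyond it. Roots come
from the companion matrix; amplitudes from the Vandermonde least-squares
fit; `t_k = T·arg(u_k)/λ` with the argument in `[0, 2π)`. Roots are *not*
projected onto the unit circle: deviation of |u_k| from 1 is kept as a
noise/border diagnostic (and used as a rejection criterion in streaming,
threshold 0.2 by default).

The decaying-exponential stream reduces to the Dirac case through
`z_n = y_n − y_{n−1} e^{−αT}`: the difference of the causal exponential
collapses to a compact factor `e^{−αw} 1_{[0,T)}`, so `z_n` equals sampling
the innovation Diracs with the effective kernel
`ψ(t) = T·(β_{−αT}(−·) * φ)(t)` — itself an E-spline with one extra real
exponent `+αT`, shifted left by one. (Some statements of this reduction
carry the opposite sign on that exponent; the sign used here is the one
under which the identity holds numerically to quadrature accuracy.) ψ
reproduces the same exponentials as φ, so its coefficients `d_{m,n}` follow
from the same formula.

Model order: the Toeplitz moment matrix with `⌈P/2⌉+1` columns has rank K
in the noiseless case; K is estimated as the number of singular values with
`μ_i/μ_1 ≥ μ₀` (default μ₀ = 0.3, to be lowered in clean data and raised in
heavy noise). The estimate never returns 0 and is biased upward in noise —
by design it feeds a consistency stage that tolerates overestimation.

## Denoising

Cadzow denoising alternates SVD truncation to rank K with re-Toeplitzing by
diagonal averaging on the near-square moment matrix (default 20 sweeps,
stopping when `μ_{K+1}/μ_1 < 10⁻¹⁰`; the stopping rule is a package choice,
the iteration count is not prescribed by the theory). The annihilator is
then the total-least-squares minimiser of ‖S h‖ with ‖h‖ = 1, normalised by
its first element. The matrix pencil alternative estimates the roots as
rank-reducing numbers of (S₀, S₁); for stability the pencil is formed on
the K leading left singular vectors of S (shift invariance of the signal
subspace). The pencil needs K+1 rows, i.e. `P ≥ 2K` — one moment more than
the critical rate; Prony and TLS work at the critical rate itself.

## Streaming and spike inference

A window of N samples slides one sample at a time; each position runs
moments → (Cadzow) → TLS/Prony. An event influences `L = P+1` consecutive
samples, so `N − L + 1` window positions capture it fully and estimate it
consistently; windows that see it partially produce scattered "border"
estimates. Pooling all retained estimates into a histogram (default bin
T/4) up to the consistency horizon `(n_last − L)·T` turns consistency into
peaks; peaks above `min_count_frac` (default 0.3) of the per-event maximum
window count, merged below `min_separation` (default T) to count-weighted
centroids, are the detected events. (The horizon expression is stated in
sample units in part of the literature; it is read here as the time
`(n_i − L)·T`.)

Spike inference runs this twice — a big window (default N = 32, order
estimated per window, K_max = 4–5) and a small window (default N = 8,
K fixed to 1) — and pools both passes into one equally-weighted joint
histogram. For an instantaneously sampled trace (no analogue acquisition
kernel, the realistic imaging case) the finite difference concentrates each
transient onto the first sample index after its onset; correlating the
innovation sequence with the kernel's integer samples then reproduces
exactly the sample pattern of an on-grid Dirac, so the window machinery
applies unchanged. The price is that locations are recovered at sample
resolution (the sub-sample offset moves into the amplitude,
`a = A e^{−α(⌈t_k/T⌉T − t_k)}`), which is why the calcium benchmarks use a
2T timing criterion while kernel-acquired streams are recovered to ~10⁻¹¹.

Because the model fixes a common jump amplitude A, per-window estimates
with amplitude below `amp_frac·A` (default 0.5) are discarded when A is
supplied: noise-driven estimates carry near-zero amplitude while true
spikes recover ≈ A, and this gate removes most of the histogram floor.

## Synthetic study conditions

The generators emulate the canonical conditions: Poisson spike trains with
a refractory gap (thinning keeps the earlier spike — deterministic and
order-preserving), unit-amplitude events, calcium parameters A = 1,
τ_ca = 0.5 s, 16 Hz sampling, SNRs of 15–20 dB. Event draws enforce a
minimum separation of one sampling period (distinct events closer than one
sample are unrecoverable in practice at the critical rate). Streaming
benchmarks observe the stream from before the first event so every event
has its full complement of capturing windows; the validation suite uses
5 events over ~9 s with ≥ 0.7 s separation (local innovation rate 3.2 with
N = 50, T = 1/16), 50 trials, and 100-trial batches for the noiseless
identities. These sizes keep the whole validation run around a minute while
leaving the measured margins far from their thresholds.

What the synthetic data does **not** model: baseline drift and slow
neuropil contamination, amplitude variability across spikes, indicator
saturation and nonlinearity, photon (Poisson) noise statistics, and motion
artifacts. Passing benchmarks therefore demonstrate the correctness of the
sampling/recovery machinery and the robustness of the consistency scheme to
additive white noise — not end-to-end performance on real recordings.

## Known limitations

* Events within ~NT of the start or end of a finite record get fewer
  capturing windows and may fall below the histogram threshold (see the
  README example).
* The trace pipeline assumes τ_ca (and optionally A) known; mis-specified
  decay degrades the finite-difference reduction gracefully but
  measurably.
* Coincident or near-coincident events (closer than a sampling period) are
  flagged through rank/residual diagnostics, not resolved.
* The matrix pencil requires one moment beyond the critical rate.
* Variable-amplitude recovery is supported by the math (a_k is free) but
  the equal-A amplitude gate must then be disabled.
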