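# Methods

## Measurement model

A real signal `x ∈ R^N` (1-D, or 2-D with `N = H·W`) is observed through
`K` coded diffraction patterns: `y_ij = |DFT(W_j ⊙ x)_i|² + η_ij`, with
mask entries i.i.d. uniform on the unimodular alphabet `{1, −1, i, −i}`
(`{1,−1}` and `{i,−i}` variants are available as options).  The DFT is
the unnormalized FFT convention (2-D FFT for images), so intensities
satisfy the Parseval identity `Σ_i y_ij = N‖x‖²` per mask — the basis of
the energy estimate used by every initializer.  Mask entries satisfy
`E{w} = E{w²} = 0` and `|w|² = 1` exactly; the zero-mean property is the
one the solver's behavior depends on.  (The convergence analysis also
quotes a fourth-moment relation `E{|w|⁴} = 2E{|w|²}`, which cannot hold
for a unimodular alphabet where `|w|⁴ ≡ 1`; it is recorded here and not
asserted anywhere.)

The bilinear operator `H_a` (rows `aᵀH_ij`, `H_ij = Re{W_j* conj(f_i)
f_iᵀ W_j}`) is applied as `Re{z_a ⊙ conj(z_b)}` with `z_v = FFT(W ⊙ v)` —
the unique conjugation convention whose diagonal case reproduces the
intensities.  Its adjoint is `Σ_j conj(W_j) ⊙ (N·IFFT(r_j ⊙ z_{a,j}))`
(real part), verified in the tests against dense `H_ij` constructions at
`N ≤ 16` to 1e-9 relative error and by the inner-product identity.
`X = b aᵀ` is never materialized; all costs are `O(K N log N)` per
operator application.

Noise: AWGN is added to the squared magnitudes with variance chosen so
the global SNR `10·log₁₀(‖Y‖²/‖η‖²)` matches the nominal value in
expectation (a single scalar per experiment, not per-mask).  The
amplitude-flow baselines natively consume non-squared magnitudes, so for
them noise at the same nominal SNR is applied to the magnitudes instead.

## Solver

Outer iteration: one least-squares half-step `b_n = argmin‖H_{a_{n−1}}b −
y‖²` followed by the fusing step `a_n = b_n = (a_{n−1} + b_n)/2`.  Only
one half-step per iteration is needed — fusing after a single exact
half-step already contracts the error.  The half-step solves the normal
equations `HᵀHb = Hᵀy` by plain conjugate gradient, matrix-free,
warm-started from the previous `b`, with relative residual tolerance
1e-12 and a cap of 50 iterations.  A fixed tight tolerance keeps runs
deterministic; normal equations (rather than a bidiagonalization method)
mirror the closed-form `(HᵀH)⁻¹Hᵀy` structure of the half-step, and the
squared condition number is harmless at these scales.

Stopping: relative change `‖a_n − a_{n−1}‖/‖a_n‖ < ε` with ε = 1e-15
(chosen relative for amplitude invariance), or `q = 2500` outer
iterations; hitting the cap sets `converged=False` and is not an error.
The fused `a` is returned as the estimate; the global sign ambiguity is
resolved only in the metrics, never inside the solver.  Setting
`SolverConfig(fuse=False)` switches to pure alternation of the two
half-steps — the diagnostic mode demonstrating that the fusing step is
what makes the method converge (without it, noise-free N=64/K=4 trials
stall around normalized error 0.2).

## Initializations

* **Positive random**: i.i.d. uniform(0,1) entries rescaled so
  `‖x̂₀‖² = ΣY/(NK)`.  Noise-free, this matches `‖x‖` exactly (Parseval).
  The two properties that matter — strictly positive entries and correct
  energy — make it a serviceable init for nonnegative signals at any K,
  with quality insensitive to K.
* **Spectral (WF / TWF / TAF)**: leading eigenvector of
  `v ↦ Σ_ij w_ij H_ij v`, scaled to the same energy estimate.  Weights:
  WF `w = y`; TWF `w = y·1{y ≤ α_y²λ²}` with α_y = 3; TAF unit weights on
  the 5/6 fraction of bins with the largest intensities (for CDP all
  rows have norm √N, so intensity order equals normalized-correlation
  order).  The eigenvector is extracted by matrix-free Lanczos
  (`scipy.sparse.linalg.eigsh`) rather than plain power iteration: the
  exact identity `Σ_i H_ij = N·I` pins the TAF operator's bulk spectrum
  to a tight cluster about 1% below the leading eigenvalue, where power
  iteration makes no progress in any practical iteration count while
  Lanczos separates it at the same matvec budget.  When the Krylov solve
  does not converge (K ≤ 3, where the top eigenspace is genuinely
  degenerate because the discarded set is too small to pin down a
  direction), the best Ritz vector is used — exactly the regime where
  the TAF init is uninformative, for this package and in the published
  comparisons alike.

## Baselines

WF (step ramp `min(1 − e^{−t/330}, 0.2)/‖x̂₀‖²`), TWF (Poisson-likelihood
gradient, truncations α_lb = 0.3, α_ub = 5, α_h = 5), TAF (amplitude
loss, keep `|z_i| ≥ ψ_i/1.7`, step 0.6), MRTAF (TAF plus heavy-ball
momentum 0.3 and a median residual filter at 6× the median), and an ADMM
solver on the same split formulation (penalty `ρ·K·N·‖anchor‖²` with
ρ = 0.1, inner CG as in the main solver; ρ was fixed once so the ADMM
converges on the noise-free N=64/K=8 problem — the method is known to be
parameter-sensitive).  All iterate over real vectors and share the FFT
forward model.  Their role is comparative: the tests assert descent of
each method's own objective, stationarity at the truth, exact recovery
where expected, and that the ADMM variant needs substantially more outer
iterations than the fusing solver on the same problem.  They are
re-implementations from published descriptions; where measured, their
success rates run somewhat higher than the printed comparisons (see
limitations).

## Metrics and diagnostics

Normalized error `min(‖x̂−x‖, ‖x̂+x‖)/‖x‖` (the real-signal case of the
phase-invariant metric); PSNR on the [0,1] range and SSIM with standard
constants, both after sign alignment, with identical images reported at
a 100 dB cap instead of infinity; success rate = percentage of trials
below threshold 1e-5 (the table protocol does not publish its threshold;
1e-5 separates the observed bimodal error distribution — machine-level
successes vs O(0.1) stalls — by four orders of magnitude on either
side).  Convergence diagnostics expose `d = a − x`, `e = b − x`,
`g = d + e`, the contraction ratio `μ = ‖e‖/‖b‖`, and the angle cosines;
the worst-case bound flags use the δ = 0 (zero concentration-slack)
forms — the slack constants are documented, not estimated from data.
`f(u) = (u+1)/(1+3u²)` is the reading of the scalar bound consistent
with its printed maximum (grid maximum 1.0774 at u = 0.1547, below the
worst-case constant 1.08); μ is monitored pre-recombination, i.e. on the
fresh half-step solution against the anchor.

## Synthetic data and experiment protocols

Signals: i.i.d. uniform[0,1] (nonnegative case), i.i.d. standard normal
(general real case), both at 32×32 for success-rate tables; a built-in
deterministic piecewise-constant phantom (background, two rectangles, a
disc, values in [0,1]) stands in for downloadable test images so no
experiment needs network or image files; grayscale PNG/TIFF images can
be supplied instead.  The phantom has more contrast than natural
photographs — mean/RMS ≈ 0.77 vs ≈ 0.95 — so the random init's error is
~0.83 on it versus ~0.6–0.75 on natural images; trend checks are
unaffected.

Success-rate protocol: per trial, fresh signal, fresh masks, fresh init,
noise-free observations, default solver config; trial seeds are distinct
`SeedSequence(master_seed, spawn_key=(trial, role))` children for the
signal/masks/noise/init roles, so every table is reproducible
byte-for-byte from one master seed (modulo FP-library caveats).  Trace
and noisy benchmarks use nested mask prefixes (each K takes the first K
masks of one draw) and a shared noise seed, making the K- and
SNR-orderings matched-seed comparisons.  Desk-scale problem sizes
throughout: success tables at N = 1024 with 100 trials per cell,
recovery and basin checks at N = 64 and 1024, trend checks on 32×32 and
64×64 phantoms — small enough for a laptop CPU while keeping every
qualitative regime (under- and over-masked, noisy and noise-free).

## What the synthetic conditions do not cover

Uniform/Gaussian signals and the phantom have no natural-image
statistics (no 1/f spectrum, textures, or saturation), noise is ideal
AWGN on intensities (no Poisson shot noise, detector saturation, or
mask-calibration error), and masks are perfectly known i.i.d. draws with
no physical phase-shift-mask constraints.  Passing tests therefore
demonstrate the algorithmic claims (exact noise-free recovery, basin
radius, necessity of fusing, error trends in K and SNR), not end-to-end
performance on a real instrument.

## Known limitations

* Real signals only — complex recovery is a fundamentally different
  problem and is out of scope.
* The measured success rate for Gaussian 32×32 signals at K = 4 from the
  random init is ~96–97%, higher than the ~80% of the original
  comparison; the gap is consistent with this package's near-exact CG
  half-steps (tolerance 1e-12, warm-started) where the original
  implementation's inner solver is unspecified.  K = 2 (0%) and K ≥ 5
  (90–100%) agree.
* The re-implemented Wirtinger flow recovers images exactly at K = 4,
  where the original comparison reports an error plateau near 0.03; the
  published description does not reproduce that failure mode.
* ADMM (PhaseSplit-style) convergence remains sensitive to ρ; the
  default is tuned to the noise-free desk-scale problems only.
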