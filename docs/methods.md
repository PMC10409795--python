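# Methods

This note documents the models, the numerical choices behind them, what the
synthetic generator does and does not emulate, and the design decisions taken
where the design was genuinely open.

## Latent-state models

Both estimators are scalar Gaussian state-space models observed through a
Bernoulli channel (sigmoid link) plus a conditionally Gaussian continuous
channel, and share one code path (`cogwear.statespace`).

**Performance** (per n-back trial): z_{k+1} = ρ z_k + w_k with
w_k ~ N(0, σ_w²); observations are the correctness flag
m_k ~ Bernoulli(1/(1+e^{−(z_k+μ)})) and the log reaction time
log t_k = α₀ + α₁ z_k + δ_k, δ_k ~ N(0, σ_δ²). **Arousal** (per impulse-grid
step): a pure random walk x_{j+1} = x_j + ε_j; observations are the impulse
indicator n_j through the same link with offset β and, only at impulse steps,
the Gaussian mark r_j = γ₀ + γ₁ x_j + v_j. The arousal transition is
deliberately a random walk (no autoregressive pull), mirroring the slower,
integrative character of electrodermal arousal.

### Filtering and smoothing

The one-step update mean solves an implicit equation because the Bernoulli
innovation m − p is evaluated at the updated state. The residual is strictly
increasing in the state whenever the Bernoulli gain is nonnegative, so the
root is unique; we use Newton–Raphson from the predicted mean (tolerance
1e−8, 50 iterations) with a bracketed-bisection fallback — the bracket width
is the gain times the maximal innovation. The posterior variance adds the
Bernoulli information p(1−p) and, when the continuous channel is present,
α₁²/σ_δ² to the predicted precision, so filtered variance never exceeds
predicted variance. Smoothing is the standard fixed-interval recursion with
gain B_k = ρ s²_{k|k}/s²_{k+1|k}, anchored at the final filtered step.

Trials with no key press keep their (incorrect) binary observation and skip
the continuous update entirely.

### Identification of the offsets

μ and β are **not** re-estimated: they are plugged in as the logit of the
empirical event rate (clipped to [1/(2K), 1−1/(2K)] so the offset stays
finite). This identifies the state as a deviation from the subject's average
and is the conventional choice for these models. A consequence worth knowing:
the *level* of the latent state is confounded with the offset, because the
empirical rate absorbs the realized mean of the state trajectory. The
intercepts α₀ and γ₀ therefore recover only up to the compensating shift
α₁·mean(z) (resp. γ₁·mean(x)); recovery tests check the identified
combinations — the predicted mean log reaction time and the mean mark level —
alongside the slopes and dynamics, which are cleanly identified. For the
random-walk arousal state this matters more than for the mean-reverting
performance state, since the realized mean of a random walk has standard
deviation O(σ_ε √J).

### EM

The E-step runs filter + smoother and forms E[z_k²] = z²_{k|K} + s²_{k|K}
and E[z_{k+1}z_k] = z_{k+1|K} z_{k|K} + B_k s²_{k+1|K}. The M-step is closed
form: intercept/slope from 2×2 normal equations in the moments, variances as
averaged expected squared residuals, and ρ as the expected lag-1 regression
through the origin (the initial state enters as a point mass at zero). ρ is
not constrained; a warning is logged if |ρ̂| ≥ 1. Convergence is declared
when the largest parameter change, relative with an absolute floor of 1e−2
(so near-zero intercepts cannot stall detection), drops below the tolerance.

The expected complete-data objective (Q) contains
E[m(μ+z) − log(1+e^{μ+z})], which has no closed form; we evaluate it with a
second-order expansion around the smoothed mean (curvature −p(1−p)/2 times
the smoothed variance). Diagnostics record, per iteration, the M-step gain
Q(θ_new) − Q(θ_old) under the same E-step moments; EM guarantees this gain is
nonnegative, and the test suite audits exactly that. The *cross-iteration*
Q trajectory is also recorded but may drift in either direction as the
E-step distribution changes — that is expected EM behavior, not a defect.

### Numerical oracle

For series of length ≤ 12 an exact posterior is computed by dense-grid
forward–backward quadrature (≥ 2000 points spanning ±6 prior standard
deviations plus slack; the run aborts if more than 1e−6 posterior mass
touches the boundary). The Gaussian-approximate filter and smoother agree
with it to better than 1e−2 in the realistic parameter regime (process noise
≲ 0.1 per step); the approximation degrades gracefully for much larger
process noise, where single-step posteriors become visibly non-Gaussian.
The oracle also supports backward joint sampling, used to validate the
cross-moment formula by Monte Carlo.

## Skin-conductance deconvolution

The discrete forward model is y = H₀ y_p0 + H₁u + H₂q + ν: H₀ the decay of
the unknown initial phasic level, H₁ the causal convolution with the
bi-exponential kernel (zero at and before the impulse instant), H₂ sampled
uniform cubic B-splines (knot spacing 10 s by default — the tonic component
is slow by definition; the basis satisfies partition of unity over the whole
record). The impulse grid equals the 4 Hz sample grid (T_u = T_y).

Estimation is coordinate descent over (u, q, y_p0), λ, and (τ_r, τ_d):

1. **Sparse recovery at fixed kernel and λ.** The unpenalized block
   [H₀ | H₂] is projected out (QR), leaving a nonnegative lasso in u solved
   by FISTA on the reduced Gram form (Lipschitz constant by power iteration;
   stop when the iterate change falls below 1e−9 relative). Given u, the
   tonic coefficients and y_p0 are exact least squares.
2. **λ by generalized cross-validation.** GCV(λ) = M·RSS/(M−df)² with
   df = |active set| + P + 1 on a 20-point log grid. The grid is centred on
   the universal threshold σ̂‖h‖√(2 log N), where σ̂ is a
   median-absolute-deviation estimate from first differences — anchoring the
   search at the noise level avoids GCV's flat overfitting valley. Ties are
   broken toward parsimony: the largest λ within 10% of the GCV minimum.
3. **Kernel search.** (τ_r, τ_d) hill-climbs an 8×8 physiological grid
   (τ_r ∈ [0.1, 1.4] s, τ_d ∈ [1.5, 6] s) scored by the same GCV criterion —
   a too-fast kernel absorbs noise with many small impulses and is charged
   for them through the df term. Two rounds of (λ selection, climb) are run;
   every accepted move lowers the score, so the recorded per-sweep history
   is non-increasing.
4. **Debiasing.** Runs of adjacent active grid points are collapsed to their
   peak (one sweat-gland burst often smears across neighbours in penalized
   solutions), then amplitudes are re-fit without the penalty under the
   nonnegativity constraint on the recovered support.

Long recordings are split into 200 s blocks advanced by 100 s, the last
block end-aligned; stitching keeps each block's interior and discards 50 s
margins (first head and last tail retained), claiming every grid point
exactly once. Kernels are estimated per block and their spread is logged.
Recovered impulses above 0.01 µS (a sensor noise floor; configurable) become
the marked point process passed to the arousal model, on the same grid.

## EEG

Band-pass 1–50 Hz with a zero-phase fourth-order Butterworth (zero-phase so
power aligns with the session annotations), decimation 256 → 128 Hz with
anti-aliasing, then burst rejection: 1 s windows hopped by 0.5 s are flagged
when any channel's RMS z-score exceeds 5; flagged samples are excluded from
averages but never altered. This RMS-burst cleaner is a deliberately simple
artifact criterion — it catches gross movement/contact bursts, not ocular or
muscle components. The time–frequency transform is a constant-Q Gaussian
filterbank (12 bins/octave over 1–50 Hz, Q = 1/(2^{1/12}−1), 0.25 s hop)
applied in the FFT domain; band power is the mean squared magnitude over the
band's bins and the unmasked frames of each half-open session interval,
averaged over the temporoparietal pair (TP9, TP10) by default. Percent
change is reported against a named baseline session.

## Synthetic generator

The generator produces exactly what the estimators assume: the AR(1)
performance walk with Bernoulli + log-normal emissions; the random-walk
arousal trajectory with marked Bernoulli emissions; skin conductance built
from the *same* design matrices the deconvolution uses (so the noiseless
forward model is reproduced to machine precision); EEG as broadband Gaussian
noise plus unit-variance band-limited components scaled per session (power
therefore scales with amplitude squared). Streams are written in the
wristband export dialect (row 1 start epoch, row 2 sample rate; EDA 4 Hz,
BVP 64 Hz, ACC 32 Hz, TEMP 4 Hz, HR 1 Hz) and the headband CSV dialect
(timestamp + TP9/AF7/AF8/TP10 at 256 Hz), with ground-truth sidecar CSVs for
recovery tests.

Defaults: ρ = 0.98, σ_w² = 0.05, α₀ = 0, α₁ = −0.3, σ_δ² = 0.04, μ = 1
(≈ 73–90% correct rates); σ_ε² = 0.01 per 0.25 s step, γ₀ = 0.3, γ₁ = 0.5,
σ_v² = 0.01, β = −2 (sparse impulses). The session schedule defaults to 16
trials of 22 two-second stimuli with 5 s instructions, 10 s breaks, and a
20 s final relaxation — a 964 s session. Under the Gaussian mark model an
amplitude can come out negative; when rendering conductance the generator
floors amplitudes at 0.01 µS, since physical responses are nonnegative.
A long random walk can also drift so low that a simulated session contains
almost no impulses; recovery experiments draw seeds until the required
number of fittable datasets (≥ 5 impulses) is reached, as an experimenter
would only fit sessions with observable events.

What the generator does *not* emulate: motion artifacts and sensor dropout
(EDA noise is white Gaussian), real EEG spectra (1/f background, line noise,
ocular artifacts), sweat-dynamics nonstationarity, or any coupling between
the performance and arousal states. Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions — not
robustness to the ways real wearable data violate them.

## Problem sizes in the tests

Unit tests use short series (grid-oracle checks at K ≤ 12, EM audits at
300–800 steps); recovery experiments use 2000 trials / 5000 grid steps with
20 replicates; deconvolution recovery uses 20 single-block (200 s) traces at
20 dB SNR plus one 300 s block-vs-whole comparison; the end-to-end pipeline
test uses a four-session bundle with a compressed schedule (154 s sessions).
These sizes were chosen so the whole suite exercises every claim at the
scale where its tolerance is meaningful while remaining comfortable to run
on a laptop core.

## Known limitations

- The Gaussian approximation biases the filter slightly toward the prior at
  extreme states; the grid oracle quantifies this (< 1e−2 in the realistic
  regime).
- Intercept/level confounding described above: only identified combinations
  are recoverable, a property of the model class, not of this code.
- GCV with an active-set df is a heuristic for nonnegative lasso; the
  noise-anchored λ grid keeps it out of its known overfitting regime, but
  very dense impulse trains (< 2 s spacing) will still merge.
- The burst cleaner is not a substitute for full artifact decomposition;
  heavily contaminated EEG should be cleaned upstream.
- One fit spans all sessions of a subject (a single continuous latent
  trajectory); per-session refits are not implemented.
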