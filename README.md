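# cogwear

Latent brain-state estimation from wearable recordings: cognitive
**performance** from n-back behavior, cognitive **arousal** from wrist-worn
skin conductance, and EEG beta-band engagement summaries, with the
relationship analyses (linear beta–performance fits, inverted-U
arousal–performance fits, one-way ANOVA session comparisons) that tie them
together.

The package is aimed at researchers analyzing working-memory experiments
recorded with consumer wearables (wristband electrodermal activity in the
standard export dialect, four-channel headband EEG) who want the full chain
from raw exports to per-session state estimates. Because such datasets are
rarely public, a first-class synthetic generator simulates every stream with
exactly the generative structure the estimators assume and writes the same
file dialects, so the entire pipeline is testable offline.

## Models

**Performance.** Per trial k, a hidden state z_k follows an AR(1)
process z_{k+1} = ρ z_k + w_k, w_k ~ N(0, σ_w²), observed through a binary
correctness flag m_k ~ Bernoulli(p_k) with p_k = 1/(1+e^{−(z_k+μ)}) and a
log-normal reaction time log t_k = α₀ + α₁ z_k + δ_k, δ_k ~ N(0, σ_δ²).
μ is fixed at logit of the empirical correct rate. Filtering uses a
Gaussian-approximate recursion whose implicit mean update is solved by
Newton–Raphson, smoothing is fixed-interval, and θ = {ρ, σ_w², α₀, α₁, σ_δ²}
is learned by EM with closed-form M-steps.

**Arousal.** Skin conductance y(t) is deconvolved into a sparse nonnegative
impulse train u through the bi-exponential response kernel
h(t) = (e^{−t/τ_r} − e^{−t/τ_d})/(τ_r − τ_d), plus a cubic B-spline tonic
drift and an initial-condition decay:
y = H₀ y_p0 + H₁u + H₂q + ν. Estimation alternates sparse recovery (λ chosen
by generalized cross-validation) with a bounded physiological search over
(τ_r, τ_d); long recordings are processed in 200 s blocks with 100 s stride
and 50 s trimmed margins. The thresholded impulses form a marked point
process n_j, r_j driving a random-walk arousal state x_{j+1} = x_j + ε_j
with n_j ~ Bernoulli(1/(1+e^{−(x_j+β)})) and marks
r_j = γ₀ + γ₁ x_j + v_j, fit by the same filter/smoother/EM machinery.

**EEG.** Raw 256 Hz channels are band-passed 1–50 Hz (zero-phase), decimated
to 128 Hz, cleaned by sliding-window RMS burst rejection, transformed with a
constant-Q Gaussian filterbank, and summarized as mean beta-band (13–30 Hz)
power per labeled session with percent change against baseline.

## Worked example

```python
import numpy as np
from cogwear.synthetic import SessionSchedule, simulate_performance_trajectory
from cogwear.performance import fit_em

schedule = SessionSchedule(n_trials_per_session=2000, sessions=(("s1", 1.0),))
truth, series = simulate_performance_trajectory(schedule, seed=0)
params, smoothed, diag = fit_em(series, tol=1e-5, max_iter=60)
print(f"rho_hat={params.rho:.4f}  alpha1_hat={params.alpha1:.3f}  "
      f"corr={np.corrcoef(smoothed.mean, truth.z)[0, 1]:.3f}")
```

prints

```
rho_hat=0.9828  alpha1_hat=-0.286  corr=0.975
```

i.e. from 2000 simulated trials the EM recovers the generating state
dynamics (ρ = 0.98) and reaction-time slope (α₁ = −0.3), and the smoothed
state tracks the hidden trajectory with correlation 0.97.

The full pipeline runs from a YAML config or a directory of device exports:

```bash
cogwear simulate --output session_dir --seed 0
cogwear report --config run.yaml       # or the individual subcommands:
cogwear fit-performance --input session_dir/behavior.csv --output out
cogwear deconvolve --input session_dir/EDA.csv --output out
```

outputs land as `summaries.csv` (per session × task: correct %, mean
reaction time, mean performance and arousal states, beta power),
`relationships.json` (quadratic and linear fits), and `anova.csv`.

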