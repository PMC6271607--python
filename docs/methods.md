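# Methods

## The model

A single-particle trajectory is modeled as a switching linear dynamical
system (SLDS).  At each frame `i` a latent mode `s_i` selects the
parameters of a linear-Gaussian state-space model for the true position
`r_i` (a 3-vector in um) and its noisy measurement `psi_i`:

    r_{i+1} = mu_{s_i} + F_{s_i} r_i + eta_i,   eta_i ~ N(0, Sigma_{s_i})
    psi_i   = H r_i + eps_i,                    eps_i ~ N(0, R)

`H` is an observation selector (identity for full 3D imaging, `[I2 0]`
when the axial coordinate is not measured).  `R` — localization noise —
is shared by all modes.  Each mode is the exact sampling of an
overdamped-Langevin (multivariate Ornstein-Uhlenbeck) SDE

    dr_t = Phi B (rbar - r_t) dt + sqrt(2) C dW_t,   Phi = C C^T / kBT,

through `F = exp(-Phi B dt)`, `mu = (I - F) rbar`, and `Sigma` equal to
the finite-horizon Lyapunov integral of the diffusion `D = C C^T`,
evaluated exactly with the van Loan block-matrix-exponential
construction (no quadrature tolerance).  `kBT` is a pure scale, default
1, so `Phi = D`.  With the restoring force written `B (rbar - r)` the
stationary mean of the discrete recursion solves `m = mu + F m`, i.e.
`m = (I - F)^{-1} mu`; the algebraically equivalent form `-F^{-1} mu`
appears in the SPT literature and coincides whenever `mu = (I - F) rbar`
and `F` is invertible.  We implement `(I - F)^{-1} mu`, which is defined
for every stable `F`.

The number of modes is not fixed: modes and their transition structure
carry a sticky hierarchical-Dirichlet-process prior.  Shared stick
weights `beta ~ GEM(gamma)` are truncated at `L` modes (weak-limit
approximation, default `L = 10`), and each transition row is

    pi^(j) ~ DP(alpha + kappa, (alpha beta + kappa delta_j)/(alpha + kappa)),

so `kappa` adds prior mass on self-transitions; `rho = kappa/(kappa +
alpha)` quantifies the persistence bias.  Hyperpriors: `gamma ~
Gamma(a, b)`, `(alpha + kappa) ~ Gamma(a, b)`, `rho ~ Beta(c, d)`.

## Inference

A blocked Gibbs sweep (per single trajectory; trajectories are never
pooled) samples in order:

1. **Continuous path** `r_{0:T-1} | modes, theta, R, psi` — forward
   Kalman filter, backward sampling (simulation smoother) with
   per-step mode-indexed parameters.  Joseph-form covariance updates;
   tiered diagonal jitter on innovation covariances (1e-12 relative
   first, 1e-9 only if a Cholesky fails).  Diffuse initialization:
   mean `H^+ psi_0` (zero for hidden components), covariance `1e3 x`
   the measurement variance scale.
2. **Mode sequence** `s_{0:T-1} | r, theta, pi` — forward-filter
   backward-sample over the `L` modes; the emission of mode `k` at step
   `i` is the transition density `N(r_{i+1}; mu_k + F_k r_i, Sigma_k)`
   (the final label carries no emission); uniform prior on `s_0`.
3. **Mode parameters** — conjugate matrix-normal-inverse-Wishart
   regression of `r_{i+1}` on `[r_i; 1]` per mode; unoccupied modes are
   refreshed from the base measure (the same update with empty data).
   `R` from its inverse-Wishart conditional on the pooled residuals
   `psi - H r`.  Inverse-Wishart draws use an in-package Bartlett
   sampler (cross-checked against scipy).
4. **Transition structure** — rows `pi^(j) ~ Dirichlet(alpha beta +
   kappa delta_j + counts)`; `beta ~ Dirichlet(gamma/L + mbar)` with
   Chinese-restaurant auxiliary table counts and the usual binomial
   sticky-override correction.
5. **Concentrations** — auxiliary Beta/Bernoulli Gamma updates for
   `(alpha + kappa)`, Escobar-West augmentation for `gamma` (validated
   against a grid-evaluated density in the tests), and the Beta
   conditional for `rho` from the override counts.

Initialization: all steps in one mode, parameters at prior means.
Burn-in is the first half of the chain.  The reported segmentation is
the per-time mode of the post-burn-in marginal after aligning every
sweep's arbitrary labels to the final sweep's by Hungarian assignment.
Chains are bit-reproducible from a single integer seed; all randomness
flows through one numpy Generator (the numba kernels consume pre-drawn
variates).

## Base measure calibration

The benchmark centers the inverse-Wishart prior means for `Sigma` and
`R` on the data generating process's discretized values ("baseline");
the misspecification probes divide one of those means by 4 ("D/4",
"R/4").  Two deliberately asymmetric strengths:

* `Sigma` prior: df `= d + 2`, the vaguest with a defined mean, because
  each mode's diffusivity and drift must be learned from its own
  segment (the DGP's states differ 10x in diffusivity).
* `R` prior: informative, `r_pseudo = 1000` pseudo-observations
  (df `= d_obs + 2 + 1000`).  Localization noise in SPT is calibrated
  independently of any one trajectory (immobilized-bead measurements),
  so the model treats it as known up to roughly one trajectory's worth
  of weight.  A vague `R` prior would be swamped by the pooled-residual
  posterior and prior misspecification of `R` could not matter at all.

The matrix-normal prior on `[F mu]` is centered on a random walk
(`F = I`, `mu = 0`) with column covariance `10 I`.

Concentration hyperpriors: `gamma ~ Gamma(1, rate gamma_b)` with
baseline `gamma_b = 0.01` (a weakly informative prior, mean 100; the
posterior concentrates wherever the table counts put it),
`(alpha + kappa) ~ Gamma(1, rate 0.01)` (mean 100, so the sticky mass is
substantial), and `rho ~ Beta(rho_c, 1)` with baseline `rho_c = 25`.
The sensitivity-sweep knobs are `gamma_b` and `rho_c`; the row
concentration keeps its own fixed prior so the sticky mass does not vary
with the `gamma_b` knob.  A small-mean prior on `gamma` was evaluated
and rejected: it suppresses mode births so strongly that genuinely
multi-state trajectories under-segment and prior-misspecification
effects vanish.

## The synthetic data generator

Four states, selected each step by the current position (left-continuous
switching: the step `i -> i+1` uses the parameters of `s(r_i)`):

| state | region | change from base |
|---|---|---|
| 1 | elsewhere | — (base) |
| 2 | `z < C1` and `y < C2` | `D -> D/10` |
| 3 | `z > 0` and `y > C2` | `D -> D/10` and `B -> 10 B` (bound/confined) |
| 4 | `z < 0`, `y_alt < y < C2` | `rbar -> rbar_alt` (well-minimum shift) |

States 2 and 4 overlap when `C1 < 0`; precedence 3 > 2 > 4 > 1 makes
the rule single-valued.  Defaults (simulation units um, s): `dt = 1/22`
(22 frames/s), `D_base = 0.01 I`, effective reversion rates
`Phi B = diag(1, 1, 1e-6)` (the z axis is numerically a pure diffusion
at trajectory length 1000), `rbar_base = 0`, `R = (0.03)^2 I`,
`C1 = -0.3`, `C2 = 0.3`, `y_alt = -0.3`, `rbar_alt = (0.3, 0, -0.3)`,
`B_alt = 10 B_base`, `D_alt = D_base/10`.  All overridable in
`DGPConfig`.

Initial condition: axes that equilibrate within the trajectory start
from their stationary variance `D/rate`; the near-unit-root z axis
borrows the smallest equilibrated variance (the x/y scale, sd 0.1 um)
so trajectories start where the switching regions are actually visited
— the z axis's nominal stationary sd (~100 um) would scatter starting
points into regions the benchmark never probes.  With no equilibrated
axis at all the start collapses to the one-step diffusion scale.

A Markov-switching variant (labels drawn from a fixed transition
matrix, initial state from its stationary law) is provided for
illustrations and for clean two-state tests; the region rule is the
benchmark default.

What the generator does *not* emulate: blinking/bleaching photophysics,
non-Gaussian localization error, motion blur, anomalous diffusion,
nonlinear or time-dependent force fields.  Passing benchmarks therefore
demonstrate correct inference under the stated SLDS assumptions, not
robustness to those real-data effects.

## Scoring

Inferred labels are arbitrary, so each estimated sequence is first
mapped onto the truth by the injective assignment minimizing mismatches
(Hungarian algorithm on the negated confusion matrix).  Surplus
estimated labels map to a sink and count as errors wherever they occur,
penalizing over-segmentation; greedy per-label matching can double-map
labels and understate error.  The average Hamming distance is the
mismatch fraction after alignment (0 = perfect); Match Score = 1 -
Hamming.  Ensemble summaries report the mean with both the empirical
standard error (sd/sqrt(n)) and the sd, since printed "(x.xx)"
dispersion conventions vary.  Per-true-state conditional assignment
matrices give the finer breakdown.

## Problem sizes

The full benchmark profile is 500 trajectories x 1000 observations x
10,000 sweeps per scenario (hours of compute); `analysis/` defaults to
a reduced profile (40 x 1000 x 2,000).  The test suite and
`scripts/acceptance.py` use further scaled-down profiles (typically
4-12 trajectories, 200-1000 observations, 400-2000 sweeps; each file
states its sizes) chosen so the whole suite completes in minutes on one
CPU while the Monte-Carlo error of each checked quantity stays within
the stated tolerance.  Short chains cost segmentation accuracy: the
duplicate-mode metastability below consolidates roughly over thousands
of sweeps, so scaled-down means sit slightly above the full-profile
ones.

## Numerical and degenerate-input choices

* `discretize`/`continuize` are exact mutual inverses on stable
  parameters (round-trip tolerance 1e-8 relative); `continuize` refuses
  propagators with eigenvalues on the closed negative real axis (no
  real matrix logarithm) and near-unit-root stationary queries raise
  rather than returning enormous covariances.
* Exactly singular `Sigma` or `R` in the simulator use an
  eigen-clipped PSD square root, so noise-free limits are exact.
* Dirichlet draws with very small concentrations go through per-component
  Gamma draws with a floor, avoiding NaNs from underflow.
* A noise-free DGP (`R = 0`) gets a tiny PSD floor in prior
  construction — except in `R_div4` mode, where a degenerate prior is
  rejected outright.

## Known limitations

* **Duplicate-mode metastability.**  Blocked Gibbs conditions on drawn
  mode parameters, so two modes with near-identical parameters can
  split one true state for many sweeps (each duplicate's parameters
  sharpen on its own segment).  Merges do happen — wholesale, via the
  joint label draw, once the parameter draws wander close — but need
  on the order of a thousand sweeps on these problem sizes.  Split-merge
  moves would accelerate this and are deliberately out of scope.
* The hardest transition is State 1 <-> State 4 (only the fixed point
  moves; the position relaxes slowly toward the new well minimum), and
  conditional assignment matrices show exactly that confusion.
* The hidden-z observation model (3D state, 2D data) degrades
  segmentation badly — more state dimensions are not automatically
  better when they are unobserved.
* Missing-data gaps, non-uniform sampling, pooled multi-trajectory
  inference and the HDP-AR variants are out of scope.
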