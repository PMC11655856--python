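# Methods

## The model

Each brain region of each subject contributes one training sample: its BOLD
series `y ∈ R^{n_t}` (z-scored per region), the structural-connectivity-
weighted network input `u_j(t) = Σ_{i≠j} w_ji y_i(t)` from the other
regions' observed BOLD, and an optional global-mean external input. The
latent description of a sample is a state trajectory `x_{1:n_t}` (`n_s = 2`
states per encoder), an initial state `x_0`, region-level parameters
`θ^r ∈ R^2`, and subject-level parameters `θ^s ∈ R^2`.

Two structurally identical amortized encoders produce diagonal-Gaussian
posteriors over these quantities: a **shared** encoder fed by every sample,
and a **specific** encoder fed only by patient samples. `x`, `x_0` and
`θ^r` come from an LSTM (32 hidden units) over the per-timestep input
`(y_t, u_t)` concatenated with a small trainable subject embedding; `θ^s`
is read from per-subject mean/log-variance tables indexed by subject
identity. For controls, the specific states and parameters are zero-padded,
so control samples contribute no gradient to the specific encoder and the
specific outputs emitted for controls are meaningless by construction.

State evolution is a learned velocity field: a two-layer ReLU network `f`
over the augmented input
`x_aug = (x_shared, x_specific, θ^r_sh, θ^r_sp, θ^s_sh, θ^s_sp, u_ext, u_j)`
(width 14 under the reference dimensions), with transition
`x_{k+1} ~ N(x_k + Δt·f(x_aug), σ_s² I)` and `Δt` = 1 sample. We read `f`
as a velocity rather than a direct next-state map because fixed points of
the trained systems then live at `f = 0` with continuous-time stability
(all Jacobian eigenvalue real parts negative), which matches how the
attractor analysis interprets them; the literal map convention (`f(x) = x`,
`|λ| < 1`) is available behind a switch in the dynamics module for
sensitivity analysis. Observations decode linearly from the full
(shared ⊕ specific) state: `y_k ~ N(W·x_k + b, σ_o²)`.

## The loss

The training objective is the negative evidence lower bound, assembled per
batch as

```
L = L_encoder + L_decoder + L_source(controls) + L_source(patients)
L_encoder = L_{θ^s} + L_{θ^r} + L_{x0} − H[q(x_{1:n_t})]
```

with closed-form KLs against standard-normal priors, the subject-level KL
scaled by `1/n_regions` so each subject's `θ^s` prior is counted once
across its regional samples, and the transition/decoder terms evaluated at
a single reparameterized draw. Control samples contribute transition
likelihood only through the shared state coordinates. The Gaussian entropy
of the state posterior is included in the encoder term: without it the
objective is not a bound and the posterior variance collapses, degrading
the reparameterized transition and decoder expectations.

Every term is verified against an independent straight-line numpy
reimplementation on frozen noise draws to 1e-10 (the test suite's loss
oracle).

## Optimization

Adam at learning rate 0.003, batch size 64 (mixed groups), with five-fold
cross-validation over regional samples (80/20 per fold) and fold-stability
selection: encoded parameters (per-subject `θ^s` of both encoders and
subject-averaged per-region `θ^r`) are correlated between folds and the
fold with the highest mean correlation with the others is kept.

Two optimization details matter on short budgets and are defaults here:

- **Gained noise scales.** `log σ_s` and `log σ_o` are parametrized as
  `gain·w` with gain 4. The noise scales have to traverse roughly two
  orders of magnitude between initialization and fit; under Adam's
  near-uniform per-parameter step this parametrization shortens that
  traversal proportionally, and the model enters the regime where the
  heterogeneity parameters `θ` become informative several hundred batches
  earlier.
- **Polyak averaging** (decay 0.995) of all weights; the averaged model is
  the one returned. Encoded parameters fluctuate batch to batch; the
  average tracks their running mean.

Posterior log-variances are initialized at −2 (posterior sd ≈ 0.37) so the
reparameterization noise does not drown the early gradient signal, and
`σ_s, σ_o` start at 0.3, roughly the scale of the process/observation noise
of z-scored data.

All neural components (LSTM, dense layers, self-attention, Adam) run on the
package's own numpy reverse-mode autodiff engine (`ndcvae.nn`), with a
fused LSTM-sequence operation whose hand-written backpropagation-through-
time is validated against central finite differences.

## Synthetic cohorts

The generator plants a ground truth inside the model class. Per region, a
2-state damped linear oscillator `ẋ = A(θ)x + c·u_j + η` is integrated by
Euler–Maruyama with step 1 sample — exactly the discrete transition the
autoencoder trains, so recovery failures indict the inference machinery,
not a model mismatch. `A` has eigenvalues `−d ± iω`; damping `d` and
frequency `ω` (units 1/sample, rad/sample) follow regional gradients
(shared: `d` 0.08→0.40, `ω` 0.15→0.45 across the ring; specific, patients
only: reversed gradients, `d` 0.35→0.15, `ω` 0.30→0.15) and are scaled per
subject by log-normal factors (sd 0.20 shared, 0.25 specific, truncated at
±1.8 sd so every planted system is stable under the unit Euler step — the
truncated values are recorded as the truth). Observations mix the states
linearly with weights (1.0, 0.3) per subsystem, observation noise sd 0.1,
process noise sd 0.15, network coupling 0.1 into the first state
coordinate, and a 50-sample burn-in. Patients' three symptom scores are
linear in their specific subject parameters (a fixed 3×2 weight matrix)
plus Gaussian noise (sd 0.5); controls score exactly zero, as healthy
individuals do on clinical symptom scales. Expression maps are white noise
smoothed on the ring-distance graph, optionally mixing in a target map.

What the generator does **not** emulate: hemodynamic convolution, scanner
artifacts, site batch effects (site is a pure categorical covariate),
missing data, or nonlinear symptom links. Passing tests therefore
demonstrate that the machinery recovers structure the model class can
express — not that real fMRI obeys that class.

## Dynamics analysis

Per (subject, region) node, the velocity field with the encoded posterior
means, zero network input, and zero external input is handed to Powell-
hybrid root finding from 10 uniform starts in [−2, 2]; converged roots
(residual max-norm < 1e-8) are deduplicated at 1e-4. Jacobians come from
reverse-mode automatic differentiation through the field and are checked
against central finite differences at 1e-4. Control nodes are solved in the
shared-state subspace with the specific coordinates clamped at zero.
Attractor maps average, per region and group, the root nearest the node's
mean encoded state. Forward simulation closes the network input through
the decoded observations of the other regions at the previous step; with
zero noise it is exactly repeatable.

## Time-series features

Nine per-series descriptors plus a sliding-window dynamic-connectivity
variability:

| feature | definition | key invariance |
| --- | --- | --- |
| mean, standard deviation | arithmetic mean; sample (ddof = 1) sd | — |
| kernel entropy | differential entropy of a Silverman-bandwidth Gaussian KDE on a grid spanning data ± 3 bandwidths (nats) | + ln c under scaling by c |
| trev3 denom | `mean(d²)^{3/2}`, `d_t = x_{t+3} − x_t` (full normalized ratio behind a flag) | degree-3 homogeneous |
| std of 4th derivative | sd of the 4-fold first difference | level-invariant |
| PP mean stat | Phillips–Perron `Z_τ` (Bartlett/Newey–West long-run variance) averaged over truncation lags 0–5; at lag 0 it reduces to the Dickey–Fuller t-ratio | — |
| walker dist-diff | KS distance between the series and a pursuing walker `w_{t+1} = w_t + 0.5(x_t − w_t)` | — |
| visibility exp-nlogL | mean negative log-likelihood of natural-visibility-graph degrees (series z-scored first) under an exponential fit to min-shifted degrees | — |
| variance ratio z | Lo–MacKinlay VR(4) homoscedastic z from overlapping increments with bias correction | — |
| dynamic variability | `V_k = 1 − mean corr(F_i,k, F_j,k)` over window pairs, `F_i,k` = region k's window-i correlations with all other regions; windows of 20 samples, step 4, left-aligned, remainder dropped | 0 when connectivity is static |

Features are computed on the raw inferred state series (no internal
z-scoring — mean and sd are themselves features), except the visibility
graph, which standardizes first. Internals the toolbox convention leaves
open (walker constant, PP lag set, exponential-fit shift, VR flavor) are
fixed as above and exposed in keyword arguments; equivalence with any
specific MATLAB toolbox is not claimed. Deterministic features are verified
against brute-force loop implementations to 1e-10 on random fixtures; the
test statistics are verified by null calibration (rejection rates within
the 95% binomial interval of the nominal 5% over 500 replicates).

## Association machinery

Subject dissimilarity: |difference| for scalars, Euclidean norm for
parameter blocks, 0/1 for categoricals. RSA compares Kendall τ (lower
triangles) of parameter-block dissimilarities against a target
dissimilarity across 10 posterior draws per encoder, with an unpaired
t-test. Covariates (age, sex, site contrasts) are OLS-residualized out of
responses before PLS.

PLS takes successive leading singular pairs of the z-scored cross-
covariance `X'Y` with deflation of X by each score. Components are judged
by permutation of Y's rows (add-one p-values, Benjamini–Hochberg across
components; significance at `p ≤ α` — the rejection rule appropriate for
discrete permutation p-values). Loadings are Pearson correlations of the
original variables with the latent scores. The gene mode replaces row
permutation with variogram-matched surrogate maps of the response map, and
normalizes gene weights by bootstrap (regions resampled with replacement,
component sign realigned to the original weights) standard errors;
|z| > 3 defines the reported gene sets, and a top/bottom-n ranking by
Pearson correlation with the map is available for validation.

Surrogate maps permute the target, re-smooth with inverse-distance k-NN
kernels, regress the target variogram on the smoothed one, recombine
`√|β|·smoothed + √|α|·noise`, and rescale to the target's mean/variance.
k is chosen per draw by the realized (post-rescale) surrogate's variogram
SSE against the target — with the rescale in place this choice, rather
than the regression SSE, is what actually delivers the variogram match.
Variogram bins are equal-count up to the 25th-percentile distance, capped
so each bin keeps ≥ 25 pairs.

## Classifier

Per time step, a linear embedding plus residual fully-connected blocks
encode the regional pattern; a sinusoidal positional code is added and
pre-norm self-attention blocks (width 64, 4 heads at reference settings)
model the temporal structure; mean pooling feeds a sigmoid head trained
with binary cross-entropy under Adam (3e-4, ÷10 every 10 epochs, batch 64,
20 epochs at reference settings). Inputs are z-scored per region. The
specific-information contrast classifies series simulated from the trained
generative model with and without the specific components and compares
accuracies over repeated train/test splits.

## Problem sizes in the test and acceptance runs

The packaged checks run at desk scale, chosen as the smallest sizes at
which each property is cleanly measurable: cohorts of 40 subjects ×
30 regions × 225 samples with 2000 training batches for parameter
recovery; 500 replicates for the null calibrations; 60 draws for the
surrogate-quality comparison; classifier contrasts on time-decimated
(stride 3) series with a reduced classifier (width 16, 1+1 blocks,
4 epochs) over repeated splits. The reference-scale constants (927
subjects, 100 regions, 30000 batches, width-64 classifier) remain the
package defaults.

## Known limitations

- **Contrastive identifiability.** Nothing in the objective penalizes the
  shared encoder for absorbing patient-specific variance: for a patient
  sample, symptom-linked structure can flow through either encoder at
  equal KL cost. On synthetic cohorts at desk scale the shared encoder's
  per-sample region-level parameters do absorb it, so dissimilarity
  analyses over the full parameter blocks need not favor the specific
  encoder. Total-correlation or adversarial penalties would enforce the
  separation; they are outside the model family implemented here.
- **Simulation realism.** Freely simulated series are smoother than the
  data they were fit to — the per-timestep posterior soaks up variability
  during training, leaving small learned noise scales — so classifiers
  trained on real series can behave degenerately on simulated ones.
  Contrasts that compare classifier accuracy between real and simulated
  inputs are reliable only when the generative fit is close.
- Per-timestep diagonal state posteriors (no autoregressive structure);
  the encoder is causal (unidirectional LSTM), so early-time state
  estimates use no future context.
- The network input uses observed BOLD of other regions, making samples
  conditionally independent; feedback through latent states is only
  closed in forward simulation.
- Fold-stability selection correlates a fixed parameter concatenation;
  other choices (states, per-sample parameters) are possible.
- The surrogate-map generator targets the variogram-matching property,
  not numerical identity with any reference implementation.
- Recovery benchmarks use a generator inside the model class; robustness
  to model mismatch (hemodynamics, nonstationarity) is untested.
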