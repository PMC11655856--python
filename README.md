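# ndcvae

Contrastive variational autoencoding of regional brain dynamics: separate
the dynamical features **specific to a patient group** from the features
**shared** with controls, then quantify what the specific features carry —
attractor geometry, symptom associations, and classifier-visible
disorder information.

## Who this is for

Computational psychiatry / network-neuroscience researchers who fit
individualized dynamical models to regional fMRI time series of a
two-group (patient/control) cohort and want disorder-specific latent
parameters and states, with the downstream statistical machinery
(representational similarity analysis, PLS with permutation, bootstrap and
spatial-surrogate nulls, fixed-point analysis, a spatiotemporal
classifier) in one reproducible pipeline. Everything runs on synthetic
cohorts with known ground truth, so each stage can be validated before it
touches real data.

## The model

Each region of each subject is a sample `(y, u, c)`: its BOLD series `y`,
the structural-connectivity-weighted input `u_j(t) = Σ_i w_ji y_i(t)` from
other regions, and the subject identity `c`. Two structurally identical
recurrent encoders — one fed by all samples (*shared*), one fed only by
patient samples (*specific*) — infer Gaussian posteriors over a state
trajectory `x`, region-level parameters `θ^r`, and subject-level
parameters `θ^s`. A learned two-layer velocity field ties states together,

&nbsp;&nbsp;`ẋ = f(x, θ^r, θ^s, u_ext, u_j) + η`,&nbsp;&nbsp;
`x_{k+1} ~ N(x_k + Δt·f(x_aug), σ_s²)`,

with the specific slots of `x_aug` zero-padded for controls, and a linear
decoder `y_k ~ N(W·x_k + b, σ_o²)` reconstructs the signal from the full
state. The negative ELBO decomposes into encoder KL terms, group-split
transition terms, and the decoder term; training is Adam with five-fold
cross-validation and fold-stability model selection. Fixed points of the
learned per-node systems (`f = 0`, stability from Jacobian eigenvalues)
give attractor brain maps; features of the specific state series feed PLS
against symptom scores; a residual-FC + self-attention classifier measures
how much disorder information survives in simulated BOLD.

See `docs/methods.md` for the full model, loss, and every numerical choice.

## Worked example

```python
import numpy as np
from scipy import stats
from ndcvae.synthetic import generate_cohort
from ndcvae.data import ModelConfig, assemble_dataset
from ndcvae.training import TrainConfig, make_folds, train_fold

cohort = generate_cohort(n_controls=20, n_patients=20, n_regions=30,
                         n_time=225, seed=7)
mc = ModelConfig(n_time=225, n_regions=30)
ds = assemble_dataset(cohort.bold, cohort.phenotypes["group"],
                      cohort.connectome, mc)
fold = make_folds(len(ds), 5, seed=0)[0]          # 960 → 768/192 samples
result = train_fold(ds, fold, TrainConfig(n_batches=2000, seed=0), mc)

enc, gt = result.encoded, cohort.ground_truth
r_region = max(
    abs(stats.pearsonr(enc["shared.region"].mean(axis=0)[:, p],
                       gt.true_region_params["shared"][:, 0]).statistic)
    for p in range(2))
pat = gt.specific_mask
r_subject = max(
    abs(stats.pearsonr(enc["specific.subject"][pat][:, p],
                       cohort.phenotypes.loc[pat, s]).statistic)
    for p in range(2) for s in ("score_pos", "score_neg", "score_gen"))
print(f"region-parameter recovery r = {r_region:.3f}")
print(f"subject-symptom recovery r = {r_subject:.3f}")
```

On one CPU this trains in a few minutes and prints

```
region-parameter recovery r = 0.615
subject-symptom recovery r = 0.426
```

meaning the shared encoder's region-level parameter recovered the planted
regional damping gradient (|r| = 0.62 across 30 regions), and the specific
encoder's subject-level parameter tracked the planted symptom scores
(|r| = 0.43 across 20 patients) — the two recovery checks at the heart of
the synthetic validation.

The same workflow is scriptable end to end:

```bash
ndcvae all --config demo.yaml --out run/ --seed 1
```

with per-stage YAML sections (`cohort`, `model`, `train`, `dynamics`,
`features`, `associate`, `classify`); stages hash their inputs and are
skipped on rerun when up to date.

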