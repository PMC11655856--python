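"""The contrastive neurodynamic variational autoencoder.

Two structurally identical recurrent encoders — a *shared* encoder fed by
every sample and a *specific* encoder fed only by patient samples — emit
diagonal-Gaussian posteriors over a per-region state trajectory, an initial
state, region-level parameters, and (via per-subject tables) subject-level
parameters.  A learned two-layer velocity field ``f`` ties consecutive
states together: the transition mean is ``x_k + Δt·f(x_aug)`` where
``x_aug`` concatenates both encoders' states and parameters with the
external and network inputs.  A linear decoder maps the full (shared ⊕
specific) state to the observed BOLD sample.  For control samples the
specific slots are zero-padded, so the specific encoder receives no
gradient from them.

The training objective is the negative evidence lower bound, decomposed into
encoder KL terms (region-level, initial-state, and 1/n_regions-scaled
subject-level, plus the Gaussian entropy of the state posterior),
group-split transition likelihood terms, and the decoder likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from .data import CohortDataset, Group, ModelConfig, RegionalSample
from .nn import LSTM, Linear, Module, Tensor, concat

__all__ = [
    "Batch",
    "EncoderPosterior",
    "Encoder",
    "LossBreakdown",
    "NDCVAE",
    "make_batch",
    "gaussian_kl",
    "save_checkpoint",
    "load_checkpoint",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class Batch:
    """Numpy view of a minibatch of regional samples."""

    y: np.ndarray  # (B, T)
    u: np.ndarray  # (B, T)
    u_ext: np.ndarray  # (B, T)
    subject_index: np.ndarray  # (B,) int
    is_patient: np.ndarray  # (B,) bool
    region_index: np.ndarray  # (B,) int

    def __len__(self) -> int:
        return self.y.shape[0]


def make_batch(samples: list[RegionalSample]) -> Batch:
    return Batch(
        y=np.stack([s.bold for s in samples]),
        u=np.stack([s.network_input for s in samples]),
        u_ext=np.stack([s.external_input for s in samples]),
        subject_index=np.array([s.subject_index for s in samples], dtype=int),
        is_patient=np.array([s.group == Group.PATIENT for s in samples], dtype=bool),
        region_index=np.array([s.region_index for s in samples], dtype=int),
    )


@dataclass
class EncoderPosterior:
    """Diagonal-Gaussian posterior parameters emitted by one encoder."""

    state_mean: Tensor  # (B, T, n_states)
    state_logvar: Tensor
    x0_mean: Tensor  # (B, n_states)
    x0_logvar: Tensor
    region_mean: Tensor  # (B, m_region)
    region_logvar: Tensor
    subject_mean: Tensor  # (B, m_subject), rows of the subject table
    subject_logvar: Tensor


class Encoder(Module):
    """Recurrent amortized encoder over (y_t, u_t) plus a subject embedding.

    The per-timestep hidden state parameterizes the state posterior; the
    final hidden state parameterizes the initial-state and region-level
    posteriors.  Subject-level parameters are encoded directly from the
    subject's identity through trainable mean/log-variance tables.
    """

    def __init__(self, config: ModelConfig, n_sub: int, rng: np.random.Generator):
        h = config.lstm_hidden
        self.config = config
        self.embed = Tensor(
            rng.normal(scale=0.1, size=(n_sub, config.subject_embed_dim)),
            requires_grad=True,
        )
        self.lstm = LSTM(2 + config.subject_embed_dim, h, rng)
        self.state_head = Linear(h, 2 * config.n_states, rng)
        self.x0_head = Linear(h, 2 * config.n_states, rng)
        self.region_head = Linear(h, 2 * config.m_region, rng)
        # start posteriors narrow (sd ≈ e^{-1} ≈ 0.37): less reparameterization
        # noise early in training speeds up learning of the posterior means
        self.state_head.bias.data[config.n_states :] = -2.0
        self.x0_head.bias.data[config.n_states :] = -2.0
        self.region_head.bias.data[config.m_region :] = -2.0
        # per-subject tables: posterior means and log-variances of θ^s
        self.subject_mean_table = Tensor(
            rng.normal(scale=0.1, size=(n_sub, config.m_subject)), requires_grad=True
        )
        self.subject_logvar_table = Tensor(
            np.full((n_sub, config.m_subject), -2.0), requires_grad=True
        )

    def __call__(self, batch: Batch) -> EncoderPosterior:
        ns = self.config.n_states
        mr = self.config.m_region
        n_b, n_t = batch.y.shape
        yu = np.stack([batch.y, batch.u], axis=2)  # (B, T, 2)
        emb = self.embed[list(batch.subject_index)]  # (B, E)
        emb_t = emb.reshape(n_b, 1, -1) + Tensor(
            np.zeros((n_b, n_t, self.config.subject_embed_dim))
        )
        enc_in = concat([Tensor(yu), emb_t], axis=2)
        hs, h_last = self.lstm(enc_in)
        state = self.state_head(hs)  # (B, T, 2 ns)
        x0 = self.x0_head(h_last)
        region = self.region_head(h_last)
        idx = list(batch.subject_index)
        return EncoderPosterior(
            state_mean=state[:, :, :ns],
            state_logvar=state[:, :, ns:],
            x0_mean=x0[:, :ns],
            x0_logvar=x0[:, ns:],
            region_mean=region[:, :mr],
            region_logvar=region[:, mr:],
            subject_mean=self.subject_mean_table[idx],
            subject_logvar=self.subject_logvar_table[idx],
        )


def reparameterized_sample(mean: Tensor, logvar: Tensor, eps: np.ndarray) -> Tensor:
    """Draw ``mean + exp(logvar/2)·ε`` with gradients through mean and logvar."""
    return mean + (logvar * 0.5).exp() * Tensor(eps)


def gaussian_kl(mean: Tensor, logvar: Tensor, axis=-1) -> Tensor:
    """KL[N(mean, diag exp(logvar)) || N(0, I)], summed over ``axis``."""
    return (0.5 * (mean * mean + logvar.exp() - logvar - 1.0)).sum(axis=axis)


def gaussian_entropy(logvar: Tensor, axis=-1) -> Tensor:
    """Entropy of a diagonal Gaussian, summed over ``axis`` (nats)."""
    return (0.5 * (logvar + LOG_2PI + 1.0)).sum(axis=axis)


@dataclass
class LossBreakdown:
    """Per-sample-averaged components of the negative ELBO."""

    l_theta_s: float
    l_theta_r: float
    l_x0: float
    neg_entropy: float  # −H[q(x_{1:T})], part of the encoder term
    l_encoder: float
    l_source_nc: float
    l_source_scz: float
    l_decoder: float
    total: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class NDCVAE(Module):
    def __init__(self, config: ModelConfig, n_sub: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.n_sub = n_sub
        self.shared = Encoder(config, n_sub, rng)
        self.specific = Encoder(config, n_sub, rng)
        self.source_w1 = Linear(config.aug_width, config.source_hidden, rng)
        self.source_w2 = Linear(config.source_hidden, 2 * config.n_states, rng)
        self.decoder = Linear(2 * config.n_states, 1, rng)
        # noise scales must traverse orders of magnitude during fitting; the
        # gained parametrization log σ = gain·w lets them adapt quickly under
        # a uniform learning rate
        self._sigma_gain = 4.0
        self.log_sigma_s_raw = Tensor(np.log(0.3) / self._sigma_gain,
                                      requires_grad=True)
        self.log_sigma_o_raw = Tensor(np.log(0.3) / self._sigma_gain,
                                      requires_grad=True)

    # ------------------------------------------------------------- components
    def source_step(self, x_aug: Tensor) -> Tensor:
        """Velocity field ``f(x_aug) = W2 φ(W1 x_aug + b1) + b2``, ReLU φ."""
        if x_aug.shape[-1] != self.config.aug_width:
            raise ValueError(
                f"x_aug width {x_aug.shape[-1]} != {self.config.aug_width}"
            )
        return self.source_w2(self.source_w1(x_aug).relu())

    def augment_states(
        self,
        shared_x: Tensor,
        specific_x: Tensor | None,
        shared_region: Tensor,
        specific_region: Tensor | None,
        shared_subject: Tensor,
        specific_subject: Tensor | None,
        u_ext: np.ndarray,
        u: np.ndarray,
    ) -> Tensor:
        """Assemble the source-model input block over a trajectory.

        ``shared_x`` is (B, T, n_states); parameter blocks are (B, m).  For
        control samples the specific operands are ``None`` and their slots
        are zero-filled, keeping the block width identical for both groups.
        """
        n_b, n_t, ns = shared_x.shape
        cfg = self.config

        def tile(p: Tensor, width: int) -> Tensor:
            return p.reshape(n_b, 1, width) + Tensor(np.zeros((n_b, n_t, width)))

        def zeros(width: int) -> Tensor:
            return Tensor(np.zeros((n_b, n_t, width)))

        parts = [
            shared_x,
            specific_x if specific_x is not None else zeros(ns),
            tile(shared_region, cfg.m_region),
            tile(specific_region, cfg.m_region)
            if specific_region is not None
            else zeros(cfg.m_region),
            tile(shared_subject, cfg.m_subject),
            tile(specific_subject, cfg.m_subject)
            if specific_subject is not None
            else zeros(cfg.m_subject),
            Tensor(u_ext[:, :, None]),
            Tensor(u[:, :, None]),
        ]
        return concat(parts, axis=2)

    def transition_loglik(
        self, x_full: Tensor, x0_full: Tensor, x_aug: Tensor, coord_mask: np.ndarray
    ) -> Tensor:
        """Per-sample Gaussian log-likelihood of the realized trajectory under
        the learned transitions ``x_{k+1} ~ N(x_k + Δt·f(x_aug_k), σ_s²)``.

        ``coord_mask`` (B, 2·n_states) selects which state coordinates
        contribute: shared only for controls, all for patients.
        """
        x_prev = concat([x0_full.reshape(x0_full.shape[0], 1, -1),
                         x_full[:, :-1, :]], axis=1)
        mean_next = x_prev + self.config.euler_step * self.source_step(x_aug)
        resid = x_full - mean_next
        sig2 = (2.0 * self.log_sigma_s).exp()
        nll_el = 0.5 * (LOG_2PI + 2.0 * self.log_sigma_s + resid * resid / sig2)
        masked = nll_el * Tensor(coord_mask[:, None, :])
        return -masked.sum(axis=2).sum(axis=1)  # (B,)

    def decode_loglik(self, y: np.ndarray, x_full: Tensor) -> Tensor:
        """Per-sample Gaussian log-likelihood of the observations around the
        linear readout of the full (shared ⊕ specific) state."""
        if y.shape[1] != x_full.shape[1]:
            raise ValueError("observation/state length mismatch")
        y_hat = self.decoder(x_full)[:, :, 0]
        resid = Tensor(y) - y_hat
        sig2 = (2.0 * self.log_sigma_o).exp()
        nll = 0.5 * (LOG_2PI + 2.0 * self.log_sigma_o + resid * resid / sig2)
        return -nll.sum(axis=1)

    # ------------------------------------------------------------------ loss
    def _noise_for(self, key: str, shape, noise, rng) -> np.ndarray:
        if noise is not None:
            return noise[key]
        return rng.standard_normal(shape)

    def total_loss(
        self,
        batch: Batch,
        rng: np.random.Generator | None = None,
        noise: dict[str, np.ndarray] | None = None,
    ) -> tuple[Tensor, LossBreakdown]:
        """Negative ELBO of a mixed batch, with componentwise bookkeeping.

        Noise draws can be supplied explicitly (keys ``{shared,specific}.
        {state,x0,region,subject}``) for reproducibility; otherwise ``rng``
        is used.  All components are averaged per sample in the batch.
        """
        if rng is None and noise is None:
            rng = np.random.default_rng(0)
        cfg = self.config
        n_b, n_t = batch.y.shape
        ns = cfg.n_states
        pat = np.where(batch.is_patient)[0]
        n_pat = len(pat)

        post_sh = self.shared(batch)
        eps = {
            "shared.state": self._noise_for("shared.state", (n_b, n_t, ns), noise, rng),
            "shared.x0": self._noise_for("shared.x0", (n_b, ns), noise, rng),
            "shared.region": self._noise_for(
                "shared.region", (n_b, cfg.m_region), noise, rng
            ),
            "shared.subject": self._noise_for(
                "shared.subject", (n_b, cfg.m_subject), noise, rng
            ),
        }
        x_sh = reparameterized_sample(
            post_sh.state_mean, post_sh.state_logvar, eps["shared.state"]
        )
        x0_sh = reparameterized_sample(
            post_sh.x0_mean, post_sh.x0_logvar, eps["shared.x0"]
        )
        thr_sh = reparameterized_sample(
            post_sh.region_mean, post_sh.region_logvar, eps["shared.region"]
        )
        ths_sh = reparameterized_sample(
            post_sh.subject_mean, post_sh.subject_logvar, eps["shared.subject"]
        )

        # specific encoder sees only the patient sub-batch; realized values are
        # scattered back into zero-padded full-batch blocks.
        def scatter(t_sub: Tensor, shape) -> Tensor:
            buf = Tensor(np.zeros(shape))
            idx_arr = np.zeros(shape[0], dtype=bool)
            idx_arr[pat] = True
            # differentiable scatter: zero tensor + indexed add via one-hot matmul
            onehot = np.zeros((shape[0], n_pat))
            onehot[pat, np.arange(n_pat)] = 1.0
            if t_sub.ndim == 2:
                return buf + Tensor(onehot) @ t_sub
            flat = t_sub.reshape(n_pat, -1)
            return buf + (Tensor(onehot) @ flat).reshape(*shape)

        if n_pat > 0:
            sub = Batch(
                y=batch.y[pat],
                u=batch.u[pat],
                u_ext=batch.u_ext[pat],
                subject_index=batch.subject_index[pat],
                is_patient=batch.is_patient[pat],
                region_index=batch.region_index[pat],
            )
            post_sp = self.specific(sub)
            eps_sp = {
                "specific.state": self._noise_for(
                    "specific.state", (n_pat, n_t, ns), noise, rng
                ),
                "specific.x0": self._noise_for(
                    "specific.x0", (n_pat, ns), noise, rng
                ),
                "specific.region": self._noise_for(
                    "specific.region", (n_pat, cfg.m_region), noise, rng
                ),
                "specific.subject": self._noise_for(
                    "specific.subject", (n_pat, cfg.m_subject), noise, rng
                ),
            }
            x_sp = scatter(
                reparameterized_sample(
                    post_sp.state_mean, post_sp.state_logvar, eps_sp["specific.state"]
                ),
                (n_b, n_t, ns),
            )
            x0_sp = scatter(
                reparameterized_sample(
                    post_sp.x0_mean, post_sp.x0_logvar, eps_sp["specific.x0"]
                ),
                (n_b, ns),
            )
            thr_sp = scatter(
                reparameterized_sample(
                    post_sp.region_mean,
                    post_sp.region_logvar,
                    eps_sp["specific.region"],
                ),
                (n_b, cfg.m_region),
            )
            ths_sp = scatter(
                reparameterized_sample(
                    post_sp.subject_mean,
                    post_sp.subject_logvar,
                    eps_sp["specific.subject"],
                ),
                (n_b, cfg.m_subject),
            )
        else:
            x_sp = Tensor(np.zeros((n_b, n_t, ns)))
            x0_sp = Tensor(np.zeros((n_b, ns)))
            thr_sp = Tensor(np.zeros((n_b, cfg.m_region)))
            ths_sp = Tensor(np.zeros((n_b, cfg.m_subject)))

        x_full = concat([x_sh, x_sp], axis=2)
        x0_full = concat([x0_sh, x0_sp], axis=1)
        # the transition at step k departs from the previous state
        x_prev_sh = concat([x0_sh.reshape(n_b, 1, ns), x_sh[:, :-1, :]], axis=1)
        x_prev_sp = concat([x0_sp.reshape(n_b, 1, ns), x_sp[:, :-1, :]], axis=1)
        x_aug = self.augment_states(
            x_prev_sh, x_prev_sp, thr_sh, thr_sp, ths_sh, ths_sp,
            batch.u_ext, batch.u,
        )

        coord_mask = np.ones((n_b, 2 * ns))
        coord_mask[~batch.is_patient, ns:] = 0.0
        trans_ll = self.transition_loglik(x_full, x0_full, x_aug, coord_mask)
        dec_ll = self.decode_loglik(batch.y, x_full)

        is_pat = Tensor(batch.is_patient.astype(float))
        inv_b = 1.0 / n_b
        l_source_nc = -(trans_ll * (1.0 - is_pat)).sum() * inv_b
        l_source_scz = -(trans_ll * is_pat).sum() * inv_b
        l_decoder = -dec_ll.sum() * inv_b

        kl_thr = gaussian_kl(post_sh.region_mean, post_sh.region_logvar).sum()
        kl_x0 = gaussian_kl(post_sh.x0_mean, post_sh.x0_logvar).sum()
        kl_ths = gaussian_kl(post_sh.subject_mean, post_sh.subject_logvar).sum()
        ent = gaussian_entropy(post_sh.state_logvar).sum(axis=1).sum()
        if n_pat > 0:
            kl_thr = kl_thr + gaussian_kl(post_sp.region_mean, post_sp.region_logvar).sum()
            kl_x0 = kl_x0 + gaussian_kl(post_sp.x0_mean, post_sp.x0_logvar).sum()
            kl_ths = kl_ths + gaussian_kl(
                post_sp.subject_mean, post_sp.subject_logvar
            ).sum()
            ent = ent + gaussian_entropy(post_sp.state_logvar).sum(axis=1).sum()
        l_theta_r = kl_thr * inv_b
        l_x0 = kl_x0 * inv_b
        # each subject's θ^s prior counted once across its n_regions samples
        l_theta_s = kl_ths * (inv_b / cfg.n_regions)
        neg_entropy = -ent * inv_b
        l_encoder = l_theta_s + l_theta_r + l_x0 + neg_entropy

        total = l_encoder + l_decoder + l_source_nc + l_source_scz
        if not np.isfinite(total.item()):
            parts = {
                "l_encoder": l_encoder.item(),
                "l_decoder": l_decoder.item(),
                "l_source_nc": l_source_nc.item(),
                "l_source_scz": l_source_scz.item(),
            }
            bad = [k for k, v in parts.items() if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite loss components: {bad}")
        breakdown = LossBreakdown(
            l_theta_s=l_theta_s.item(),
            l_theta_r=l_theta_r.item(),
            l_x0=l_x0.item(),
            neg_entropy=neg_entropy.item(),
            l_encoder=l_encoder.item(),
            l_source_nc=l_source_nc.item(),
            l_source_scz=l_source_scz.item(),
            l_decoder=l_decoder.item(),
            total=total.item(),
        )
        return total, breakdown

    # -------------------------------------------------------------- inference
    def encode_dataset(self, dataset: CohortDataset, batch_size: int = 256) -> dict:
        """Posterior means for every sample: state trajectories and parameter
        tables, organised per encoder.

        Returns arrays keyed ``{shared,specific}.{states,region,subject}``:
        states (n_sub, n_regions, T, n_states), region (n_sub, n_regions,
        m_region), subject (n_sub, m_subject).  Specific-encoder outputs for
        control subjects are zero (undefined by construction).
        """
        cfg = self.config
        n_sub, n_reg = dataset.n_sub, dataset.n_regions
        n_t = dataset.samples[0].bold.shape[0]
        out = {
            "shared.states": np.zeros((n_sub, n_reg, n_t, cfg.n_states)),
            "specific.states": np.zeros((n_sub, n_reg, n_t, cfg.n_states)),
            "shared.region": np.zeros((n_sub, n_reg, cfg.m_region)),
            "specific.region": np.zeros((n_sub, n_reg, cfg.m_region)),
            "shared.subject": self.shared.subject_mean_table.data.copy(),
            "specific.subject": self.specific.subject_mean_table.data.copy(),
            "is_patient": np.zeros(n_sub, dtype=bool),
        }
        samples = dataset.samples
        for start in range(0, len(samples), batch_size):
            chunk = samples[start : start + batch_size]
            batch = make_batch(chunk)
            post = self.shared(batch)
            si, ri = batch.subject_index, batch.region_index
            out["shared.states"][si, ri] = post.state_mean.data
            out["shared.region"][si, ri] = post.region_mean.data
            out["is_patient"][si] = batch.is_patient
            if batch.is_patient.any():
                pat = np.where(batch.is_patient)[0]
                sub = Batch(
                    y=batch.y[pat],
                    u=batch.u[pat],
                    u_ext=batch.u_ext[pat],
                    subject_index=si[pat],
                    is_patient=batch.is_patient[pat],
                    region_index=ri[pat],
                )
                post_sp = self.specific(sub)
                out["specific.states"][si[pat], ri[pat]] = post_sp.state_mean.data
                out["specific.region"][si[pat], ri[pat]] = post_sp.region_mean.data
        # specific subject rows of controls are meaningless: zero them
        out["specific.subject"][~out["is_patient"]] = 0.0
        return out

    @property
    def log_sigma_s(self) -> Tensor:
        return self.log_sigma_s_raw * self._sigma_gain

    @property
    def log_sigma_o(self) -> Tensor:
        return self.log_sigma_o_raw * self._sigma_gain

    @property
    def sigma_s(self) -> float:
        return float(np.exp(self.log_sigma_s_raw.data * self._sigma_gain))

    @property
    def sigma_o(self) -> float:
        return float(np.exp(self.log_sigma_o_raw.data * self._sigma_gain))


def save_checkpoint(model: NDCVAE, path: str | Path, meta: dict | None = None) -> None:
    """Persist all parameter arrays plus config metadata in one HDF5 file."""
    import h5py

    cfg = model.config
    with h5py.File(path, "w") as f:
        for name, arr in model.state_arrays().items():
            f.create_dataset(name, data=arr)
        f.attrs["config"] = json.dumps(
            {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
        )
        f.attrs["n_sub"] = model.n_sub
        if meta:
            f.attrs["meta"] = json.dumps(meta)


def load_checkpoint(path: str | Path) -> NDCVAE:
    import h5py

    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["config"])
        cfg_dict["external_input_mode"] = str(cfg_dict["external_input_mode"])
        config = ModelConfig(**cfg_dict)
        model = NDCVAE(config, n_sub=int(f.attrs["n_sub"]))
        arrays = {k: np.array(f[k]) for k in f.keys()}
    model.load_state_arrays(arrays)
    return model
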