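"""Contrastive autoencoder: loss components vs. an independent numpy oracle,
masking of specific slots for controls, and closed-form term checks."""

import numpy as np
import pytest
from scipy.integrate import quad

from ndcvae.data import ModelConfig, assemble_dataset
from ndcvae.model import (
    NDCVAE,
    Batch,
    gaussian_kl,
    load_checkpoint,
    make_batch,
    reparameterized_sample,
    save_checkpoint,
)
from ndcvae.nn import Tensor
from ndcvae.synthetic import generate_cohort

LOG_2PI = np.log(2 * np.pi)


@pytest.fixture(scope="module")
def tiny_setup():
    cohort = generate_cohort(3, 3, 4, 60, seed=5)
    cfg = ModelConfig(n_time=60, n_regions=4, lstm_hidden=8, source_hidden=8,
                      subject_embed_dim=2)
    ds = assemble_dataset(
        cohort.bold, cohort.phenotypes["group"], cohort.connectome, cfg
    )
    model = NDCVAE(cfg, n_sub=ds.n_sub, seed=1)
    return cohort, cfg, ds, model


def frozen_noise(cfg, n_b, n_pat, n_t, seed=0):
    rng = np.random.default_rng(seed)
    keys = {
        "shared.state": (n_b, n_t, cfg.n_states),
        "shared.x0": (n_b, cfg.n_states),
        "shared.region": (n_b, cfg.m_region),
        "shared.subject": (n_b, cfg.m_subject),
        "specific.state": (n_pat, n_t, cfg.n_states),
        "specific.x0": (n_pat, cfg.n_states),
        "specific.region": (n_pat, cfg.m_region),
        "specific.subject": (n_pat, cfg.m_subject),
    }
    return {k: rng.standard_normal(shape) for k, shape in keys.items()}


def oracle_loss(model, batch, noise):
    """Straight-line numpy recomputation of the negative ELBO:
    per-term KLs, state-posterior entropy, transition and decoder Gaussian
    likelihoods, assembled exactly as the loss decomposition states."""
    cfg = model.config
    n_b, n_t = batch.y.shape
    ns, mr, ms = cfg.n_states, cfg.m_region, cfg.m_subject
    pat = np.where(batch.is_patient)[0]

    def post_np(encoder, b):
        p = encoder(b)
        return {k: getattr(p, k).data for k in (
            "state_mean", "state_logvar", "x0_mean", "x0_logvar",
            "region_mean", "region_logvar", "subject_mean", "subject_logvar")}

    p_sh = post_np(model.shared, batch)
    sub = Batch(batch.y[pat], batch.u[pat], batch.u_ext[pat],
                batch.subject_index[pat], batch.is_patient[pat],
                batch.region_index[pat])
    p_sp = post_np(model.specific, sub)

    draw = lambda m, lv, e: m + np.exp(lv / 2) * e
    x_sh = draw(p_sh["state_mean"], p_sh["state_logvar"], noise["shared.state"])
    x0_sh = draw(p_sh["x0_mean"], p_sh["x0_logvar"], noise["shared.x0"])
    thr_sh = draw(p_sh["region_mean"], p_sh["region_logvar"], noise["shared.region"])
    ths_sh = draw(p_sh["subject_mean"], p_sh["subject_logvar"],
                  noise["shared.subject"])
    x_sp = np.zeros((n_b, n_t, ns))
    x0_sp = np.zeros((n_b, ns))
    thr_sp = np.zeros((n_b, mr))
    ths_sp = np.zeros((n_b, ms))
    x_sp[pat] = draw(p_sp["state_mean"], p_sp["state_logvar"],
                     noise["specific.state"])
    x0_sp[pat] = draw(p_sp["x0_mean"], p_sp["x0_logvar"], noise["specific.x0"])
    thr_sp[pat] = draw(p_sp["region_mean"], p_sp["region_logvar"],
                       noise["specific.region"])
    ths_sp[pat] = draw(p_sp["subject_mean"], p_sp["subject_logvar"],
                       noise["specific.subject"])

    w1, b1 = model.source_w1.weight.data, model.source_w1.bias.data
    w2, b2 = model.source_w2.weight.data, model.source_w2.bias.data
    wd, bd = model.decoder.weight.data[:, 0], model.decoder.bias.data[0]
    sig_s2 = np.exp(2 * model.log_sigma_s.data)
    sig_o2 = np.exp(2 * model.log_sigma_o.data)

    x_full = np.concatenate([x_sh, x_sp], axis=2)
    x0_full = np.concatenate([x0_sh, x0_sp], axis=1)
    trans_ll = np.zeros(n_b)
    dec_ll = np.zeros(n_b)
    for i in range(n_b):
        prev = x0_full[i]
        coords = 2 * ns if batch.is_patient[i] else ns
        for k in range(n_t):
            aug = np.concatenate([
                prev[:ns], prev[ns:], thr_sh[i], thr_sp[i], ths_sh[i], ths_sp[i],
                [batch.u_ext[i, k], batch.u[i, k]],
            ])
            f = np.maximum(aug @ w1 + b1, 0) @ w2 + b2
            mean_next = prev + cfg.euler_step * f
            resid = x_full[i, k] - mean_next
            trans_ll[i] += -0.5 * np.sum(
                (LOG_2PI + np.log(sig_s2) + resid[:coords] ** 2 / sig_s2)
            )
            y_hat = x_full[i, k] @ wd + bd
            dec_ll[i] += -0.5 * (
                LOG_2PI + np.log(sig_o2) + (batch.y[i, k] - y_hat) ** 2 / sig_o2
            )
            prev = x_full[i, k]

    kl = lambda m, lv: 0.5 * np.sum(m**2 + np.exp(lv) - lv - 1, axis=-1)
    ent = lambda lv: 0.5 * np.sum(lv + LOG_2PI + 1, axis=-1)
    is_pat = batch.is_patient.astype(float)
    l_src_nc = -np.sum(trans_ll * (1 - is_pat)) / n_b
    l_src_scz = -np.sum(trans_ll * is_pat) / n_b
    l_dec = -np.sum(dec_ll) / n_b
    kl_thr = kl(p_sh["region_mean"], p_sh["region_logvar"]).sum() + kl(
        p_sp["region_mean"], p_sp["region_logvar"]).sum()
    kl_x0 = kl(p_sh["x0_mean"], p_sh["x0_logvar"]).sum() + kl(
        p_sp["x0_mean"], p_sp["x0_logvar"]).sum()
    kl_ths = kl(p_sh["subject_mean"], p_sh["subject_logvar"]).sum() + kl(
        p_sp["subject_mean"], p_sp["subject_logvar"]).sum()
    entropy = ent(p_sh["state_logvar"]).sum() + ent(p_sp["state_logvar"]).sum()
    l_enc = (kl_ths / cfg.n_regions + kl_thr + kl_x0 - entropy) / n_b
    return l_enc + l_dec + l_src_nc + l_src_scz


class TestLossOracle:
    def test_total_loss_matches_straight_line_reimplementation(self, tiny_setup):
        _, cfg, ds, model = tiny_setup
        rng = np.random.default_rng(9)
        idx = rng.choice(len(ds), 8, replace=False)
        batch = make_batch([ds.samples[i] for i in idx])
        n_pat = int(batch.is_patient.sum())
        assert 0 < n_pat < len(batch)  # mixed batch
        noise = frozen_noise(cfg, len(batch), n_pat, batch.y.shape[1], seed=3)
        total, bd = model.total_loss(batch, noise=noise)
        expected = oracle_loss(model, batch, noise)
        assert abs(total.item() - expected) < 1e-10 * max(1, abs(expected))

    def test_total_equals_sum_of_logged_components(self, tiny_setup):
        _, cfg, ds, model = tiny_setup
        batch = make_batch(ds.samples[:6])
        _, bd = model.total_loss(batch, np.random.default_rng(0))
        assert np.isclose(
            bd.total, bd.l_encoder + bd.l_decoder + bd.l_source_nc + bd.l_source_scz
        )
        assert np.isclose(
            bd.l_encoder, bd.l_theta_s + bd.l_theta_r + bd.l_x0 + bd.neg_entropy
        )

    def test_control_only_batch_has_no_specific_terms(self, tiny_setup):
        _, cfg, ds, model = tiny_setup
        controls = [s for s in ds.samples if s.group.value == "control"][:6]
        batch = make_batch(controls)
        model.zero_grad()
        total, bd = model.total_loss(batch, np.random.default_rng(0))
        assert bd.l_source_scz == 0.0
        total.backward()
        for p in model.specific.parameters():
            assert p.grad is None or np.all(p.grad == 0)

    def test_kl_terms_nonnegative(self, tiny_setup):
        _, _, ds, model = tiny_setup
        _, bd = model.total_loss(make_batch(ds.samples[:8]),
                                 np.random.default_rng(1))
        assert bd.l_theta_s >= 0 and bd.l_theta_r >= 0 and bd.l_x0 >= 0


class TestClosedForms:
    def test_kl_standard_normal_is_zero(self):
        assert gaussian_kl(Tensor(np.zeros(3)), Tensor(np.zeros(3))).item() == 0

    def test_kl_unit_mean_is_half(self):
        assert np.isclose(
            gaussian_kl(Tensor([1.0]), Tensor([0.0])).item(), 0.5
        )

    def test_kl_matches_quadrature(self):
        mu, var = 0.5, 0.25
        closed = gaussian_kl(Tensor([mu]), Tensor([np.log(var)])).item()

        def integrand(x):
            q = np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)
            p = np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)
            return q * np.log(q / p) if q > 1e-300 else 0.0

        numeric, _ = quad(integrand, -10, 10)
        assert np.isclose(closed, numeric, atol=1e-8)
        assert np.isclose(closed, 0.4431, atol=5e-4)

    def test_reparameterization_zero_noise_returns_mean(self):
        m = Tensor(np.array([1.0, -2.0]))
        lv = Tensor(np.array([0.3, -0.7]))
        s = reparameterized_sample(m, lv, np.zeros(2))
        assert np.array_equal(s.data, m.data)

    def test_reparameterization_moments(self):
        rng = np.random.default_rng(0)
        m, lv = 1.5, np.log(0.49)
        draws = reparameterized_sample(
            Tensor(np.full(100_000, m)), Tensor(np.full(100_000, lv)),
            rng.standard_normal(100_000),
        ).data
        se_mean = 0.7 / np.sqrt(draws.size)
        assert abs(draws.mean() - m) < 3 * se_mean
        assert abs(draws.var() - 0.49) < 0.49 * 3 * np.sqrt(2 / draws.size)


class TestSourceModel:
    def test_zero_weight_network_returns_bias(self, tiny_setup):
        _, cfg, _, _ = tiny_setup
        model = NDCVAE(cfg, n_sub=2, seed=0)
        model.source_w1.weight.data *= 0
        model.source_w1.bias.data *= 0
        model.source_w2.weight.data *= 0
        model.source_w2.bias.data = np.array([0.1, -0.2, 0.3, 0.0])
        out = model.source_step(Tensor(np.ones((1, cfg.aug_width))))
        assert np.allclose(out.data, [[0.1, -0.2, 0.3, 0.0]])

    def test_single_hidden_unit_hand_forward(self, tiny_setup):
        _, cfg, _, _ = tiny_setup
        model = NDCVAE(cfg, n_sub=2, seed=0)
        model.source_w1.weight.data = np.zeros((cfg.aug_width, cfg.source_hidden))
        model.source_w1.weight.data[0, 0] = 1.0
        model.source_w1.bias.data *= 0
        model.source_w2.weight.data = np.zeros((cfg.source_hidden, 4))
        model.source_w2.weight.data[0, 0] = 1.0
        model.source_w2.bias.data *= 0
        x = np.zeros((1, cfg.aug_width))
        x[0, 0] = 3.0
        assert np.allclose(model.source_step(Tensor(x)).data, [[3, 0, 0, 0]])
        x[0, 0] = -1.0  # ReLU clips the negative pre-activation
        assert np.allclose(model.source_step(Tensor(x)).data, 0)

    def test_dimension_mismatch_rejected(self, tiny_setup):
        _, cfg, _, model = tiny_setup
        with pytest.raises(ValueError):
            model.source_step(Tensor(np.ones((1, cfg.aug_width + 1))))


class TestAugmentation:
    def test_control_slots_zero_and_width(self, tiny_setup):
        _, cfg, ds, model = tiny_setup
        n_b, n_t, ns = 2, 5, cfg.n_states
        sh = Tensor(np.random.default_rng(0).normal(size=(n_b, n_t, ns)))
        aug = model.augment_states(
            sh, None, Tensor(np.ones((n_b, cfg.m_region))), None,
            Tensor(np.ones((n_b, cfg.m_subject))), None,
            np.zeros((n_b, n_t)), np.zeros((n_b, n_t)),
        )
        assert aug.shape[-1] == 14
        assert np.array_equal(aug.data[:, :, ns : 2 * ns], np.zeros((n_b, n_t, ns)))

    def test_patient_states_pass_through(self, tiny_setup):
        _, cfg, _, model = tiny_setup
        rng = np.random.default_rng(1)
        sp = rng.normal(size=(1, 4, cfg.n_states))
        aug = model.augment_states(
            Tensor(np.zeros((1, 4, cfg.n_states))), Tensor(sp),
            Tensor(np.zeros((1, cfg.m_region))), Tensor(np.zeros((1, cfg.m_region))),
            Tensor(np.zeros((1, cfg.m_subject))),
            Tensor(np.zeros((1, cfg.m_subject))),
            np.zeros((1, 4)), np.zeros((1, 4)),
        )
        assert np.array_equal(aug.data[:, :, cfg.n_states : 2 * cfg.n_states], sp)


class TestEncoderDeterminism:
    def test_identical_samples_identical_posteriors(self, tiny_setup):
        _, _, ds, model = tiny_setup
        batch = make_batch([ds.samples[0], ds.samples[0]])
        post = model.shared(batch)
        assert np.array_equal(post.state_mean.data[0], post.state_mean.data[1])
        assert np.array_equal(post.region_mean.data[0], post.region_mean.data[1])

    def test_posterior_trajectory_length_matches_series(self, tiny_setup):
        _, _, ds, model = tiny_setup
        batch = make_batch(ds.samples[:2])
        post = model.shared(batch)
        assert post.state_mean.shape[1] == 60


def test_checkpoint_roundtrip(tmp_path, tiny_setup):
    _, cfg, ds, model = tiny_setup
    path = tmp_path / "ckpt.h5"
    save_checkpoint(model, path, meta={"note": "test"})
    clone = load_checkpoint(path)
    batch = make_batch(ds.samples[:4])
    noise = frozen_noise(cfg, 4, int(batch.is_patient.sum()), 60, seed=0)
    t1, _ = model.total_loss(batch, noise=noise)
    t2, _ = clone.total_loss(batch, noise=noise)
    assert np.isclose(t1.item(), t2.item())
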