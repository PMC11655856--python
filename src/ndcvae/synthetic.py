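"""Synthetic two-group cohorts with planted neurodynamic ground truth.

The generator emulates the data a contrastive neurodynamic state-space model
is fit to: every brain region of every subject carries a 2-state damped
linear-oscillator latent subsystem, and patients additionally carry a second
("specific") subsystem with its own planted parameters.  Damping and
frequency vary along a regional gradient and are scaled per subject, so both
region-level and subject-level heterogeneity are recoverable.  Symptom
scores are linear in the planted specific subject parameters (controls score
zero), and expression maps are spatially autocorrelated Gaussian fields on
the cohort's ring geometry.

Dynamics are integrated by Euler–Maruyama with a step of one sample, which
is exactly the discrete transition model the autoencoder trains, so the
planted system lies inside the model class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_connectome",
    "generate_cohort",
    "generate_symptoms",
    "generate_expression_map",
    "write_cohort",
]

SITES = ("siteA", "siteB", "siteC")


@dataclass
class GeneratorConfig:
    """Planted-dynamics settings.

    Damping/frequency are in units of 1/sample and rad/sample of the
    oscillator velocity field ``dx = A x dt``; with the unit Euler step the
    discrete update is ``x_{k+1} = (I + A) x_k``, stable for the ranges below.
    """

    # shared subsystem: per-region gradients (low → high region index)
    damping_range: tuple[float, float] = (0.08, 0.40)
    freq_range: tuple[float, float] = (0.15, 0.45)
    # specific subsystem (patients only): reversed gradients so the planted
    # specific geography is distinguishable from the shared one
    specific_damping_range: tuple[float, float] = (0.35, 0.15)
    specific_freq_range: tuple[float, float] = (0.30, 0.15)
    subject_scale_sd: float = 0.20  # log-normal subject scaling of (d, w)
    specific_subject_scale_sd: float = 0.25
    coupling_strength: float = 0.10  # network input weight into state 1
    process_noise_sd: float = 0.15
    obs_noise_sd: float = 0.10
    obs_weights: tuple[float, ...] = (1.0, 0.3)  # decoder per subsystem state
    obs_bias: float = 0.0
    euler_step: float = 1.0
    burn_in: int = 50
    symptom_noise_sd: float = 0.5
    # rows: positive / negative / general score; cols: specific subject params
    symptom_weights: tuple[tuple[float, float], ...] = (
        (1.2, 0.0),
        (0.0, 1.0),
        (0.8, 0.6),
    )


@dataclass
class GroundTruth:
    """Planted parameters of the generative process."""

    true_region_params: dict[str, np.ndarray]  # {"shared","specific"}: (n_regions, 2)
    true_subject_params: dict[str, np.ndarray]  # {"shared","specific"}: (n_sub, 2)
    specific_mask: np.ndarray  # (n_sub,) bool — True for patients
    planted_symptom_weights: np.ndarray  # (3, 2)

    def __post_init__(self):
        w = np.asarray(self.planted_symptom_weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("planted symptom weights must be finite")
        spec = np.asarray(self.true_subject_params["specific"], dtype=float)
        if np.any(np.nan_to_num(spec[~self.specific_mask]) != 0):
            raise ValueError("controls must not carry specific subject parameters")


@dataclass
class SyntheticCohort:
    bold: np.ndarray  # (n_sub, n_regions, n_time)
    connectome: np.ndarray  # (n_regions, n_regions)
    phenotypes: pd.DataFrame
    distances: np.ndarray  # (n_regions, n_regions)
    ground_truth: GroundTruth
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self):
        if np.any(np.isnan(self.bold)):
            raise ValueError("bold contains NaN")
        if np.any(np.diag(self.connectome) != 0):
            raise ValueError("connectome diagonal must be zero")
        d = self.distances
        if not (np.allclose(d, d.T) and np.all(np.diag(d) == 0) and np.all(d >= 0)):
            raise ValueError("distances must be symmetric, nonnegative, zero-diagonal")

    @property
    def n_subjects(self) -> int:
        return self.bold.shape[0]

    @property
    def n_regions(self) -> int:
        return self.bold.shape[1]


def generate_connectome(
    n_regions: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Ring-geometry connectome: weights decay with arc distance, lognormal noise.

    Returns ``(weights, distances)``; weights are symmetric, nonnegative, with
    zero diagonal; distances are ring arc lengths (unit spacing).
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_regions)
    diff = np.abs(idx[:, None] - idx[None, :])
    distances = np.minimum(diff, n_regions - diff).astype(float)
    decay_scale = max(n_regions / 10.0, 1.0)
    base = np.exp(-distances / decay_scale)
    noise = rng.lognormal(mean=0.0, sigma=0.4, size=(n_regions, n_regions))
    noise = np.sqrt(noise * noise.T)  # symmetrize multiplicatively
    weights = base * noise
    np.fill_diagonal(weights, 0.0)
    weights = 0.5 * (weights + weights.T)
    return weights, distances


def _oscillator_matrix(damping: float, freq: float) -> np.ndarray:
    """Velocity field of a damped oscillator; eigenvalues −d ± iω."""
    return np.array([[-damping, freq], [-freq, -damping]])


def _check_stable(a: np.ndarray, step: float) -> None:
    eig = np.linalg.eigvals(a)
    if np.any(eig.real >= 0):
        raise ValueError("unstable requested dynamics: eigenvalue with Re >= 0")
    if np.any(np.abs(1.0 + step * eig) >= 1.0):
        raise ValueError("requested dynamics unstable under the Euler step")


def generate_cohort(
    n_controls: int,
    n_patients: int,
    n_regions: int,
    n_time: int,
    seed: int,
    config: GeneratorConfig | None = None,
) -> SyntheticCohort:
    """Simulate a two-group cohort of regional BOLD series with ground truth.

    Per region, a 2-state damped oscillator ``dx = A(θ_r, θ_s) x + c·u_j + η``
    is integrated by Euler–Maruyama (step = 1 sample); patients carry an
    additional specific subsystem.  The observation is
    ``y = w·x + b + ε`` with Gaussian observation noise.
    """
    if min(n_controls, n_patients, n_regions) <= 0:
        raise ValueError("all counts must be positive")
    if n_time < 50:
        raise ValueError("n_time must be >= 50")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n_sub = n_controls + n_patients
    h = cfg.euler_step

    connectome, distances = generate_connectome(
        n_regions, seed=int(rng.integers(2**31 - 1))
    )
    w_row = connectome / np.maximum(connectome.max(axis=1, keepdims=True), 1e-12)

    region_shared = np.column_stack(
        [
            np.linspace(*cfg.damping_range, n_regions),
            np.linspace(*cfg.freq_range, n_regions),
        ]
    )
    region_specific = np.column_stack(
        [
            np.linspace(*cfg.specific_damping_range, n_regions),
            np.linspace(*cfg.specific_freq_range, n_regions),
        ]
    )

    # subject scalings are truncated at ±1.8 sd so every planted system stays
    # stable under the unit Euler step; the truncated values are the truth
    subj_shared = np.clip(rng.normal(size=(n_sub, 2)), -1.8, 1.8)
    specific_mask = np.zeros(n_sub, dtype=bool)
    specific_mask[n_controls:] = True
    subj_specific = np.zeros((n_sub, 2))
    subj_specific[specific_mask] = np.clip(
        rng.normal(size=(n_patients, 2)), -1.8, 1.8
    )

    n_total = cfg.burn_in + n_time
    bold = np.empty((n_sub, n_regions, n_time))
    w_obs = np.asarray(cfg.obs_weights)

    for s in range(n_sub):
        scale_sh = np.exp(cfg.subject_scale_sd * subj_shared[s])
        a_shared = np.empty((n_regions, 2, 2))
        for r in range(n_regions):
            a = _oscillator_matrix(
                region_shared[r, 0] * scale_sh[0], region_shared[r, 1] * scale_sh[1]
            )
            _check_stable(a, h)
            a_shared[r] = a
        has_spec = bool(specific_mask[s])
        if has_spec:
            scale_sp = np.exp(cfg.specific_subject_scale_sd * subj_specific[s])
            a_spec = np.empty((n_regions, 2, 2))
            for r in range(n_regions):
                a = _oscillator_matrix(
                    region_specific[r, 0] * scale_sp[0],
                    region_specific[r, 1] * scale_sp[1],
                )
                _check_stable(a, h)
                a_spec[r] = a

        x_sh = np.zeros((n_regions, 2))
        x_sp = np.zeros((n_regions, 2))
        y_prev = np.zeros(n_regions)
        series = np.empty((n_regions, n_total))
        for t in range(n_total):
            u = w_row @ y_prev  # network input from other regions' observations
            drift = np.einsum("rij,rj->ri", a_shared, x_sh)
            drift[:, 0] += cfg.coupling_strength * u
            x_sh = x_sh + h * drift + np.sqrt(h) * cfg.process_noise_sd * rng.normal(
                size=(n_regions, 2)
            )
            obs = x_sh @ w_obs
            if has_spec:
                drift_sp = np.einsum("rij,rj->ri", a_spec, x_sp)
                x_sp = x_sp + h * drift_sp + np.sqrt(
                    h
                ) * cfg.process_noise_sd * rng.normal(size=(n_regions, 2))
                obs = obs + x_sp @ w_obs
            y = obs + cfg.obs_bias + cfg.obs_noise_sd * rng.normal(size=n_regions)
            series[:, t] = y
            y_prev = y
        bold[s] = series[:, cfg.burn_in :]

    ground_truth = GroundTruth(
        true_region_params={"shared": region_shared, "specific": region_specific},
        true_subject_params={"shared": subj_shared, "specific": subj_specific},
        specific_mask=specific_mask,
        planted_symptom_weights=np.asarray(cfg.symptom_weights, dtype=float),
    )
    phenotypes = generate_symptoms(
        ground_truth,
        noise_sd=cfg.symptom_noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    return SyntheticCohort(
        bold=bold,
        connectome=connectome,
        phenotypes=phenotypes,
        distances=distances,
        ground_truth=ground_truth,
        config=cfg,
    )


def generate_symptoms(
    ground_truth: GroundTruth, noise_sd: float, seed: int
) -> pd.DataFrame:
    """Phenotype table: symptoms linear in planted specific subject parameters.

    Patients receive three symptom scores (positive, negative, general) equal
    to the planted weight matrix applied to their specific subject parameters
    plus Gaussian noise; controls score exactly zero on all three, as healthy
    individuals do on clinical symptom scales.  Covariates (site, age, sex,
    education) are drawn independently of symptoms.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    mask = ground_truth.specific_mask
    n_sub = mask.size
    weights = ground_truth.planted_symptom_weights
    scores = np.zeros((n_sub, 3))
    params = ground_truth.true_subject_params["specific"]
    scores[mask] = params[mask] @ weights.T
    if noise_sd > 0:
        scores[mask] += noise_sd * rng.normal(size=(int(mask.sum()), 3))
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n_sub)],
            "group": np.where(mask, "patient", "control"),
            "score_pos": scores[:, 0],
            "score_neg": scores[:, 1],
            "score_gen": scores[:, 2],
            "site": rng.choice(SITES, size=n_sub),
            "age": rng.uniform(18, 60, size=n_sub).round(1),
            "sex": rng.choice(["M", "F"], size=n_sub),
            "edu": rng.integers(6, 20, size=n_sub),
        }
    )


def generate_expression_map(
    n_regions: int,
    n_genes: int,
    distances: np.ndarray,
    target_map: np.ndarray | None = None,
    n_correlated: int = 0,
    seed: int = 0,
    smoothing_radius: float = 3.0,
    mix_coefficient: float = 0.7,
) -> np.ndarray:
    """Region × gene expression matrix of spatially smoothed Gaussian fields.

    Each gene map is white noise smoothed with a Gaussian kernel of the given
    radius on the distance graph; the first ``n_correlated`` genes mix in
    ``target_map`` with weight ``mix_coefficient``.  Columns are standardized
    to mean 0, sd 1.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.shape != (n_regions, n_regions) or not np.allclose(
        distances, distances.T
    ):
        raise ValueError("distances must be a symmetric n_regions x n_regions matrix")
    if n_correlated > n_genes:
        raise ValueError("n_correlated must be <= n_genes")
    if n_correlated > 0 and target_map is None:
        raise ValueError("target_map required when n_correlated > 0")
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_regions, n_genes))
    if smoothing_radius > 0:
        kernel = np.exp(-(distances**2) / (2.0 * smoothing_radius**2))
        kernel /= kernel.sum(axis=1, keepdims=True)
        expr = kernel @ raw
    else:
        expr = raw
    if n_correlated > 0:
        tgt = np.asarray(target_map, dtype=float)
        if tgt.shape != (n_regions,):
            raise ValueError("target_map must have length n_regions")
        tgt_z = (tgt - tgt.mean()) / tgt.std()
        expr_z = (expr[:, :n_correlated] - expr[:, :n_correlated].mean(axis=0)) / (
            expr[:, :n_correlated].std(axis=0) + 1e-12
        )
        expr[:, :n_correlated] = (
            mix_coefficient * tgt_z[:, None]
            + np.sqrt(1.0 - mix_coefficient**2) * expr_z
        )
    expr = expr - expr.mean(axis=0)
    sd = expr.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("degenerate (constant) gene column")
    return expr / sd


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict:
    """Write a cohort to disk (TSV/CSV/JSON) and return a manifest dict.

    Layout: one TSV per subject (regions × time), connectome and distance
    TSVs, a phenotype CSV, and a JSON sidecar with the ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bold_paths = []
    for s in range(cohort.n_subjects):
        p = out / f"sub-{s:04d}_bold.tsv"
        np.savetxt(p, cohort.bold[s], delimiter="\t")
        bold_paths.append(p.name)
    np.savetxt(out / "connectome.tsv", cohort.connectome, delimiter="\t")
    np.savetxt(out / "distances.tsv", cohort.distances, delimiter="\t")
    cohort.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    gt = cohort.ground_truth
    sidecar = {
        "true_region_params": {k: v.tolist() for k, v in gt.true_region_params.items()},
        "true_subject_params": {
            k: v.tolist() for k, v in gt.true_subject_params.items()
        },
        "specific_mask": gt.specific_mask.tolist(),
        "planted_symptom_weights": gt.planted_symptom_weights.tolist(),
        "generator_config": asdict(cohort.config),
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    manifest = {
        "bold": bold_paths,
        "connectome": "connectome.tsv",
        "distances": "distances.tsv",
        "phenotypes": "phenotypes.csv",
        "ground_truth": "ground_truth.json",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
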