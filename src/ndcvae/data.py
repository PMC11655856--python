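"""Core data types, file I/O, and per-region training-sample assembly.

A cohort of regional BOLD matrices is flattened into one sample per
(subject, region) pair.  Each sample carries the region's own (z-scored)
BOLD series, the structural-connectivity-weighted network input from the
other regions' observed BOLD, and an optional global-mean external input —
making regional samples conditionally independent and trainable in shuffled
batches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "ModelConfig",
    "Connectome",
    "RegionalSample",
    "CohortDataset",
    "normalize_connectome",
    "compute_network_input",
    "compute_external_input",
    "assemble_dataset",
    "load_cohort",
]


class Group(str, Enum):
    CONTROL = "control"
    PATIENT = "patient"


class LoadError(ValueError):
    """Raised on malformed cohort inputs, with file/row context."""


@dataclass
class ModelConfig:
    """Dimensions and conventions of the neurodynamic autoencoder.

    Defaults are the reference configuration: 225-sample series, 100 regions,
    2 states per encoder, 2 region-level and 2 subject-level parameters per
    encoder, unit Euler step.
    """

    n_time: int = 225
    n_regions: int = 100
    n_states: int = 2
    m_region: int = 2
    m_subject: int = 2
    euler_step: float = 1.0
    external_input_mode: str = "zero"  # or "global_mean"
    sc_normalization: str = "max"  # "row", "max", or "none"
    lstm_hidden: int = 32
    source_hidden: int = 32
    subject_embed_dim: int = 4

    def __post_init__(self):
        counts = (self.n_time, self.n_regions, self.n_states, self.m_region,
                  self.m_subject, self.lstm_hidden, self.source_hidden)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.euler_step <= 0:
            raise ValueError("euler_step must be positive")
        if self.external_input_mode not in ("zero", "global_mean"):
            raise ValueError(f"unknown external_input_mode {self.external_input_mode}")
        if self.sc_normalization not in ("row", "max", "none"):
            raise ValueError(f"unknown sc_normalization {self.sc_normalization}")

    @property
    def aug_width(self) -> int:
        """Width of the augmented source-model input: states of both
        encoders, both parameter blocks, plus (u_ext, u_j)."""
        return 2 * self.n_states + 2 * self.m_region + 2 * self.m_subject + 2


@dataclass
class Connectome:
    weights: np.ndarray
    normalization: str = "none"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome must be square")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectome must be finite")
        if np.any(w < 0):
            raise ValueError("connectome weights must be nonnegative")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        self.weights = w


def normalize_connectome(weights: np.ndarray, mode: str = "max") -> Connectome:
    """Normalize raw structural weights: per-row sum ('row'), global max
    ('max'), or leave untouched ('none')."""
    c = Connectome(weights)
    w = c.weights
    if mode == "row":
        sums = w.sum(axis=1, keepdims=True)
        w = np.divide(w, sums, out=np.zeros_like(w), where=sums > 0)
    elif mode == "max":
        m = w.max()
        if m > 0:
            w = w / m
    elif mode != "none":
        raise ValueError(f"unknown normalization mode {mode}")
    return Connectome(w, normalization=mode)


@dataclass
class RegionalSample:
    """One brain region of one subject as a training sample."""

    bold: np.ndarray  # y, length n_time
    network_input: np.ndarray  # u, length n_time
    external_input: np.ndarray  # u_ext, length n_time
    subject_index: int
    region_index: int
    group: Group


@dataclass
class CohortDataset:
    samples: list[RegionalSample]
    n_sub: int
    n_regions: int
    phenotypes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if len(self.samples) != self.n_sub * self.n_regions:
            raise ValueError("|samples| must equal n_sub * n_regions")

    def __len__(self) -> int:
        return len(self.samples)


def compute_network_input(
    bold: np.ndarray, connectome: Connectome, region_index: int
) -> np.ndarray:
    """SC-weighted input to one region from the other regions' observed BOLD:
    ``u_j(t) = Σ_{i≠j} w_ji y_i(t)``."""
    bold = np.asarray(bold, dtype=float)
    n_regions = bold.shape[0]
    if connectome.weights.shape[0] != n_regions:
        raise ValueError("connectome dimension does not match BOLD regions")
    if not 0 <= region_index < n_regions:
        raise ValueError(f"region_index {region_index} out of range")
    row = connectome.weights[region_index]
    return row @ bold


def compute_external_input(bold: np.ndarray, mode: str = "zero") -> np.ndarray:
    """Subject-wide external input: zero series, or the across-region mean."""
    bold = np.asarray(bold, dtype=float)
    if mode == "zero":
        return np.zeros(bold.shape[1])
    if mode == "global_mean":
        return bold.mean(axis=0)
    raise ValueError(f"unknown external input mode {mode}")


def _zscore_rows(bold: np.ndarray) -> np.ndarray:
    mu = bold.mean(axis=1, keepdims=True)
    sd = bold.std(axis=1, ddof=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (bold - mu) / sd


def assemble_dataset(
    bold: np.ndarray,
    groups: list[Group] | np.ndarray,
    connectome_weights: np.ndarray,
    config: ModelConfig,
    phenotypes: pd.DataFrame | None = None,
) -> CohortDataset:
    """Assemble per-region samples from a (subjects × regions × time) array.

    BOLD is z-scored per region before the network input is computed, so the
    standard-normal state priors and the linear decoder operate on a common
    scale.  Ordering is subject-major, region-minor.
    """
    bold = np.asarray(bold, dtype=float)
    n_sub, n_regions, n_time = bold.shape
    for s in range(n_sub):
        for r in range(n_regions):
            if np.any(np.isnan(bold[s, r])):
                raise LoadError(f"NaN in BOLD of subject {s}, region {r}")
    groups = [Group(g) for g in groups]
    if len(groups) != n_sub:
        raise LoadError("one group label required per subject")
    conn = normalize_connectome(connectome_weights, config.sc_normalization)
    if conn.weights.shape[0] != n_regions:
        raise LoadError("connectome dimension does not match BOLD regions")

    samples: list[RegionalSample] = []
    for s in range(n_sub):
        z = _zscore_rows(bold[s])
        u_ext = compute_external_input(z, config.external_input_mode)
        for r in range(n_regions):
            samples.append(
                RegionalSample(
                    bold=z[r],
                    network_input=compute_network_input(z, conn, r),
                    external_input=u_ext,
                    subject_index=s,
                    region_index=r,
                    group=groups[s],
                )
            )
    return CohortDataset(
        samples=samples,
        n_sub=n_sub,
        n_regions=n_regions,
        phenotypes=phenotypes if phenotypes is not None else pd.DataFrame(),
    )


def load_cohort(manifest_path: str | Path, config: ModelConfig) -> CohortDataset:
    """Load a cohort from a JSON manifest (as written by the generator).

    The manifest names per-subject BOLD TSVs (regions × time), a connectome
    TSV, and a phenotype CSV with a ``group`` column.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    phenotypes = pd.read_csv(root / manifest["phenotypes"])
    if "group" not in phenotypes.columns:
        raise LoadError(f"{manifest['phenotypes']}: missing 'group' column")
    unknown = set(phenotypes["group"]) - {g.value for g in Group}
    if unknown:
        raise LoadError(f"unknown group label(s): {sorted(unknown)}")
    mats = []
    for name in manifest["bold"]:
        p = root / name
        if not p.exists():
            raise LoadError(f"missing BOLD file {name}")
        m = np.loadtxt(p, delimiter="\t", ndmin=2)
        mats.append(m)
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise LoadError(f"BOLD matrices do not share dimensions: {sorted(shapes)}")
    bold = np.stack(mats)
    if len(phenotypes) != bold.shape[0]:
        raise LoadError("phenotype rows do not match number of BOLD files")
    connectome = np.loadtxt(root / manifest["connectome"], delimiter="\t")
    return assemble_dataset(
        bold, list(phenotypes["group"]), connectome, config, phenotypes
    )
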