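"""Optimization loop, five-fold cross-validation, fold-stability selection.

Regional samples (not subjects) are split 80/20 per fold; Adam minimizes the
negative ELBO on shuffled mixed-group batches while both split losses are
logged periodically.  Across folds, the encoded parameters are correlated
pairwise and the fold most consistent with the others is selected as the
reference model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortDataset, ModelConfig
from .model import NDCVAE, make_batch
from .nn import Adam

__all__ = [
    "TrainConfig",
    "FoldResult",
    "make_folds",
    "train_fold",
    "train_cv",
    "fold_stability_select",
]


@dataclass
class TrainConfig:
    """Reference settings: Adam at 0.003, batches of 64, 30000 batches,
    five folds."""

    learning_rate: float = 0.003
    batch_size: int = 64
    n_batches: int = 30000
    n_folds: int = 5
    seed: int = 0
    log_every: int = 100
    eval_subset: int = 256  # samples drawn from each split per evaluation
    ema_decay: float = 0.995  # Polyak averaging of weights; 0 disables

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.n_folds) <= 0:
            raise ValueError("learning_rate, batch_size, n_folds must be positive")
        if self.n_batches < 0:
            raise ValueError("n_batches must be nonnegative")


@dataclass
class FoldResult:
    model: NDCVAE
    history: pd.DataFrame  # batch, train_loss, test_loss (+ components)
    encoded: dict = field(default_factory=dict)  # encode_dataset() output
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    diverged: bool = False


def make_folds(
    n_samples: int, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random partition of sample indices into ``n_folds`` (train, test)
    pairs; each test part is one fold of the shuffled indices."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    parts = np.array_split(perm, n_folds)
    folds = []
    for i in range(n_folds):
        test = np.sort(parts[i])
        train = np.sort(np.concatenate([parts[j] for j in range(n_folds) if j != i]))
        folds.append((train, test))
    return folds


def _eval_loss(
    model: NDCVAE,
    dataset: CohortDataset,
    idx: np.ndarray,
    rng: np.random.Generator,
    n_eval: int,
) -> float:
    take = idx if len(idx) <= n_eval else rng.choice(idx, n_eval, replace=False)
    batch = make_batch([dataset.samples[i] for i in take])
    total, _ = model.total_loss(batch, rng)
    return total.item()


def train_fold(
    dataset: CohortDataset,
    fold_assignment: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    encode_after: bool = True,
) -> FoldResult:
    """Train one fold; deterministic under ``config.seed``.

    On a non-finite loss the last logged checkpoint is restored and training
    aborts with ``diverged=True``.
    """
    train_idx, test_idx = fold_assignment
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("fold assignment must be a nonempty 80/20-style split")
    mc = model_config or ModelConfig(
        n_time=dataset.samples[0].bold.shape[0], n_regions=dataset.n_regions
    )
    model = NDCVAE(mc, n_sub=dataset.n_sub, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    last_good = {k: v.copy() for k, v in model.state_arrays().items()}
    diverged = False
    params = model.parameters()
    # Polyak-averaged weights smooth out batch-to-batch fluctuation in the
    # encoded parameters; the averaged model is the one returned
    ema = [p.data.copy() for p in params] if config.ema_decay > 0 else None
    for b in range(config.n_batches):
        idx = rng.choice(train_idx, size=min(config.batch_size, len(train_idx)),
                         replace=False)
        batch = make_batch([dataset.samples[i] for i in idx])
        opt.zero_grad()
        try:
            total, bd = model.total_loss(batch, rng)
        except FloatingPointError:
            model.load_state_arrays(last_good)
            diverged = True
            break
        total.backward()
        opt.step()
        if ema is not None:
            d = config.ema_decay
            for e, p in zip(ema, params):
                e *= d
                e += (1.0 - d) * p.data
        if b % config.log_every == 0 or b == config.n_batches - 1:
            test_loss = _eval_loss(model, dataset, test_idx, rng, config.eval_subset)
            rows.append(
                {"batch": b, "train_loss": bd.total, "test_loss": test_loss,
                 **{k: v for k, v in bd.as_dict().items() if k != "total"}}
            )
            last_good = {k: v.copy() for k, v in model.state_arrays().items()}
    if not rows:  # n_batches == 0: model equals initialization
        rows.append({"batch": -1, "train_loss": np.nan, "test_loss": np.nan})
    if ema is not None and not diverged and config.n_batches > 0:
        for e, p in zip(ema, params):
            p.data = e.copy()
    history = pd.DataFrame(rows)
    encoded = model.encode_dataset(dataset) if encode_after else {}
    return FoldResult(
        model=model,
        history=history,
        encoded=encoded,
        train_idx=np.asarray(train_idx),
        test_idx=np.asarray(test_idx),
        diverged=diverged,
    )


def train_cv(
    dataset: CohortDataset,
    config: TrainConfig,
    model_config: ModelConfig | None = None,
) -> list[FoldResult]:
    """Five-fold (or ``config.n_folds``) cross-validated training."""
    folds = make_folds(len(dataset), config.n_folds, config.seed)
    results = []
    for i, fold in enumerate(folds):
        cfg_i = TrainConfig(
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            n_batches=config.n_batches,
            n_folds=config.n_folds,
            seed=config.seed + 1000 * i,
            log_every=config.log_every,
            eval_subset=config.eval_subset,
        )
        results.append(train_fold(dataset, fold, cfg_i, model_config))
    return results


def _fold_param_vector(encoded: dict) -> np.ndarray:
    """All encoded parameters of one fold as a single vector: per-subject
    θ^s of both encoders, and subject-averaged per-region θ^r of both."""
    return np.concatenate(
        [
            encoded["shared.subject"].ravel(),
            encoded["specific.subject"].ravel(),
            encoded["shared.region"].mean(axis=0).ravel(),
            encoded["specific.region"].mean(axis=0).ravel(),
        ]
    )


def fold_stability_select(
    fold_results: list[FoldResult] | list[dict],
) -> tuple[int, np.ndarray]:
    """Pick the fold whose encoded parameters correlate best with the others.

    Returns ``(selected_index, correlation_matrix)``.  Ties break to the
    lowest fold index.
    """
    if len(fold_results) < 2:
        raise ValueError("need at least 2 folds")
    encs = [
        fr.encoded if isinstance(fr, FoldResult) else fr for fr in fold_results
    ]
    vecs = np.stack([_fold_param_vector(e) for e in encs])
    corr = np.corrcoef(vecs)
    n = corr.shape[0]
    mean_off = (corr.sum(axis=1) - 1.0) / (n - 1)
    best = int(np.argmax(mean_off))  # argmax returns the first (lowest) index on ties
    return best, corr
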