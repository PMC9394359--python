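"""Holdout splitting, k-fold cross-validation and the MSECV response.

A campaign fixes one :class:`SplitPlan` — a seeded random holdout into
training and testing indices, with the training indices further cut into k
near-equal folds — and every hyperparameter configuration is scored against
that same plan. The score is MSECV: for each fold, train on the remaining
folds and measure MSE on the held-out fold, then average over folds.

Normalization is refit on the learning folds of each rotation by default
(strict no-leakage). ``leaky_normalization=True`` instead fits min/max on the
whole dataset once, the common shortcut when data are normalized before
splitting; the difference is negligible for well-mixed data but the strict
mode is the defensible default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neural_net import (
    NormalizationParams,
    TrainConfig,
    TrainingDivergedError,
    TrainingStalledError,
    fit_normalization,
    init_network,
    forward,
    mse,
    normalize,
    train,
)

__all__ = ["SplitPlan", "CVResult", "make_split", "evaluate_config"]


@dataclass(frozen=True)
class SplitPlan:
    """Materialized train/test and fold indices for one campaign."""

    n_samples: int
    train_fraction: float
    k_folds: int
    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    folds: tuple[np.ndarray, ...]


@dataclass(frozen=True)
class CVResult:
    """Per-fold validation MSEs and their mean for one configuration."""

    fold_mse: tuple[float, ...]
    config: TrainConfig

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.fold_mse))


def make_split(n_samples: int, train_fraction: float = 0.6, k: int = 3, seed: int = 0) -> SplitPlan:
    """Seeded random holdout followed by k near-equal folds of the training set.

    Fold sizes differ by at most one; folds partition the training indices and
    are disjoint from the test indices. Deterministic per seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if k < 2:
        raise ValueError("need at least 2 folds")
    n_train = int(round(n_samples * train_fraction))
    if k > n_train:
        raise ValueError(f"k={k} exceeds training-set size {n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    # contiguous blocks of a seeded shuffle of the training indices
    shuffled = rng.permutation(train_idx)
    folds = tuple(np.sort(f) for f in np.array_split(shuffled, k))
    return SplitPlan(
        n_samples=n_samples,
        train_fraction=train_fraction,
        k_folds=k,
        seed=seed,
        train_indices=train_idx,
        test_indices=test_idx,
        folds=folds,
    )


def evaluate_config(
    config: TrainConfig,
    X: np.ndarray,
    y: np.ndarray,
    plan: SplitPlan,
    leaky_normalization: bool = False,
    epoch_scale: float = 1.0,
) -> CVResult:
    """Cross-validated MSE of one training configuration under a split plan.

    For each fold rotation the network is trained on the other folds and
    scored on the held fold; the per-fold training seed is derived from
    (config.seed, fold index) so reruns are bit-identical. A diverged or
    stalled training run contributes an infinite fold MSE instead of aborting
    the campaign. ``epoch_scale`` rescales the configured epoch budget
    (minimum 1) so a whole campaign can be run at reduced cost.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) != len(y) or len(X) != plan.n_samples:
        raise ValueError("data size does not match the split plan")

    if leaky_normalization:
        global_xn = fit_normalization(X)
        global_yn = fit_normalization(y)

    fold_mses: list[float] = []
    for i, fold in enumerate(plan.folds):
        learn_idx = np.concatenate([f for j, f in enumerate(plan.folds) if j != i])
        if leaky_normalization:
            xn, yn = global_xn, global_yn
        else:
            xn = fit_normalization(X[learn_idx])
            yn = fit_normalization(y[learn_idx])
        Xl = normalize(X[learn_idx], xn)
        yl = normalize(y[learn_idx], yn)
        Xv = normalize(X[fold], xn)
        yv = normalize(y[fold], yn)
        epochs = max(1, int(round(config.epochs * epoch_scale))) if config.epochs else 0
        fold_config = TrainConfig(
            n_hidden=config.n_hidden,
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            epochs=epochs,
            algorithm=config.algorithm,
            seed=(config.seed * 1000003 + i) % (2 ** 31),
            goal_mse=config.goal_mse,
            matlab_momentum=config.matlab_momentum,
        )
        net = init_network(X.shape[1], fold_config)
        try:
            trained, _ = train(net, Xl, yl, fold_config)
            fold_mses.append(mse(yv, forward(trained, Xv)))
        except (TrainingDivergedError, TrainingStalledError):
            fold_mses.append(float("inf"))
    return CVResult(fold_mse=tuple(fold_mses), config=config)
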