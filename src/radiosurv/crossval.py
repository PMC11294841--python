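"""Nested cross-validation with a seeded hyperparameter-tuning contract.

The outer loop is stratified by event status and used exclusively for
validation; the inner loop carves a validation split out of each outer
training fold, scores a small number of candidate configurations by
inner-validation concordance, and never touches the outer-validation
samples. Metrics per outer fold: Harrell's C, IPCW C and the mean
cumulative/dynamic AUC; outer-fold prognostic indices are pooled for
median risk stratification, Kaplan-Meier curves and the log-rank test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datatypes import RadiogenomicsDataset, SurvivalLabels
from .metrics import (
    concordance_index,
    cumulative_dynamic_auc,
    ipcw_concordance,
    log_rank_test,
    stratify_by_median,
)


@dataclass
class NestedCVSpec:
    """Protocol constants of the evaluation loop."""

    outer_folds: int = 5
    inner_folds: int = 3          # inner val fraction = 1 / inner_folds
    trials: int = 3
    executions_per_trial: int = 2
    tuning_epochs: int | None = 20     # None: quarter of the family default
    final_epochs: int | None = 100     # None: the family's default recipe
    seed: int = 0

    def __post_init__(self):
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")


class HyperparameterSpace:
    """Finite choice sets per hyperparameter name."""

    def __init__(self, **choices):
        if any(len(v) == 0 for v in choices.values()):
            raise ValueError("every hyperparameter needs a non-empty range")
        self.choices = {k: list(v) for k, v in choices.items()}

    @property
    def n_points(self) -> int:
        return int(np.prod([len(v) for v in self.choices.values()])) \
            if self.choices else 1

    def all_points(self):
        keys = list(self.choices)
        for combo in itertools.product(*(self.choices[k] for k in keys)):
            yield dict(zip(keys, combo))

    def sample(self, n: int, rng) -> list[dict]:
        """Up to ``n`` distinct configurations, seeded."""
        points = list(self.all_points())
        if len(points) <= n:
            return points
        idx = rng.choice(len(points), size=n, replace=False)
        return [points[i] for i in idx]


def stratified_outer_folds(labels: SurvivalLabels, k: int,
                           seed: int = 0) -> np.ndarray:
    """Event-stratified fold assignment (0..k-1 per sample)."""
    n = len(labels)
    if k > n:
        raise ValueError("more folds than samples")
    counts = np.bincount(labels.event, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"a survival-status class has fewer members ({counts.min()}) "
            f"than folds ({k})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(n), labels.event)):
        assignment[val_idx] = fold
    return assignment


def _inner_split(dataset: RadiogenomicsDataset, val_fraction: float,
                 seed: int):
    """Single stratified train/validation split of an outer-train fold."""
    n = dataset.n_samples
    k = max(2, int(round(1.0 / val_fraction)))
    assignment = stratified_outer_folds(dataset.labels, k, seed)
    val = assignment == 0
    return dataset.subset(np.nonzero(~val)[0]), dataset.subset(np.nonzero(val)[0])


def tune_hyperparameters(train_dataset: RadiogenomicsDataset,
                         space: HyperparameterSpace,
                         cv_spec: NestedCVSpec,
                         family) -> dict:
    """Sequential search over sampled configurations.

    Each candidate is trained ``tuning_epochs`` on the inner-train split
    (``executions_per_trial`` times, averaging inner-validation
    concordance); the arg-max configuration is returned. A single-point
    space is returned immediately without any training.
    """
    if space.n_points == 1:
        return next(space.all_points())
    rng = np.random.default_rng([cv_spec.seed, 101])
    candidates = space.sample(cv_spec.trials, rng)
    inner_train, inner_val = _inner_split(
        train_dataset, 1.0 / cv_spec.inner_folds, cv_spec.seed)
    tuning_epochs = cv_spec.tuning_epochs
    if tuning_epochs is None:
        tuning_epochs = max(20, getattr(family, "default_epochs", 80) // 4)
    best_cfg, best_score = None, -np.inf
    failures = []
    for t, cfg in enumerate(candidates):
        scores = []
        for e in range(cv_spec.executions_per_trial):
            try:
                model = family.fit(inner_train, cfg,
                                   epochs=tuning_epochs,
                                   seed=int(rng.integers(2 ** 31)))
                pi = family.predict(model, inner_val)
                scores.append(concordance_index(pi, inner_val.labels))
            except Exception as exc:   # degenerate configs score -inf
                failures.append((cfg, repr(exc)))
        if scores and np.mean(scores) > best_score:
            best_cfg, best_score = cfg, float(np.mean(scores))
    if best_cfg is None:
        raise RuntimeError(f"all tuning trials failed: {failures}")
    return best_cfg


@dataclass
class MetricsReport:
    """Per-fold and aggregate survival metrics of a nested-CV run."""

    fold_cindex: list
    fold_ipcw: list
    fold_auc: list
    pooled_pi: np.ndarray
    risk_groups: np.ndarray
    logrank_chi2: float
    logrank_p: float
    fold_assignment: np.ndarray
    best_configs: list = field(default_factory=list)
    fold_models: list = field(default_factory=list)

    @property
    def mean_cindex(self) -> float:
        return float(np.mean(self.fold_cindex))

    @property
    def sd_cindex(self) -> float:
        return float(np.std(self.fold_cindex))

    @property
    def mean_ipcw(self) -> float:
        vals = [v for v in self.fold_ipcw if v is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_auc(self) -> float:
        vals = [v for v in self.fold_auc if v is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def summary(self) -> dict:
        return {
            "mean_cindex": self.mean_cindex,
            "sd_cindex": self.sd_cindex,
            "mean_ipcw_cindex": self.mean_ipcw,
            "mean_cumulative_auc": self.mean_auc,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
        }


def nested_cv_run(dataset: RadiogenomicsDataset, family,
                  cv_spec: NestedCVSpec | None = None,
                  space: HyperparameterSpace | None = None,
                  eval_times=None, keep_models: bool = False) -> MetricsReport:
    """Run the full nested-CV protocol for one model family.

    For each outer fold: tune on the outer-train fold (inner split),
    retrain with ``final_epochs`` using the selected configuration, and
    predict the prognostic index on the outer-validation fold. The
    pooled outer-validation indices drive median stratification and the
    log-rank test, so every sample is scored exactly once by a model
    that never saw it.
    """
    cv_spec = cv_spec or NestedCVSpec()
    space = space or HyperparameterSpace()
    labels = dataset.labels
    assignment = stratified_outer_folds(labels, cv_spec.outer_folds,
                                        cv_spec.seed)
    if eval_times is None:
        event_times = labels.time[labels.event == 1]
        eval_times = np.quantile(event_times, [0.25, 0.5, 0.75])
    pooled_pi = np.empty(dataset.n_samples)
    fold_c, fold_ipcw, fold_auc, best_cfgs, fold_models = [], [], [], [], []
    for fold in range(cv_spec.outer_folds):
        val_mask = assignment == fold
        train_ds = dataset.subset(np.nonzero(~val_mask)[0])
        val_ds = dataset.subset(np.nonzero(val_mask)[0])
        best = tune_hyperparameters(train_ds, space, cv_spec, family)
        best_cfgs.append(best)
        model = family.fit(train_ds, best, epochs=cv_spec.final_epochs,
                           seed=cv_spec.seed + 1000 + fold)
        if keep_models:
            fold_models.append(model)
        pi = family.predict(model, val_ds)
        pooled_pi[val_mask] = pi
        fold_c.append(concordance_index(pi, val_ds.labels))
        try:
            fold_ipcw.append(ipcw_concordance(pi, val_ds.labels))
        except ValueError:
            fold_ipcw.append(None)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, mean_auc = cumulative_dynamic_auc(pi, val_ds.labels,
                                                        eval_times)
            fold_auc.append(mean_auc)
        except ValueError:
            fold_auc.append(None)
    groups = stratify_by_median(pooled_pi)
    if groups.sum() in (0, len(groups)):
        chi2, p = 0.0, 1.0
    else:
        chi2, p = log_rank_test(groups, labels)
    return MetricsReport(fold_c, fold_ipcw, fold_auc, pooled_pi, groups,
                         chi2, p, assignment, best_cfgs, fold_models)
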