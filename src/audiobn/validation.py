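"""Cross-validated one-vs-rest ROC/AUC for the loss-group classifier.

The fitted network scores each held-out worker with the posterior
probability of each loss group given that worker's predictors; per group,
those scores against the one-vs-rest labels give a ROC curve whose area is
computed by the Mann-Whitney rank statistic with midrank tie correction:

    AUC = (R+ − n+(n+ + 1)/2) / (n+ · n−)

where R+ is the midrank sum of the positives.  Folds are plain disjoint
random N/k blocks (no stratification), so a sparse group can be absent from
a fold's test set; such (fold, group) AUCs are reported as undefined rather
than silently dropped or set to 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bayesnet import DAG, DiscreteBayesNet, fit_parameters
from .cohort import Cohort, VariableSpec, canonical_schema

TARGET = "loss_group"


class UndefinedAUCError(ValueError):
    """Both classes are required for a ROC curve."""


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: np.ndarray  # fold id per record index
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


@dataclass
class AUCReport:
    groups: tuple[str, ...]
    per_group_per_fold: dict[str, list[Optional[float]]]
    per_group_pooled: dict[str, Optional[float]]
    k: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = {g: self.per_group_per_fold[g] + [self.per_group_pooled[g]] for g in self.groups}
        idx = [f"fold {i}" for i in range(self.k)] + ["pooled"]
        return pd.DataFrame(rows, index=idx)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "k": self.k,
                "seed": self.seed,
                "groups": list(self.groups),
                "per_group_per_fold": self.per_group_per_fold,
                "per_group_pooled": self.per_group_pooled,
            },
            indent=2,
        )


def kfold_indices(n: int, k: int, seed: int) -> FoldPlan:
    """Seeded permutation split into k contiguous blocks of near-equal size."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=np.int64)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        assignments[perm[start : start + size]] = fold
        start += size
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via midranks; exact under ties.

    Raises :class:`UndefinedAUCError` when only one class is present —
    a degenerate ROC is not a coin flip and must not report 0.5.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos + n_neg != len(labels):
        raise ValueError("labels must be binary 0/1")
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(f"need both classes, got {n_pos} positives / {n_neg} negatives")
    ranks = rankdata(scores, method="average")
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _posterior_scores(
    net: DiscreteBayesNet, df: pd.DataFrame, predictors: Sequence[str]
) -> np.ndarray:
    """Loss-group posterior for each record, cached per unique predictor config."""
    key = df[list(predictors)].apply(tuple, axis=1)
    cache: dict[tuple, np.ndarray] = {}
    for cfg in key.unique():
        cache[cfg] = net.query_posterior(TARGET, dict(zip(predictors, cfg)))
    return np.vstack([cache[cfg] for cfg in key])


def cross_validated_auc(
    data,
    dag: DAG,
    k: int = 10,
    alpha: float = 1.0,
    seed: int = 0,
    schema: Optional[Mapping[str, VariableSpec]] = None,
) -> AUCReport:
    """k-fold cross-validated one-vs-rest AUC per loss group.

    Each fold is scored by a network fitted (with Laplace ``alpha``) on the
    other folds; pooling the held-out scores of all folds gives the primary
    per-group figure, with per-fold AUCs reported alongside.
    """
    if isinstance(data, Cohort):
        data = data.to_dataframe()
    if schema is None:
        schema = canonical_schema()
    schema = {n: schema[n] for n in dag.nodes}
    groups = schema[TARGET].states
    predictors = [v for v in dag.nodes if v != TARGET]
    n = len(data)
    plan = kfold_indices(n, k, seed)

    all_scores = np.empty((n, len(groups)))
    for fold in range(k):
        train = data.iloc[plan.train_indices(fold)]
        test_idx = plan.test_indices(fold)
        net = fit_parameters(train, dag, schema, alpha=alpha)
        all_scores[test_idx] = _posterior_scores(net, data.iloc[test_idx], predictors)

    y = data[TARGET].to_numpy()
    per_fold: dict[str, list[Optional[float]]] = {g: [] for g in groups}
    pooled: dict[str, Optional[float]] = {}
    for j, g in enumerate(groups):
        labels = (y == g).astype(int)
        for fold in range(k):
            idx = plan.test_indices(fold)
            try:
                per_fold[g].append(roc_auc(all_scores[idx, j], labels[idx]))
            except UndefinedAUCError:
                per_fold[g].append(None)
        try:
            pooled[g] = roc_auc(all_scores[:, j], labels)
        except UndefinedAUCError:
            pooled[g] = None
    return AUCReport(
        groups=tuple(groups),
        per_group_per_fold=per_fold,
        per_group_pooled=pooled,
        k=k,
        seed=seed,
    )
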