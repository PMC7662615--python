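"""Scenario (sensitivity) tables: loss-group posteriors under fixed predictors.

A scenario table conditions the loss-group distribution on every joint
configuration of a chosen predictor subset, with the unconditional model
marginal as the baseline row — the layout used to report how hearing
deteriorates across gender, age and family-history scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bayesnet import DiscreteBayesNet

TARGET = "loss_group"


@dataclass
class ScenarioTable:
    """Per-configuration conditional distributions over the loss groups."""

    conditioning_vars: tuple[str, ...]
    configurations: list[tuple[str, ...]]
    rows: np.ndarray  # shape (n_configurations, n_loss_groups), each row sums to 1
    baseline: np.ndarray
    loss_states: tuple[str, ...]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, float)
        if self.rows.ndim != 2 or self.rows.shape[0] != len(self.configurations):
            raise ValueError("rows/configurations shape mismatch")
        if not np.allclose(self.rows.sum(axis=1), 1.0, rtol=0, atol=1e-9):
            raise ValueError("scenario rows must sum to 1")

    def row(self, *config: str) -> np.ndarray:
        return self.rows[self.configurations.index(tuple(config))]

    def to_dataframe(self, percent: bool = True) -> pd.DataFrame:
        """Publication-style layout: label columns then the five group columns."""
        scale = 100.0 if percent else 1.0
        cols = {
            var: [cfg[i] for cfg in self.configurations]
            for i, var in enumerate(self.conditioning_vars)
        }
        for j, state in enumerate(self.loss_states):
            cols[f"Group {state}"] = np.round(self.rows[:, j] * scale, 2)
        return pd.DataFrame(cols)

    def best_hearing(self) -> pd.Series:
        """P(best-hearing group) per configuration; see :func:`best_hearing_summary`."""
        return best_hearing_summary(self)


def scenario_table(
    net: DiscreteBayesNet, conditioning: Sequence[str]
) -> ScenarioTable:
    """One posterior row per joint configuration of the conditioning variables.

    Empty conditioning yields just the baseline (the model marginal of the
    loss group).  Conditioning on the loss group itself is rejected.
    """
    conditioning = tuple(conditioning)
    if TARGET in conditioning:
        raise ValueError("cannot condition a scenario table on the loss group itself")
    for v in conditioning:
        if v not in net.schema:
            raise KeyError(f"unknown variable {v!r}")
    baseline = net.query_posterior(TARGET)
    state_lists = [net.schema[v].states for v in conditioning]
    configs = [tuple(c) for c in product(*state_lists)] if conditioning else []
    rows = np.array(
        [
            net.query_posterior(TARGET, dict(zip(conditioning, cfg)))
            for cfg in configs
        ]
    ).reshape(len(configs), len(net.schema[TARGET].states))
    return ScenarioTable(
        conditioning_vars=conditioning,
        configurations=configs,
        rows=rows,
        baseline=baseline,
        loss_states=net.schema[TARGET].states,
    )


def initial_probability_table(
    net: DiscreteBayesNet, predictors: Optional[Sequence[str]] = None
) -> dict[str, ScenarioTable]:
    """One single-predictor scenario table per predictor (plus its baseline)."""
    if predictors is None:
        predictors = [v for v in net.dag.nodes if v != TARGET]
    return {v: scenario_table(net, [v]) for v in predictors}


def best_hearing_summary(table: ScenarioTable) -> pd.Series:
    """Probability of the best-hearing (zero-loss) group per configuration."""
    labels = [
        ", ".join(cfg) if len(cfg) > 1 else cfg[0] for cfg in table.configurations
    ]
    return pd.Series(table.rows[:, 0], index=labels, name="P(best hearing)")


def plot_best_hearing(table: ScenarioTable, path=None):
    """Bar chart of P(best-hearing group) across configurations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = best_hearing_summary(table)
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(s)), 4))
    ax.bar(range(len(s)), 100 * s.values)
    ax.set_xticks(range(len(s)))
    ax.set_xticklabels(s.index, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("P(no measurable loss) [%]")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
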