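"""Model/Results facade over the hearing-loss Bayesian network pipeline.

``HearingLossModel`` is constructed from a cohort (or a discretized
DataFrame), holds the network structure to use — the canonical
predictors→loss DAG, a user DAG, or one learned from the data — and
``fit()`` returns a ``HearingLossResults`` carrying the fitted network with
scenario queries, cross-validation and a text ``summary()``.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .bayesnet import (
    DAG,
    DiscreteBayesNet,
    bic_score,
    canonical_dag,
    fit_parameters,
    learn_structure,
    parameter_count,
)
from .cohort import Cohort, VariableSpec, canonical_schema
from .scenarios import ScenarioTable, initial_probability_table, scenario_table
from .validation import AUCReport, cross_validated_auc

TARGET = "loss_group"


class HearingLossModel:
    """Discrete Bayesian network model of loss group given the predictors.

    Parameters
    ----------
    data : Cohort or DataFrame
        Discretized observations with columns gender, age_group,
        family_history and loss_group (a Cohort is discretized on the fly,
        computing loss groups from audiograms or percentages if needed).
    dag : "canonical" | "learn" | DAG
        Network structure: the three-predictors-into-loss study topology,
        BIC hill-climbing structure learning, or an explicit DAG.
    seed : int
        Used only when ``dag="learn"``.
    """

    def __init__(
        self,
        data: Union[Cohort, pd.DataFrame],
        dag: Union[str, DAG] = "canonical",
        schema: Optional[Mapping[str, VariableSpec]] = None,
        seed: int = 0,
        restarts: int = 3,
    ):
        if isinstance(data, Cohort):
            data = data.to_dataframe()
        self.data = data
        self.schema = dict(schema or canonical_schema())
        if isinstance(dag, DAG):
            self.dag = dag
        elif dag == "canonical":
            self.dag = canonical_dag()
        elif dag == "learn":
            self.dag = learn_structure(data, self.schema, seed=seed, restarts=restarts)
        else:
            raise ValueError(f"dag must be 'canonical', 'learn' or a DAG, got {dag!r}")
        self.nobs = len(data)

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "HearingLossModel":
        return cls(cohort, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HearingLossModel":
        return cls(df, **kwargs)

    def fit(self, alpha: float = 0.0) -> "HearingLossResults":
        """Estimate all CPTs (``alpha=0``: maximum likelihood)."""
        net = fit_parameters(self.data, self.dag, self.schema, alpha=alpha)
        return HearingLossResults(self, net, alpha)


class HearingLossResults:
    """Fitted network plus the analyses hanging off it."""

    def __init__(self, model: HearingLossModel, net: DiscreteBayesNet, alpha: float):
        self.model = model
        self.net = net
        self.alpha = alpha
        self.nobs = model.nobs

    # -- inference ----------------------------------------------------------

    def predict(self, evidence: Optional[Mapping[str, str]] = None) -> pd.Series:
        """Posterior loss-group distribution given (partial) evidence."""
        post = self.net.query_posterior(TARGET, evidence or {})
        return pd.Series(post, index=list(self.net.schema[TARGET].states), name=TARGET)

    def scenario_table(self, by: Sequence[str]) -> ScenarioTable:
        return scenario_table(self.net, by)

    def initial_probabilities(self) -> dict[str, ScenarioTable]:
        return initial_probability_table(self.net)

    def sample(self, n: int, seed: int) -> pd.DataFrame:
        return self.net.sample(n, seed)

    # -- diagnostics --------------------------------------------------------

    @property
    def df_model(self) -> int:
        cards = {k: v.cardinality for k, v in self.net.schema.items()}
        return parameter_count(self.net.dag, cards)

    def bic(self) -> float:
        return bic_score(self.net.dag, self.model.data, self.model.schema)

    def cross_validate(
        self, k: int = 10, alpha: float = 1.0, seed: int = 0
    ) -> AUCReport:
        return cross_validated_auc(
            self.model.data, self.net.dag, k=k, alpha=alpha, seed=seed,
            schema=self.model.schema,
        )

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        lines = []
        w = 72
        lines.append("Hearing-loss Bayesian network".center(w))
        lines.append("=" * w)
        lines.append(f"No. observations: {self.nobs:>10d}    Laplace alpha: {self.alpha:g}")
        lines.append(f"Free parameters:  {self.df_model:>10d}    BIC: {self.bic():.2f}")
        lines.append(f"Edges: {', '.join(f'{u}->{v}' for u, v in self.net.dag.edges) or '(none)'}")
        lines.append("-" * w)
        lines.append("Loss-group distribution by single predictor (percent):")
        for var, table in self.initial_probabilities().items():
            lines.append(f"\n  {var}")
            base = ", ".join(f"{100 * p:.2f}" for p in table.baseline)
            lines.append(f"    baseline: {base}")
            for cfg, row in zip(table.configurations, table.rows):
                vals = ", ".join(f"{100 * p:.2f}" for p in row)
                lines.append(f"    {cfg[0]:>8}: {vals}")
        lines.append("=" * w)
        return "\n".join(lines)

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.net.to_json())
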