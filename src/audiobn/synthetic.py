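"""Seeded synthetic cohorts calibrated to the published summary tables.

The study's raw records are not deposited; what the publication does print
are the cohort marginals (gender split, age quintiles, family-history flag)
and the full grid of loss-group distributions conditional on the three
predictors.  This module packages those tables as a generating model and
draws cohorts from it, so every downstream stage — indexing, fitting,
inference, validation — can be exercised and checked against known ground
truth.

Predictors are sampled independently of each other: the predictor joint was
never published, and conditional-recovery checks do not depend on it (the
estimate of P(loss group | full predictor configuration) converges to the
generating row under any predictor joint with support on that cell).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from .audiometry import Audiogram, LOW_FENCE_DB, SLOPE_PCT_PER_DB
from .bayesnet import CPT, DAG, DiscreteBayesNet, canonical_dag
from .cohort import (
    AGE_GROUP_STATES,
    Cohort,
    FAMILY_HISTORY_STATES,
    GENDER_STATES,
    LOSS_GROUP_STATES,
    VariableSpec,
    WorkerRecord,
    canonical_schema,
)

#: Integer-year bounds of each age group, both ends inclusive; the outer
#: bounds are the observed cohort minimum and maximum ages.
AGE_BOUNDS = ((17, 28), (29, 34), (35, 39), (40, 48), (49, 66))

#: Binaural-loss percentage interval of each group, lower-exclusive /
#: upper-inclusive except group 1 (exactly 0); group 5 is capped at the
#: observed cohort maximum of 67 %.
LOSS_PCT_INTERVALS = ((0.0, 0.0), (0.0, 15.0), (15.0, 30.0), (30.0, 45.0), (45.0, 67.0))


def load_fixture(name: str) -> dict:
    """Load one of the packaged summary-table fixtures by file name."""
    text = resources.files("audiobn.fixtures").joinpath(name).read_text()
    return json.loads(text)


@dataclass
class GeneratingModel:
    """Predictor priors plus P(loss group | gender, age group, family history)."""

    gender_prior: np.ndarray  # over (Women, Men)
    age_prior: np.ndarray  # over the 5 age groups
    fh_prior: np.ndarray  # over (No, Yes)
    loss_cpt: np.ndarray  # shape (2, 5, 2, 5): gender x age x fh x loss group

    def __post_init__(self) -> None:
        self.gender_prior = _unit(np.asarray(self.gender_prior, float), "gender prior")
        self.age_prior = _unit(np.asarray(self.age_prior, float), "age prior")
        self.fh_prior = _unit(np.asarray(self.fh_prior, float), "family-history prior")
        self.loss_cpt = np.asarray(self.loss_cpt, float)
        if self.loss_cpt.shape != (2, 5, 2, 5):
            raise ValueError(f"loss_cpt shape {self.loss_cpt.shape} != (2, 5, 2, 5)")
        if not np.allclose(self.loss_cpt.sum(axis=-1), 1.0, rtol=0, atol=1e-12):
            raise ValueError("loss_cpt rows must sum to 1")

    def row(self, gender: str, age_group: str, family_history: str) -> np.ndarray:
        return self.loss_cpt[
            GENDER_STATES.index(gender),
            AGE_GROUP_STATES.index(age_group),
            FAMILY_HISTORY_STATES.index(family_history),
        ]

    def to_bayes_net(self) -> DiscreteBayesNet:
        """The equivalent network on the canonical predictor→loss DAG."""
        return build_net(
            {
                "gender": self.gender_prior,
                "age_group": self.age_prior,
                "family_history": self.fh_prior,
            },
            self.loss_cpt,
        )


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    if np.any(v < 0):
        raise ValueError(f"{what}: negative entry")
    s = v.sum()
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"{what}: sums to {s}, expected 1")
    return v / s


def _normalize_rows(table: np.ndarray) -> np.ndarray:
    """Renormalize percent rows that sum to 100 ± rounding noise."""
    table = np.asarray(table, float)
    sums = table.sum(axis=-1, keepdims=True)
    if np.any(np.abs(sums - 100.0) > 0.5):
        raise ValueError("a table row is too far from 100% to be rounding noise")
    return table / sums


def default_generating_model() -> GeneratingModel:
    """The packaged model: published marginals + the full conditional grid."""
    gender = load_fixture("gender.json")
    age = load_fixture("table2_age.json")
    fh = load_fixture("table3_family_history.json")
    full = load_fixture("table8_full.json")
    cpt = np.empty((2, 5, 2, 5))
    for gi, g in enumerate(GENDER_STATES):
        for ai, a in enumerate(AGE_GROUP_STATES):
            for fi, f in enumerate(FAMILY_HISTORY_STATES):
                cpt[gi, ai, fi] = full["rows"][f][g][a]
    return GeneratingModel(
        gender_prior=np.array(gender["frequencies"]),
        age_prior=np.array(age["frequencies"]),
        fh_prior=np.array(fh["frequencies"]),
        loss_cpt=_normalize_rows(cpt),
    )


def build_net(
    priors: Mapping[str, Sequence[float]], loss_table: np.ndarray
) -> DiscreteBayesNet:
    """Assemble a predictors→loss_group network from priors and a conditional table.

    ``priors`` maps a subset of the canonical predictors to their marginal
    distributions; ``loss_table`` has one leading axis per prior (in the
    given order) and the loss-group axis last.  Rows given in percent are
    renormalized.
    """
    schema_all = canonical_schema()
    names = tuple(priors.keys())
    loss_table = np.asarray(loss_table, float)
    if np.any(loss_table.sum(axis=-1) > 2.0):  # percent-scaled input
        loss_table = _normalize_rows(loss_table)
    expected = tuple(schema_all[v].cardinality for v in names) + (5,)
    if loss_table.shape != expected:
        raise ValueError(f"loss table shape {loss_table.shape} != {expected}")
    dag = DAG(nodes=(*names, "loss_group"), edges=tuple((v, "loss_group") for v in names))
    cpts = {v: CPT(v, (), _unit(np.asarray(priors[v], float), v)) for v in names}
    cpts["loss_group"] = CPT("loss_group", names, loss_table)
    schema = {v: schema_all[v] for v in (*names, "loss_group")}
    return DiscreteBayesNet(dag, cpts, schema)


def recover_conditional(
    priors: Mapping[str, Sequence[float]],
    loss_table: np.ndarray,
    evidence: Mapping[str, str],
    n: int,
    seed: int,
    alpha: float = 0.0,
) -> np.ndarray:
    """Sampling-and-refitting recovery of one conditional loss-group row.

    Builds the generating predictors→loss network, draws ``n`` records,
    refits the CPTs (``alpha=0``: MLE) and returns the loss-group posterior
    under the given evidence by variable elimination.  A point-mass prior
    pins a predictor to a single state, which turns this into per-cell
    recovery of a single conditional row.
    """
    from .bayesnet import fit_parameters

    net = build_net(priors, loss_table)
    df = net.sample(n, seed)
    fitted = fit_parameters(df, net.dag, net.schema, alpha=alpha)
    return fitted.query_posterior("loss_group", dict(evidence))


def _records_from_codes(
    gender_c: np.ndarray,
    age_group_c: np.ndarray,
    fh_c: np.ndarray,
    loss_c: np.ndarray,
    rng: np.random.Generator,
    with_audiograms: bool,
    id_prefix: str = "w",
) -> Cohort:
    n = len(gender_c)
    lows = np.array([b[0] for b in AGE_BOUNDS])
    highs = np.array([b[1] for b in AGE_BOUNDS])
    ages = rng.integers(lows[age_group_c], highs[age_group_c] + 1)
    records = []
    pcts = None
    if with_audiograms:
        pcts = loss_pct_for_group(loss_c + 1, rng)
    for i in range(n):
        audiogram = None
        pct = None
        if with_audiograms:
            pct = float(pcts[i])
            audiogram = audiogram_for_loss(pct)
        records.append(
            WorkerRecord(
                id=f"{id_prefix}{i:06d}",
                gender=GENDER_STATES[gender_c[i]],
                age_years=int(ages[i]),
                family_history=FAMILY_HISTORY_STATES[fh_c[i]],
                audiogram=audiogram,
                binaural_loss_pct=pct,
                loss_group=LOSS_GROUP_STATES[loss_c[i]],
            )
        )
    return Cohort(records)


def _draw_rows(table2d: np.ndarray, row_idx: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = table2d.cumsum(axis=1)
    u = rng.random(len(row_idx))
    codes = (u[:, None] > cum[row_idx]).sum(axis=1)
    return np.minimum(codes, table2d.shape[1] - 1)


def sample_cohort(
    model: GeneratingModel,
    n: int,
    seed: int,
    with_audiograms: bool = False,
) -> Cohort:
    """Draw a full synthetic cohort; deterministic given the seed.

    Ages are drawn uniformly on the integer years of the drawn age group.
    With ``with_audiograms=True`` each record also carries a binaural-loss
    percentage drawn uniformly on its group's interval and a flat audiogram
    that reproduces it exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    g = _draw_rows(model.gender_prior[None, :], np.zeros(n, int), rng)
    a = _draw_rows(model.age_prior[None, :], np.zeros(n, int), rng)
    f = _draw_rows(model.fh_prior[None, :], np.zeros(n, int), rng)
    flat = model.loss_cpt.reshape(-1, 5)
    cfg = np.ravel_multi_index((g, a, f), dims=(2, 5, 2))
    loss = _draw_rows(flat, cfg, rng)
    return _records_from_codes(g, a, f, loss, rng, with_audiograms)


def sample_cell(
    model: GeneratingModel,
    config: Mapping[str, str],
    n: int,
    seed: int,
    with_audiograms: bool = False,
) -> Cohort:
    """Draw ``n`` records all sharing one fixed predictor configuration."""
    required = {"gender", "age_group", "family_history"}
    if set(config) != required:
        raise ValueError(f"config must fix exactly {sorted(required)}, got {sorted(config)}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    gi = GENDER_STATES.index(config["gender"])
    ai = AGE_GROUP_STATES.index(config["age_group"])
    fi = FAMILY_HISTORY_STATES.index(config["family_history"])
    row = model.loss_cpt[gi, ai, fi]
    loss = _draw_rows(row[None, :], np.zeros(n, int), rng)
    g = np.full(n, gi)
    a = np.full(n, ai)
    f = np.full(n, fi)
    return _records_from_codes(g, a, f, loss, rng, with_audiograms)


def loss_pct_for_group(groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform percentage within each group's interval (group 1 → exactly 0).

    Intervals are lower-exclusive, matching the discretizer's bins, so the
    draw is on the open-left interval; group 5 is capped at 67 %.
    """
    groups = np.asarray(groups, int)
    lo = np.array([iv[0] for iv in LOSS_PCT_INTERVALS])[groups - 1]
    hi = np.array([iv[1] for iv in LOSS_PCT_INTERVALS])[groups - 1]
    u = rng.random(len(groups))
    # (lo, hi]: u in [0,1) maps to hi - u*(hi-lo), never hitting lo exactly
    return hi - u * (hi - lo)


def audiogram_for_loss(binaural_pct: float, seed: int = 0) -> Audiogram:
    """A flat, symmetric audiogram whose binaural index equals ``binaural_pct``.

    Both ears get identical flat thresholds ``25 + pct/1.5`` dB HL, so both
    monaural losses — and hence the binaural mix — equal the requested
    percentage exactly.  The ``seed`` is accepted for interface symmetry;
    the construction is jitter-free.
    """
    if not (0.0 <= binaural_pct <= 100.0):
        raise ValueError(f"binaural loss {binaural_pct} outside [0, 100]")
    t = LOW_FENCE_DB + binaural_pct / SLOPE_PCT_PER_DB
    ear = (t, t, t, t)
    return Audiogram(ear, ear)
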