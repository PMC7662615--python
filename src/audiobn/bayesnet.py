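"""From-scratch discrete Bayesian network.

A network is a directed acyclic graph over named categorical variables plus
one conditional probability table (CPT) per variable, factorizing the joint
as ``p(x1,...,xn) = prod_i p(xi | parents(xi))``.  This module provides

* maximum-likelihood / Laplace-smoothed parameter fitting from a cohort,
* exact posterior queries by sum-product variable elimination,
* BIC-scored greedy hill-climbing structure search with random restarts,
* ancestral sampling, and
* a bit-exact JSON serialization.

All probability arithmetic is in linear space (the networks here are tiny);
only the BIC log-likelihood works in log space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import Cohort, VariableSpec, canonical_schema

ROW_SUM_TOL = 1e-12


class ImpossibleEvidenceError(ValueError):
    """The supplied evidence has zero probability under the network."""


class UndefinedScoreError(ValueError):
    pass


# ---------------------------------------------------------------------------
# DAG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DAG:
    """A directed acyclic graph as an ordered node list plus parent→child edges."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        known = set(self.nodes)
        for u, v in self.edges:
            if u not in known or v not in known:
                raise ValueError(f"edge ({u}, {v}) references undeclared node")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"edge set {self.edges} contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(u for u, v in self.edges if v == node)

    def topological_order(self) -> list[str]:
        # deterministic: break ties by declaration order
        order_idx = {n: i for i, n in enumerate(self.nodes)}
        return list(
            nx.lexicographical_topological_sort(
                self.to_networkx(), key=lambda n: order_idx[n]
            )
        )

    def with_edge(self, u: str, v: str) -> "DAG":
        return DAG(self.nodes, (*self.edges, (u, v)))

    def without_edge(self, u: str, v: str) -> "DAG":
        return DAG(self.nodes, tuple(e for e in self.edges if e != (u, v)))

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.edges)

    def v_structures(self) -> frozenset[tuple[str, str, str]]:
        """Unshielded colliders (a, c, b) with a→c←b, a-b non-adjacent, a<b."""
        adj = self.skeleton()
        out = set()
        for c in self.nodes:
            ps = sorted(self.parents(c))
            for i, a in enumerate(ps):
                for b in ps[i + 1 :]:
                    if frozenset((a, b)) not in adj:
                        out.add((a, c, b))
        return frozenset(out)


def markov_equivalent(d1: DAG, d2: DAG) -> bool:
    """Same skeleton and same unshielded colliders (Verma–Pearl criterion)."""
    return d1.skeleton() == d2.skeleton() and d1.v_structures() == d2.v_structures()


def canonical_dag() -> DAG:
    """The study network: the three predictors are parentless parents of loss."""
    return DAG(
        nodes=("gender", "age_group", "family_history", "loss_group"),
        edges=(
            ("gender", "loss_group"),
            ("age_group", "loss_group"),
            ("family_history", "loss_group"),
        ),
    )


def parameter_count(dag: DAG, cardinalities: Mapping[str, int]) -> int:
    """Free parameters of the factorized joint: Σ (card−1)·Π card(parents)."""
    total = 0
    for node in dag.nodes:
        if node not in cardinalities:
            raise KeyError(f"no cardinality for node {node!r}")
        prod = 1
        for p in dag.parents(node):
            prod *= cardinalities[p]
        total += (cardinalities[node] - 1) * prod
    return total


# ---------------------------------------------------------------------------
# CPTs and the network
# ---------------------------------------------------------------------------

@dataclass
class CPT:
    """P(child | parents) as an array with one axis per parent, child last."""

    child: str
    parents: tuple[str, ...]
    table: np.ndarray  # shape (*parent_cards, child_card)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != len(self.parents) + 1:
            raise ValueError(
                f"CPT for {self.child}: table rank {self.table.ndim} != "
                f"{len(self.parents) + 1}"
            )
        if np.any(self.table < -ROW_SUM_TOL) or np.any(self.table > 1 + ROW_SUM_TOL):
            raise ValueError(f"CPT for {self.child}: entries outside [0, 1]")
        sums = self.table.sum(axis=-1)
        if not np.allclose(sums, 1.0, rtol=0.0, atol=ROW_SUM_TOL):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(
                f"CPT for {self.child}: rows must sum to 1 (worst deviation {worst:g})"
            )

    def row(self, parent_idx: tuple[int, ...]) -> np.ndarray:
        return self.table[parent_idx]


@dataclass
class DiscreteBayesNet:
    dag: DAG
    cpts: dict[str, CPT]
    schema: dict[str, VariableSpec]

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise ValueError(f"missing CPT for {node!r}")
            if tuple(self.cpts[node].parents) != tuple(self.dag.parents(node)):
                raise ValueError(f"CPT parents for {node!r} disagree with DAG")

    def cardinality(self, node: str) -> int:
        return self.schema[node].cardinality

    # -- joint and inference ------------------------------------------------

    def joint_probability(self, assignment: Mapping[str, str]) -> float:
        """Probability of one full assignment: the product of CPT entries."""
        missing = [n for n in self.dag.nodes if n not in assignment]
        if missing:
            raise ValueError(f"assignment missing nodes {missing}")
        p = 1.0
        for node in self.dag.nodes:
            cpt = self.cpts[node]
            pidx = tuple(self.schema[q].index(assignment[q]) for q in cpt.parents)
            p *= cpt.row(pidx)[self.schema[node].index(assignment[node])]
        return p

    def query_posterior(
        self, target: str, evidence: Optional[Mapping[str, str]] = None
    ) -> np.ndarray:
        """Exact P(target | evidence) by sum-product variable elimination.

        Elimination order is by min-degree on the factor interaction graph;
        the result is normalized and sums to 1 within 1e-12.
        """
        evidence = dict(evidence or {})
        if target in evidence:
            raise ValueError(f"target {target!r} appears in the evidence")
        for var, state in evidence.items():
            self.schema[var].index(state)  # validates

        # factors: (vars tuple, ndarray indexed by those vars' states),
        # with evidence sliced out up front
        factors: list[tuple[tuple[str, ...], np.ndarray]] = []
        for node in self.dag.nodes:
            cpt = self.cpts[node]
            fvars = (*cpt.parents, node)
            arr = cpt.table
            keep_vars, idx = [], []
            for v in fvars:
                if v in evidence:
                    idx.append(self.schema[v].index(evidence[v]))
                else:
                    keep_vars.append(v)
                    idx.append(slice(None))
            factors.append((tuple(keep_vars), arr[tuple(idx)]))

        hidden = [n for n in self.dag.nodes if n != target and n not in evidence]
        while hidden:
            # min-degree: eliminate the variable appearing with fewest neighbours
            def degree(v: str) -> tuple[int, str]:
                nbrs = set()
                for fvars, _ in factors:
                    if v in fvars:
                        nbrs.update(fvars)
                nbrs.discard(v)
                return (len(nbrs), v)

            var = min(hidden, key=degree)
            hidden.remove(var)
            involved = [f for f in factors if var in f[0]]
            factors = [f for f in factors if var not in f[0]]
            prod_vars, prod = _multiply_factors(involved)
            axis = prod_vars.index(var)
            summed = prod.sum(axis=axis)
            factors.append((tuple(v for v in prod_vars if v != var), summed))

        fvars, arr = _multiply_factors(factors)
        if fvars == ():
            raise ValueError("all variables eliminated; target missing from net?")
        if fvars != (target,):
            axes = tuple(i for i, v in enumerate(fvars) if v != target)
            arr = arr.sum(axis=axes)
        z = arr.sum()
        if z <= 0.0:
            raise ImpossibleEvidenceError(
                f"evidence {evidence} has zero probability under the network"
            )
        return arr / z

    # -- sampling -----------------------------------------------------------

    def sample(self, n: int, seed: int) -> pd.DataFrame:
        """Ancestral sampling in topological order; deterministic given seed."""
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        rng = np.random.default_rng(seed)
        cols: dict[str, np.ndarray] = {}
        for node in self.dag.topological_order():
            cpt = self.cpts[node]
            card = self.cardinality(node)
            if not cpt.parents:
                codes = rng.choice(card, size=n, p=cpt.table)
            else:
                # group rows by joint parent configuration, one draw per row
                pcards = [self.cardinality(p) for p in cpt.parents]
                pcfg = np.ravel_multi_index(
                    tuple(cols[p] for p in cpt.parents), dims=pcards
                )
                flat = cpt.table.reshape(-1, card)
                u = rng.random(n)
                cum = flat.cumsum(axis=1)
                codes = (u[:, None] > cum[pcfg]).sum(axis=1)
                codes = np.minimum(codes, card - 1)  # guard float round-off
            cols[node] = codes.astype(np.int64)
        return pd.DataFrame(
            {
                node: pd.Categorical.from_codes(
                    cols[node], categories=list(self.schema[node].states)
                ).astype(str)
                for node in self.dag.nodes
            }
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "variables": [
                {
                    "name": v.name,
                    "states": list(v.states),
                    "ordinal": v.ordinal,
                }
                for v in (self.schema[n] for n in self.dag.nodes)
            ],
            "edges": [list(e) for e in self.dag.edges],
            "cpts": [
                {
                    "child": c.child,
                    "parents": list(c.parents),
                    # row-major flattening; parent state order = schema order
                    "table": c.table.ravel().tolist(),
                }
                for c in (self.cpts[n] for n in self.dag.nodes)
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DiscreteBayesNet":
        doc = json.loads(text)
        schema = {
            v["name"]: VariableSpec(v["name"], tuple(v["states"]), v["ordinal"])
            for v in doc["variables"]
        }
        dag = DAG(
            tuple(v["name"] for v in doc["variables"]),
            tuple(tuple(e) for e in doc["edges"]),
        )
        cpts = {}
        for c in doc["cpts"]:
            shape = [schema[p].cardinality for p in c["parents"]]
            shape.append(schema[c["child"]].cardinality)
            cpts[c["child"]] = CPT(
                c["child"], tuple(c["parents"]), np.array(c["table"]).reshape(shape)
            )
        return cls(dag, cpts, schema)


def _multiply_factors(
    factors: Sequence[tuple[tuple[str, ...], np.ndarray]]
) -> tuple[tuple[str, ...], np.ndarray]:
    """Pointwise product of factors after broadcasting to a common axis set."""
    if not factors:
        return (), np.array(1.0)
    all_vars: list[str] = []
    for fvars, _ in factors:
        for v in fvars:
            if v not in all_vars:
                all_vars.append(v)
    out = np.array(1.0)
    for fvars, arr in factors:
        positions = [all_vars.index(v) for v in fvars]
        perm = np.argsort(positions)  # reorder axes to all_vars order
        transposed = np.transpose(arr, perm) if arr.ndim > 1 else arr
        shape = [1] * len(all_vars)
        for pos, dim in zip(sorted(positions), transposed.shape):
            shape[pos] = dim
        out = out * transposed.reshape(shape)
    return tuple(all_vars), out


# ---------------------------------------------------------------------------
# Parameter fitting
# ---------------------------------------------------------------------------

def _as_codes(
    data, schema: Mapping[str, VariableSpec]
) -> tuple[dict[str, np.ndarray], int]:
    """Integer-code the columns of a cohort/DataFrame per the schema."""
    if isinstance(data, Cohort):
        data = data.to_dataframe()
    codes = {}
    n = len(data)
    for name, spec in schema.items():
        if name not in data.columns:
            raise KeyError(f"cohort lacks column {name!r}")
        cat = pd.Categorical(data[name], categories=list(spec.states))
        if (cat.codes < 0).any():
            bad = sorted(set(data[name]) - set(spec.states))
            raise ValueError(f"column {name!r} has unknown state label(s) {bad}")
        codes[name] = cat.codes.astype(np.int64)
    return codes, n


def _family_counts(
    codes: Mapping[str, np.ndarray],
    child: str,
    parents: Sequence[str],
    cards: Mapping[str, int],
) -> np.ndarray:
    shape = [cards[p] for p in parents] + [cards[child]]
    idx = np.ravel_multi_index(
        tuple(codes[v] for v in (*parents, child)), dims=shape
    )
    return np.bincount(idx, minlength=int(np.prod(shape))).reshape(shape).astype(float)


def fit_parameters(
    data,
    dag: DAG,
    schema: Optional[Mapping[str, VariableSpec]] = None,
    alpha: float = 0.0,
) -> DiscreteBayesNet:
    """Estimate all CPTs from a cohort.

    Each entry is ``(count + alpha) / (row_total + alpha * card(child))``;
    ``alpha=0`` is the maximum-likelihood estimate, with unobserved parent
    configurations falling back to a uniform row.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if schema is None:
        schema = canonical_schema()
    schema = {n: schema[n] for n in dag.nodes}
    codes, n = _as_codes(data, schema)
    if n == 0:
        raise ValueError("cannot fit parameters on an empty cohort")
    cards = {k: v.cardinality for k, v in schema.items()}
    cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        counts = _family_counts(codes, node, parents, cards)
        totals = counts.sum(axis=-1, keepdims=True)
        card = cards[node]
        table = np.empty_like(counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            table = (counts + alpha) / (totals + alpha * card)
        empty = (totals + alpha * card).squeeze(-1) == 0
        if np.any(empty):
            table[empty] = 1.0 / card
        cpts[node] = CPT(node, parents, table)
    return DiscreteBayesNet(dag, cpts, dict(schema))


# ---------------------------------------------------------------------------
# Scoring and structure search
# ---------------------------------------------------------------------------

def _family_loglik(counts: np.ndarray) -> float:
    """Max log-likelihood contribution of one family, with 0·log 0 = 0."""
    totals = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        logp = np.log(counts) - np.log(totals)
        term = np.where(counts > 0, counts * logp, 0.0)
    return float(term.sum())


def family_bic(
    codes: Mapping[str, np.ndarray],
    child: str,
    parents: Sequence[str],
    cards: Mapping[str, int],
    n: int,
) -> float:
    counts = _family_counts(codes, child, parents, cards)
    k = (cards[child] - 1) * int(np.prod([cards[p] for p in parents], initial=1))
    return _family_loglik(counts) - 0.5 * k * math.log(n)


def bic_score(
    dag: DAG, data, schema: Optional[Mapping[str, VariableSpec]] = None
) -> float:
    """BIC of a DAG: max log-likelihood − (free params / 2)·ln N; higher is better.

    Decomposes over families, which the hill climber exploits.
    """
    if schema is None:
        schema = canonical_schema()
    schema = {n: schema[n] for n in dag.nodes}
    codes, n = _as_codes(data, schema)
    if n == 0:
        raise UndefinedScoreError("empty cohort")
    cards = {k: v.cardinality for k, v in schema.items()}
    return sum(family_bic(codes, node, dag.parents(node), cards, n) for node in dag.nodes)


def _hill_climb(
    start: DAG,
    codes: Mapping[str, np.ndarray],
    cards: Mapping[str, int],
    n: int,
    cache: dict,
) -> tuple[DAG, float]:
    def fam(child: str, parents: tuple[str, ...]) -> float:
        key = (child, frozenset(parents))
        if key not in cache:
            cache[key] = family_bic(codes, child, parents, cards, n)
        return cache[key]

    dag = start
    score = sum(fam(v, dag.parents(v)) for v in dag.nodes)
    improved = True
    while improved:
        improved = False
        best_gain, best_dag = 1e-9, None
        nodes = dag.nodes
        edge_set = set(dag.edges)
        # candidate moves in deterministic lexicographic order (child, parent)
        for child in sorted(nodes):
            for parent in sorted(nodes):
                if parent == child:
                    continue
                pa = dag.parents(child)
                if (parent, child) in edge_set:
                    # delete
                    gain = fam(child, tuple(p for p in pa if p != parent)) - fam(child, pa)
                    cand = dag.without_edge(parent, child)
                    if gain > best_gain:
                        best_gain, best_dag = gain, cand
                    # reverse: delete parent→child, add child→parent
                    try:
                        cand = dag.without_edge(parent, child).with_edge(child, parent)
                    except ValueError:
                        cand = None
                    if cand is not None:
                        pb = dag.parents(parent)
                        gain = (
                            fam(child, tuple(p for p in pa if p != parent))
                            - fam(child, pa)
                            + fam(parent, (*pb, child))
                            - fam(parent, pb)
                        )
                        if gain > best_gain:
                            best_gain, best_dag = gain, cand
                elif (child, parent) not in edge_set:
                    # add parent→child if acyclic
                    try:
                        cand = dag.with_edge(parent, child)
                    except ValueError:
                        continue
                    gain = fam(child, (*pa, parent)) - fam(child, pa)
                    if gain > best_gain:
                        best_gain, best_dag = gain, cand
        if best_dag is not None:
            dag = best_dag
            score += best_gain
            improved = True
    return dag, score


def learn_structure(
    data,
    schema: Optional[Mapping[str, VariableSpec]] = None,
    seed: int = 0,
    restarts: int = 3,
) -> DAG:
    """Greedy BIC hill climbing over add/delete/reverse single-edge moves.

    Restart 0 starts from the empty graph; each further restart perturbs from
    a random seeded DAG. Deterministic given the seed; the best-scoring DAG
    over all restarts is returned.
    """
    import warnings

    if schema is None:
        schema = canonical_schema()
    codes, n = _as_codes(data, schema)
    if len(schema) < 2:
        raise ValueError("structure learning needs >= 2 variables")
    for name, col in codes.items():
        if len(np.unique(col)) < 2:
            warnings.warn(f"column {name!r} is constant; it will stay disconnected")
    cards = {k: v.cardinality for k, v in schema.items()}
    nodes = tuple(schema.keys())
    rng = np.random.default_rng(seed)
    cache: dict = {}

    best_dag, best_score = _hill_climb(DAG(nodes), codes, cards, n, cache)
    for _ in range(max(0, restarts)):
        order = list(nodes)
        rng.shuffle(order)
        edges = []
        for i, u in enumerate(order):
            for v in order[i + 1 :]:
                if rng.random() < 0.3:
                    edges.append((u, v))
        start = DAG(nodes, tuple(edges))
        dag, score = _hill_climb(start, codes, cards, n, cache)
        if score > best_score + 1e-9:
            best_dag, best_score = dag, score
    return best_dag
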