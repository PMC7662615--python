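import math

import numpy as np
import pandas as pd
import pytest

from audiobn import (
    CPT,
    DAG,
    DiscreteBayesNet,
    ImpossibleEvidenceError,
    VariableSpec,
    bic_score,
    canonical_dag,
    fit_parameters,
    parameter_count,
)

from conftest import enumerate_posterior, random_net


def two_node_binary_net(p_a=0.3, p_b_given_a=(0.9, 0.2)):
    schema = {
        "a": VariableSpec("a", ("0", "1")),
        "b": VariableSpec("b", ("0", "1")),
    }
    dag = DAG(("a", "b"), (("a", "b"),))
    cpts = {
        "a": CPT("a", (), np.array([p_a, 1 - p_a])),
        "b": CPT("b", ("a",), np.array([[p_b_given_a[0], 1 - p_b_given_a[0]],
                                        [p_b_given_a[1], 1 - p_b_given_a[1]]])),
    }
    return DiscreteBayesNet(dag, cpts, schema)


# -- DAG / parameter counting ------------------------------------------------

def test_dag_rejects_cycles_and_unknown_nodes():
    with pytest.raises(ValueError):
        DAG(("a", "b"), (("a", "b"), ("b", "a")))
    with pytest.raises(ValueError):
        DAG(("a",), (("a", "z"),))


def test_parameter_count_four_binary_nodes():
    nodes = ("a", "b", "c", "d")
    cards = dict.fromkeys(nodes, 2)
    assert parameter_count(DAG(nodes), cards) == 4
    # the unfactorized joint over the same four binaries needs 2^4 - 1
    assert 2 ** 4 - 1 == 15


def test_parameter_count_canonical_study_dag():
    cards = {"gender": 2, "age_group": 5, "family_history": 2, "loss_group": 5}
    assert parameter_count(canonical_dag(), cards) == 1 + 4 + 1 + (5 - 1) * 2 * 5 * 2


# -- CPT validation ----------------------------------------------------------

def test_cpt_rejects_unnormalized_rows():
    with pytest.raises(ValueError, match="sum to 1"):
        CPT("x", (), np.array([0.5, 0.4]))
    with pytest.raises(ValueError):
        CPT("x", (), np.array([1.2, -0.2]))


# -- joint probability -------------------------------------------------------

def test_joint_single_node():
    net = DiscreteBayesNet(
        DAG(("a",)),
        {"a": CPT("a", (), np.array([0.3, 0.7]))},
        {"a": VariableSpec("a", ("0", "1"))},
    )
    assert net.joint_probability({"a": "0"}) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        net.joint_probability({})


def test_joint_two_independent_uniform_nodes():
    schema = {v: VariableSpec(v, ("0", "1")) for v in "ab"}
    net = DiscreteBayesNet(
        DAG(("a", "b")),
        {v: CPT(v, (), np.array([0.5, 0.5])) for v in "ab"},
        schema,
    )
    for a in "01":
        for b in "01":
            assert net.joint_probability({"a": a, "b": b}) == pytest.approx(0.25)


def test_joint_matches_factor_product_on_random_nets():
    rng = np.random.default_rng(42)
    for _ in range(10):
        net = random_net(rng)
        total = 0.0
        from itertools import product
        for combo in product(*[net.schema[v].states for v in net.dag.nodes]):
            total += net.joint_probability(dict(zip(net.dag.nodes, combo)))
        assert total == pytest.approx(1.0, abs=1e-10)


# -- parameter fitting -------------------------------------------------------

def test_mle_is_relative_frequency():
    df = pd.DataFrame({"a": ["0"] * 3 + ["1"] * 7, "b": ["0"] * 10})
    schema = {v: VariableSpec(v, ("0", "1")) for v in "ab"}
    net = fit_parameters(df, DAG(("a", "b")), schema, alpha=0.0)
    assert net.cpts["a"].table[0] == pytest.approx(0.3)


def test_unobserved_parent_row_falls_back_to_uniform():
    df = pd.DataFrame({"a": ["0", "0"], "b": ["0", "1"]})
    schema = {v: VariableSpec(v, ("0", "1")) for v in "ab"}
    net = fit_parameters(df, DAG(("a", "b"), (("a", "b"),)), schema, alpha=0.0)
    assert net.cpts["b"].table[1] == pytest.approx([0.5, 0.5])


def test_laplace_smoothing_formula():
    df = pd.DataFrame({"a": ["0"] * 3 + ["1"] * 7})
    schema = {"a": VariableSpec("a", ("0", "1"))}
    net = fit_parameters(df, DAG(("a",)), schema, alpha=1.0)
    assert net.cpts["a"].table == pytest.approx([(3 + 1) / 12, (7 + 1) / 12])


def test_fit_rejects_empty_cohort_and_unknown_states():
    schema = {"a": VariableSpec("a", ("0", "1"))}
    with pytest.raises(ValueError):
        fit_parameters(pd.DataFrame({"a": []}), DAG(("a",)), schema)
    with pytest.raises(ValueError, match="unknown state"):
        fit_parameters(pd.DataFrame({"a": ["0", "2"]}), DAG(("a",)), schema)


def test_parameter_recovery_from_large_sample():
    """fit_parameters ∘ sample recovers the generating CPTs within 4σ."""
    net = two_node_binary_net(p_a=0.35, p_b_given_a=(0.8, 0.1))
    n = 200_000
    df = net.sample(n, seed=7)
    fitted = fit_parameters(df, net.dag, net.schema, alpha=0.0)
    p_hat = fitted.cpts["a"].table[0]
    se = math.sqrt(0.35 * 0.65 / n)
    assert abs(p_hat - 0.35) < 4 * se
    for i, (truth, n_row) in enumerate(zip((0.8, 0.1), np.bincount(
            (df["a"] == "1").astype(int), minlength=2))):
        p_hat = fitted.cpts["b"].table[i, 0]
        se = math.sqrt(truth * (1 - truth) / n_row)
        assert abs(p_hat - truth) < 4 * se


# -- inference ---------------------------------------------------------------

def test_full_parent_evidence_returns_cpt_row(canonical_net):
    post = canonical_net.query_posterior(
        "loss_group",
        {"gender": "Women", "age_group": "<29", "family_history": "No"},
    )
    expected = canonical_net.cpts["loss_group"].table[0, 0, 0]
    assert post == pytest.approx(expected, abs=1e-12)


def test_root_prior_with_empty_evidence(canonical_net):
    post = canonical_net.query_posterior("gender")
    assert post == pytest.approx(canonical_net.cpts["gender"].table, abs=1e-12)


def test_posterior_sums_to_one(canonical_net):
    post = canonical_net.query_posterior("loss_group", {"gender": "Men"})
    assert post.sum() == pytest.approx(1.0, abs=1e-12)


def test_target_in_evidence_rejected(canonical_net):
    with pytest.raises(ValueError):
        canonical_net.query_posterior("loss_group", {"loss_group": "1"})


def test_impossible_evidence_is_an_explicit_error():
    net = two_node_binary_net(p_a=1.0, p_b_given_a=(0.5, 0.5))
    with pytest.raises(ImpossibleEvidenceError):
        net.query_posterior("b", {"a": "1"})


def test_variable_elimination_equals_enumeration_on_random_nets():
    """Exact inference ≡ brute-force joint enumeration to 1e-12."""
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(25):
        net = random_net(rng)
        nodes = list(net.dag.nodes)
        target = nodes[int(rng.integers(len(nodes)))]
        others = [v for v in nodes if v != target]
        rng.shuffle(others)
        n_ev = int(rng.integers(0, len(others) + 1))
        evidence = {v: net.schema[v].states[int(rng.integers(net.schema[v].cardinality))]
                    for v in others[:n_ev]}
        try:
            ve = net.query_posterior(target, evidence)
        except ImpossibleEvidenceError:
            continue
        brute = enumerate_posterior(net, target, evidence)
        assert ve == pytest.approx(brute, abs=1e-12)
        checked += 1
    assert checked >= 15


# -- sampling ----------------------------------------------------------------

def test_point_mass_root_sampling():
    net = two_node_binary_net(p_a=1.0, p_b_given_a=(1.0, 0.0))
    df = net.sample(50, seed=1)
    assert (df["a"] == "0").all()
    assert (df["b"] == "0").all()


def test_sampling_is_deterministic_given_seed(canonical_net):
    a = canonical_net.sample(500, seed=9)
    b = canonical_net.sample(500, seed=9)
    pd.testing.assert_frame_equal(a, b)
    c = canonical_net.sample(500, seed=10)
    assert not a.equals(c)


def test_empirical_joint_converges_to_model_joint():
    net = two_node_binary_net(p_a=0.4, p_b_given_a=(0.7, 0.2))
    n = 500_000
    df = net.sample(n, seed=13)
    for a in "01":
        for b in "01":
            p = net.joint_probability({"a": a, "b": b})
            emp = ((df["a"] == a) & (df["b"] == b)).mean()
            se = math.sqrt(p * (1 - p) / n)
            assert abs(emp - p) < 4 * se


def test_sample_rejects_bad_n(canonical_net):
    with pytest.raises(ValueError):
        canonical_net.sample(0, seed=1)


# -- serialization -----------------------------------------------------------

def test_json_round_trip_bit_exact(canonical_net):
    text = canonical_net.to_json()
    back = DiscreteBayesNet.from_json(text)
    assert back.to_json() == text
    assert back.dag.edges == canonical_net.dag.edges
    for node in canonical_net.dag.nodes:
        assert np.array_equal(back.cpts[node].table, canonical_net.cpts[node].table)


# -- BIC ---------------------------------------------------------------------

def test_bic_closed_form_single_binary_node():
    df = pd.DataFrame({"a": ["0"] * 50 + ["1"] * 50})
    schema = {"a": VariableSpec("a", ("0", "1"))}
    got = bic_score(DAG(("a",)), df, schema)
    assert got == pytest.approx(100 * math.log(0.5) - 0.5 * math.log(100))


def test_bic_is_family_decomposable():
    """A single-edge change shifts the score only through the changed family."""
    rng = np.random.default_rng(3)
    net = two_node_binary_net(0.4, (0.9, 0.3))
    df = net.sample(2000, seed=3)
    schema = net.schema
    base = DAG(("a", "b"))
    with_edge = DAG(("a", "b"), (("a", "b"),))
    from audiobn.bayesnet import _as_codes, family_bic

    codes, n = _as_codes(df, schema)
    cards = {k: v.cardinality for k, v in schema.items()}
    delta_full = bic_score(with_edge, df, schema) - bic_score(base, df, schema)
    delta_family = family_bic(codes, "b", ("a",), cards, n) - family_bic(codes, "b", (), cards, n)
    assert delta_full == pytest.approx(delta_family, abs=1e-9)


def test_bic_penalizes_spurious_edge_on_independent_data():
    schema = {v: VariableSpec(v, ("0", "1")) for v in "ab"}
    rng = np.random.default_rng(17)
    df = pd.DataFrame({
        "a": rng.choice(["0", "1"], size=5000),
        "b": rng.choice(["0", "1"], size=5000),
    })
    assert bic_score(DAG(("a", "b")), df, schema) > bic_score(
        DAG(("a", "b"), (("a", "b"),)), df, schema)
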