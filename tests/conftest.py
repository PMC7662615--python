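import numpy as np
import pytest

from audiobn import (
    CPT,
    DAG,
    DiscreteBayesNet,
    VariableSpec,
    canonical_dag,
    default_generating_model,
)


@pytest.fixture(scope="session")
def generating_model():
    return default_generating_model()


@pytest.fixture(scope="session")
def canonical_net(generating_model):
    """The study network with the packaged conditional grid as ground truth."""
    return generating_model.to_bayes_net()


def random_net(rng: np.random.Generator, max_vars: int = 6, max_states: int = 5) -> DiscreteBayesNet:
    """A random small net: random DAG over a random topological order, Dirichlet CPTs."""
    n_vars = int(rng.integers(2, max_vars + 1))
    names = tuple(f"v{i}" for i in range(n_vars))
    cards = {v: int(rng.integers(2, max_states + 1)) for v in names}
    order = list(names)
    rng.shuffle(order)
    edges = []
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            if rng.random() < 0.4:
                edges.append((u, v))
    dag = DAG(names, tuple(edges))
    schema = {
        v: VariableSpec(v, tuple(f"s{j}" for j in range(cards[v]))) for v in names
    }
    cpts = {}
    for v in names:
        parents = dag.parents(v)
        shape = [cards[p] for p in parents] + [cards[v]]
        table = rng.dirichlet(np.ones(cards[v]), size=int(np.prod(shape[:-1]))).reshape(shape)
        cpts[v] = CPT(v, parents, table)
    return DiscreteBayesNet(dag, cpts, schema)


def enumerate_posterior(net: DiscreteBayesNet, target: str, evidence: dict) -> np.ndarray:
    """Brute-force posterior by summing joint_probability over all assignments."""
    from itertools import product

    free = [v for v in net.dag.nodes if v not in evidence]
    post = np.zeros(net.schema[target].cardinality)
    for combo in product(*[net.schema[v].states for v in free]):
        assignment = dict(evidence)
        assignment.update(zip(free, combo))
        post[net.schema[target].index(assignment[target])] += net.joint_probability(assignment)
    total = post.sum()
    assert total > 0, "evidence impossible under the net"
    return post / total
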