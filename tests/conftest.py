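import numpy as np
import pytest

from flyvis.io_fixtures import builtin_fixture
from flyvis.synthetic_data import simulate_regimes, simulate_tree
from flyvis.trees import UltrametricTree


@pytest.fixture(scope="session")
def table1():
    return builtin_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return builtin_fixture("table2")


@pytest.fixture(scope="session")
def traits():
    return builtin_fixture("traits")


@pytest.fixture(scope="session")
def regimes():
    return builtin_fixture("regimes")


@pytest.fixture()
def balanced4():
    return UltrametricTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def tree18():
    return simulate_tree(18, seed=42)


@pytest.fixture(scope="session")
def painted_tree18(tree18):
    assignment, painting, _ = simulate_regimes(tree18, "clade_paint", seed=42)
    return tree18, assignment, painting


def random_tree(rng: np.random.Generator, n_tips: int) -> UltrametricTree:
    """Random coalescent-style ultrametric tree built without the simulator."""
    nodes = [f"T{i}" for i in range(n_tips)]
    height = {n: 0.0 for n in nodes}
    newick = {n: n for n in nodes}
    t = 0.0
    while len(nodes) > 1:
        t += float(rng.exponential(1.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        merged = f"({newick[a]}:{t - height[a]},{newick[b]}:{t - height[b]})"
        name = f"N{len(newick)}"
        nodes = [n for n in nodes if n not in (a, b)] + [name]
        newick[name] = merged
        height[name] = t
    return UltrametricTree.from_newick(newick[nodes[0]] + ";", rescale=True)
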