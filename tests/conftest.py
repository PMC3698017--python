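import numpy as np
import pytest

from netcompare import AnnotationSet, Network


@pytest.fixture
def path3():
    return Network([("a", "b"), ("b", "c")], name="path3")


@pytest.fixture
def star4():
    # K1,3: hub h with leaves x, y, z
    return Network([("h", "x"), ("h", "y"), ("h", "z")], name="star4")


@pytest.fixture
def triangle():
    return Network([("a", "b"), ("b", "c"), ("a", "c")], name="triangle")


@pytest.fixture
def cycle4():
    return Network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")], name="cycle4")


@pytest.fixture
def toy_annotation():
    return AnnotationSet({
        "T1": {"a", "b", "c"},
        "T2": {"a", "b"},
        "T3": {"c", "d"},
    }, category="BP")


def random_network(n, p, seed, name="rand"):
    """G(n, p) over string ids (helper shared by several test modules)."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    edges = [(genes[i], genes[j]) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return Network(edges, nodes=genes, name=name)
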