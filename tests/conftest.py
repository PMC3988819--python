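import pytest

import copetrend as ct


@pytest.fixture(scope="session")
def fossil_tree():
    """A mid-sized non-ultrametric tree at the study conditions."""
    return ct.simulate_tree(40, 160.0, seed=11, root_age=228.0)


@pytest.fixture(scope="session")
def small_tree():
    """Hand-sized non-ultrametric tree for exact-value checks."""
    return ct.simulate_tree(5, 100.0, seed=3, root_age=120.0)


@pytest.fixture(scope="session")
def era_map(fossil_tree):
    return ct.paint_eras(fossil_tree, [150.0], labels=["basal", "derived"])


@pytest.fixture(scope="session")
def study_dataset():
    """One full synthetic study at the default (emulated) conditions."""
    scenario = ct.SimScenario(seed=4)
    return ct.generate_dataset(scenario)


def cherry_tree(t_a=10.0, t_b=10.0, root_age=50.0):
    """Two-tip tree with pendant branch durations t_a, t_b."""
    root = ct.Node()
    root.add_child(ct.Node(label="A", length=t_a))
    root.add_child(ct.Node(label="B", length=t_b))
    return ct.CalibratedTree(root, root_age=root_age)
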