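import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from combogate.compute import GatingTreeValues, node_paths
from combogate.core_model import PanelSpec

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def panel1():
    return PanelSpec(["M1"], levels=[[0]])


@pytest.fixture
def panel2():
    return PanelSpec(["M1", "M2"], levels=[[0, 1]])


@pytest.fixture
def panel4():
    return PanelSpec(["M1", "M2", "M3", "M4"], levels=[[0, 1], [2, 3]])


@pytest.fixture
def panel6():
    return PanelSpec(
        ["M1", "M2", "M3", "M4", "M5", "M6"],
        levels=[[0, 1], [2, 3], [4, 5]],
    )


def random_tree(panel: PanelSpec, rng: np.random.Generator) -> GatingTreeValues:
    """A valid random gating tree: each sibling group is a Dirichlet draw
    scaled to sum exactly to 100."""
    tree = GatingTreeValues()
    parents = [()] + [
        p for p in node_paths(panel) if len(p) < panel.n_levels
    ]
    for parent in parents:
        n = panel.n_children(len(parent))
        values = rng.dirichlet(np.ones(n)) * 100.0
        values[-1] = 100.0 - values[:-1].sum()
        for c in range(n):
            tree[parent + (c,)] = values[c]
    return tree
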