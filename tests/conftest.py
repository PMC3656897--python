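import numpy as np
import pytest

from nrpslip import classification as cl
from nrpslip.annotation import default_profiles
from nrpslip.simulate import SimulationConfig, simulate_assembly_line

XANTHOLYSIN_SEQ = (
    "Leu", "Glu", "Gln", "Val", "Leu", "Gln", "Ser",
    "Val", "Leu", "Gln", "Leu", "Leu", "Gln", "Ile",
)
ENTOLYSIN_SEQ = (
    "Leu", "Glu", "Gln", "Val", "Leu", "Gln", "Val",
    "Leu", "Gln", "Ser", "Val", "Leu", "Ser", "Ile",
)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def packaged_panel():
    return cl.load_packaged_panel()


@pytest.fixture(scope="session")
def xtl_like_line():
    """One simulated xantholysin-architecture line (2+8+4 modules, TE tandem)
    with its ground truth, at the default 5% substitution rate."""
    return simulate_assembly_line(SimulationConfig(seed=20130517))


def random_binary_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted binary tree with uniform-random branch lengths."""
    nodes = [f"L{i}:{rng.uniform(0.05, 1.0):.6f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 1.0):.6f}")
    return nodes[0].rsplit(":", 1)[0] + ";"
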