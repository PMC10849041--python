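import numpy as np
import pytest

from striamap.morphology import Compartment, MorphNode, NeuronMorphology


def make_chain(points, radii=None, compartments=None) -> NeuronMorphology:
    """Unbranched morphology through the given points; first node is the soma."""
    points = [np.asarray(p, dtype=float) for p in points]
    n = len(points)
    radii = radii or [1.0] * n
    compartments = compartments or [Compartment.SOMA] + [Compartment.SHAFT] * (n - 1)
    nodes = [
        MorphNode(i + 1, compartments[i], points[i], radii[i], -1 if i == 0 else i)
        for i in range(n)
    ]
    return NeuronMorphology(nodes)


def make_random_tree(rng: np.random.Generator, n_nodes: int = 50) -> NeuronMorphology:
    """Random rooted shaft tree for oracle-equivalence tests."""
    nodes = [MorphNode(1, Compartment.SOMA, np.zeros(3), 5.0, -1)]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        ppos = nodes[parent - 1].position
        pos = ppos + rng.uniform(-10, 10, size=3)
        nodes.append(MorphNode(i, Compartment.SHAFT, pos, float(rng.uniform(0.3, 1.5)), parent))
    return NeuronMorphology(nodes)


@pytest.fixture
def rng():
    return np.random.default_rng(20240503)


@pytest.fixture
def straight_cable():
    """100 µm straight shaft along +x, radius 0.5 µm, soma radius 5 µm."""
    pts = [(0, 0, 0)] + [(10 * k, 0, 0) for k in range(1, 11)]
    return make_chain(pts, radii=[5.0] + [0.5] * 10)


@pytest.fixture(scope="session")
def spn_cell():
    """One full synthetic SPN (morphology + puncta + truth), reused read-only."""
    from striamap.synth import GenerationParams, generate_morphology, generate_puncta

    p = GenerationParams.for_cell_type("SPN", seed=42)
    m = generate_morphology(p)
    puncta, gt = generate_puncta(m, p)
    return p, m, puncta, gt


@pytest.fixture(scope="session")
def fsi_cell():
    from striamap.synth import GenerationParams, generate_morphology, generate_puncta

    p = GenerationParams.for_cell_type("FSI", seed=43)
    m = generate_morphology(p)
    puncta, gt = generate_puncta(m, p)
    return p, m, puncta, gt
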