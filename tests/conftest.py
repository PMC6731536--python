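import numpy as np
import pytest

from dlint1.morph_io import MorphNode, MorphTree
from dlint1.synthetic_data import MorphGenParams, gen_morph_population


def chain_tree(positions, radii=None, **labels) -> MorphTree:
    """Unbranched chain through the given 3D positions."""
    radii = radii or [1.0] * len(positions)
    nodes = [MorphNode(1, -1, tuple(map(float, positions[0])), radii[0])]
    for i, (p, r) in enumerate(zip(positions[1:], radii[1:]), start=2):
        nodes.append(MorphNode(i, i - 1, tuple(map(float, p)), r))
    return MorphTree(nodes, **labels)


def binary_tree(depth: int, edge: float = 10.0) -> MorphTree:
    """Perfect binary tree: each level splits along +/-y, advancing in x."""
    nodes = [MorphNode(1, -1, (0.0, 0.0, 0.0), 1.0)]
    next_id = 2
    level = [(1, 0.0)]
    for d in range(1, depth + 1):
        new_level = []
        for parent, y in level:
            for sign in (1.0, -1.0):
                ny = y + sign * edge / (2.0**d)
                nodes.append(MorphNode(next_id, parent, (d * edge, ny, 0.0), 1.0))
                new_level.append((next_id, ny))
                next_id += 1
        level = new_level
    return MorphTree(nodes)


@pytest.fixture(scope="session")
def random_trees():
    """A batch of varied synthetic whole-arborization trees (session-cached)."""
    params = MorphGenParams(n_per_group=5, n_regparam=1, min_nodes=200)
    trees = []
    for seed in (11, 12):
        pop, _ = gen_morph_population(params, seed=seed)
        trees.extend(s.WA for s in pop)
    return trees


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
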