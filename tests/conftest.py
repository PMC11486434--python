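import numpy as np
import pytest

from fetovasc import geometry, trees


@pytest.fixture(scope="session")
def small_placentone():
    """Healthy-geometry placentone domain (Table-scale inputs)."""
    return geometry.build_placentone(390.0, 24.0, 65, 1.88, 5.6)


@pytest.fixture(scope="session")
def small_shape():
    return geometry.PlacentalShapeParams(V=450.0, r_maj=9.3, E=0.49, CCI=0.36)


@pytest.fixture(scope="session")
def coarse_surface(small_shape):
    """Low-seed-density spheroid mesh: fast enough for unit tests."""
    return geometry.build_placental_surface(small_shape, target_seed_density=0.5)


@pytest.fixture(scope="session")
def coarse_plate(small_shape, coarse_surface):
    a = geometry.chorionic_area(small_shape.r_maj, small_shape.r_min,
                                small_shape.t_half)
    return geometry.extract_chorionic_plate(coarse_surface, a)


def random_tree(rng: np.random.Generator, n_nodes: int) -> trees.VascularTree:
    """Random bifurcating forest for oracle comparisons."""
    builder = trees.TreeBuilder()
    builder.add_node(rng.normal(size=3))
    child_count = {0: 0}
    diam = {0: 4.0}
    for _ in range(n_nodes - 1):
        eligible = [i for i, c in child_count.items() if c < 2 and i in diam]
        parent = int(rng.choice(eligible))
        d = diam[parent] * rng.uniform(0.6, 0.95)
        node = builder.add_node(rng.normal(size=3), parent=parent, diameter=d,
                                generation=0, label="villous")
        child_count[parent] += 1
        child_count[node] = 0
        diam[node] = d
    return builder.build()
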