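import numpy as np
import pytest

from tlsmorph import TreeParams, make_tree


@pytest.fixture(scope="session")
def standard_tree():
    """Dense noiseless reference tree: 8 m tall, crown base 3 m, DBH 0.2 m."""
    params = TreeParams(
        height=8.0, crown_base=3.0, dbh=0.2, crown_semi_axes=(2.0, 2.0, 2.5),
        trunk_point_spacing=0.02, leaf_point_count=20000, seed=1,
    )
    cloud, truth = make_tree(params)
    return params, cloud, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def circle_points(cx, cy, r, n=100, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([cx + r * np.cos(angles), cy + r * np.sin(angles)])
    if noise > 0:
        pts += rng.normal(scale=noise, size=pts.shape)
    return pts
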