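import numpy as np
import pandas as pd
import pytest

import standassoc as sa


@pytest.fixture(scope="session")
def geometry():
    """The reference survey design: 140 x 70 m, 14 m quadrats, 5 m buffer."""
    return sa.PlotGeometry(width=140.0, height=70.0, quadrat_size=14.0, buffer_width=5.0)


@pytest.fixture(scope="session")
def grid(geometry):
    return sa.build_quadrat_grid(geometry)


@pytest.fixture
def small_geometry():
    """A 2 x 2 quadrat plot for hand-checkable examples."""
    return sa.PlotGeometry(width=28.0, height=28.0, quadrat_size=14.0, buffer_width=5.0)


def make_stemmap(rows, geometry):
    """Build a StemMap from (tree_id, species, x, y, dbh) tuples."""
    df = pd.DataFrame(rows, columns=["tree_id", "species", "x", "y", "dbh"])
    return sa.StemMap(trees=df, geometry=geometry)


@pytest.fixture
def toy_two_species(small_geometry):
    """3 + 1 trees of equal DBH in disjoint quadrats: every relative measure
    should split 75 / 25 between the two species."""
    rows = [
        ("a1", "A", 1.0, 1.0, 20.0),
        ("a2", "A", 15.0, 1.0, 20.0),
        ("a3", "A", 1.0, 15.0, 20.0),
        ("b1", "B", 15.0, 15.0, 20.0),
    ]
    return make_stemmap(rows, small_geometry)


@pytest.fixture(scope="session")
def default_stand():
    """One realisation of the default synthetic community (seeded)."""
    return sa.simulate_community(sa.default_community_spec(seed=42))


@pytest.fixture(scope="session")
def default_stemmap(default_stand):
    return default_stand[0]
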