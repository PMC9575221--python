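import numpy as np
import pandas as pd
import pytest

from spatialcci.lr_database import LRDatabase, LRInteraction
from spatialcci.tendency import SpatialExpression


@pytest.fixture
def square_slide() -> SpatialExpression:
    """Four spots at unit-square corners with two genes."""
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    values = np.array(
        [
            [2.0, 2.0, 0.0, 0.0],  # geneA on the bottom edge
            [0.0, 0.0, 1.0, 3.0],  # geneB on the top edge
        ]
    )
    return SpatialExpression(
        gene_ids=["geneA", "geneB"],
        spot_ids=["s1", "s2", "s3", "s4"],
        coords=coords,
        values=values,
    )


@pytest.fixture
def simple_db() -> LRDatabase:
    return LRDatabase(
        interactions=[
            LRInteraction("A_B", ("geneA",), ("geneB",)),
        ]
    )


@pytest.fixture
def proportions() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "Bcell": [0.6, 0.5, 0.0],
            "Tcell": [0.3, 0.5, 0.2],
            "tumor": [0.1, 0.0, 0.8],
        },
        index=["s1", "s2", "s3"],
    )


def random_weighted_points(rng, max_points=25, scale=1.0):
    from spatialcci.transport import WeightedPoints

    k = int(rng.integers(2, max_points + 1))
    return WeightedPoints(
        coords=rng.uniform(0, scale, size=(k, 2)),
        weights=rng.dirichlet(np.ones(k)),
    )
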