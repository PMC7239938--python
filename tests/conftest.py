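import numpy as np
import pandas as pd
import pytest

import microvar as mv


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort shared by read-only tests."""
    cfg = mv.CohortConfig(
        n_hosts=30, n_taxa=60, n_core_taxa=10,
        depth_range=(2_000, 5_000), seed=7,
    )
    return mv.simulate_cohort(cfg)


@pytest.fixture
def toy_table():
    """3 samples x 4 taxa with a simple two-family taxonomy."""
    counts = pd.DataFrame(
        [[10, 20, 70, 0], [5, 5, 90, 0], [1, 2, 3, 4]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    taxonomy = pd.Series(
        {
            "t1": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus",
            "t2": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Lactococcus",
            "t3": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Blautia",
            "t4": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Roseburia",
        },
        name="lineage",
    )
    return mv.FeatureTable(counts, taxonomy)


def euclidean_dm(points, ids=None):
    from scipy.spatial.distance import pdist, squareform
    from skbio.stats.distance import DistanceMatrix

    points = np.asarray(points, dtype=float)
    if ids is None:
        ids = [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)
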