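import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def four_tip_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — the workhorse for hand-checked UniFrac."""
    from io import StringIO

    from skbio import TreeNode

    return TreeNode.read(StringIO("((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture(scope="session")
def small_community():
    """One deterministic synthetic community shared across tests."""
    from saltscan import SyntheticSpec, simulate_community

    spec = SyntheticSpec(
        n_taxa=40,
        n_transitions=2,
        transition_divergences=(0.02, 0.15),
        n_marine_samples=6,
        n_freshwater_samples=6,
        library_size_range=(2000, 4000),
        seed=11,
    )
    return simulate_community(spec)


@pytest.fixture()
def toy_counts():
    counts = pd.DataFrame(
        {
            "M01": [10, 0, 3, 0],
            "M02": [5, 0, 0, 1],
            "F01": [0, 7, 2, 0],
            "F02": [0, 4, 0, 0],
        },
        index=["t1", "t2", "t3", "t4"],
    )
    metadata = pd.DataFrame(
        {
            "sample_id": ["M01", "M02", "F01", "F02"],
            "habitat": ["marine", "marine", "freshwater", "freshwater"],
            "site": ["sm1", "sm2", "sf1", "sf2"],
            "depth_class": ["surface", "deep", "surface", "deep"],
        }
    )
    return counts, metadata
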