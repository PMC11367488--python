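import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from cytotype.events import EventTable
from cytotype.reference import ReferenceMatrix
from cytotype.synthetic import SimSpec, dominant_marker_reference, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=25,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blob_events():
    """Three well-separated Gaussian blobs (sigma=0.1, centers 5 sigma apart)
    over two markers, 200 events each, with planted truth labels."""
    rng = np.random.default_rng(11)
    centers = np.array([[0.0, 0.0], [0.5, 0.0], [0.0, 0.5]])
    X = np.vstack([rng.normal(c, 0.1, size=(200, 2)) for c in centers])
    truth = np.repeat(["blobA", "blobB", "blobC"], 200)
    return EventTable(
        intensities=X - X.min() + 0.1,
        markers=["mx", "my"],
        sample_id=np.repeat("s1", 600),
        obs=pd.DataFrame({"true_label": truth}),
    )


@pytest.fixture(scope="session")
def four_type_reference():
    """Four cell types, each high on exactly one of four markers."""
    return dominant_marker_reference(4)


@pytest.fixture(scope="session")
def four_type_events(four_type_reference):
    """One simulated sample: 4 planted types x ~1000 cells, default noise."""
    spec = SimSpec.single_sample(
        four_type_reference, [0.25, 0.25, 0.25, 0.25], 4000, seed=42
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def wide_reference():
    """Nine types x 13 markers with well-separated random profiles."""
    rng = np.random.default_rng(7)
    vals = rng.uniform(0, 1, size=(9, 13))
    vals = (vals - vals.min(0)) / (vals.max(0) - vals.min(0))
    return ReferenceMatrix(
        pd.DataFrame(
            vals,
            index=[f"type{i}" for i in range(9)],
            columns=[f"M{j}" for j in range(13)],
        )
    )
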