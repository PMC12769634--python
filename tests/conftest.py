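import numpy as np
import pytest

import hepafroc as hf


@pytest.fixture(scope="session")
def toy_gts():
    """Two cases, three lesions, hand-placed."""
    return [
        hf.GroundTruthLesion("c1", "c1_L01", np.array([50.0, 50.0, 30.0]), 8.0, "cyst"),
        hf.GroundTruthLesion("c1", "c1_L02", np.array([90.0, 60.0, 45.0]), 4.1, "metastasis"),
        hf.GroundTruthLesion("c2", "c2_L01", np.array([60.0, 70.0, 36.0]), 20.0, "hemangioma"),
    ]


@pytest.fixture(scope="session")
def full_bundle():
    """Default 14-reader, 30-case simulated study (shared; treat as read-only)."""
    return hf.simulate_study(seed=1)


@pytest.fixture(scope="session")
def full_matched(full_bundle):
    return hf.match_marks(
        full_bundle.marks, full_bundle.ground_truth,
        case_ids=full_bundle.design.case_ids,
    )
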