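import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import capsbench as cb
from capsbench.caps import ReferenceModel

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy_model():
    """Two contexts with hand-chosen singleton proportions 0.4 and 0.6."""
    return ReferenceModel.from_counts({"ACA>G": (10, 4), "CTG>A": (10, 6)})


def toy_group(n1, s1, n2, s2):
    """A group table with n/singleton counts in the two toy contexts."""
    return pd.DataFrame(
        {
            "context_label": ["ACA>G"] * n1 + ["CTG>A"] * n2,
            "is_singleton": [True] * s1 + [False] * (n1 - s1)
            + [True] * s2 + [False] * (n2 - s2),
        }
    )


@pytest.fixture(scope="session")
def cohort():
    """A medium synthetic cohort shared across analysis tests."""
    params = cb.SyntheticParams(n_variants=20_000, n_reference=60_000, seed=7)
    data = cb.generate_cohort(params)
    reference = cb.qc_filter(data.reference)
    model = ReferenceModel.from_table(reference, provenance="synthetic neutral reference")
    study = cb.qc_filter(data.study)
    return {
        "params": params,
        "reference": reference,
        "study": study,
        "truth": data.truth,
        "model": model,
        "registry": params.tool_registry(),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
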