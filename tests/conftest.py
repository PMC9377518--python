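import numpy as np
import pytest
from hypothesis import settings

import fcmvpa as f

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas():
    return f.build_default_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """16-subject, 20-region cohort with a strong planted 5-region clique effect."""
    spec = f.CohortSpec(
        n_per_group=8,
        n_regions=20,
        n_timepoints=60,
        rho_in=0.3,
        rho_out=0.1,
        effect_edges=tuple(f.edges_among(range(5), 20)),
        effect_delta=0.4,
        seed=3,
    )
    series, records = f.sample_cohort(spec)
    x = f.cohort_edge_matrix(series)
    groups = np.array([r.group for r in records])
    return {
        "spec": spec,
        "series": series,
        "records": records,
        "x": x,
        "groups": groups,
        "y": f.encode_labels(groups),
    }


@pytest.fixture(scope="session")
def null_cohort():
    """12-subject, 10-region cohort with no group difference."""
    spec = f.CohortSpec(n_per_group=6, n_regions=10, n_timepoints=50, seed=11)
    series, records = f.sample_cohort(spec)
    x = f.cohort_edge_matrix(series)
    groups = np.array([r.group for r in records])
    return {"x": x, "groups": groups, "y": f.encode_labels(groups)}
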