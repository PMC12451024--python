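import numpy as np
import pytest

from hubnet import CohortConfig, calibrate_hub_loading, generate_cohort


@pytest.fixture(scope="session")
def hub_loading():
    """Hub FA loading calibrated once to the planted partial r of 0.56."""
    return calibrate_hub_loading(0.56, CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_cohort(hub_loading):
    """One default synthetic cohort (37 good / 28 poor, planted hub)."""
    cfg = CohortConfig(seed=1, hub_loading=hub_loading)
    connectomes, records = generate_cohort(cfg)
    return cfg, connectomes, records


def make_connectome(subject_id, fa_pairs, n_regions, count=10):
    """Toy connectome from {(i, j): fa} upper-triangle entries."""
    from hubnet import SubjectConnectome

    cm = np.zeros((n_regions, n_regions), dtype=int)
    fm = np.zeros((n_regions, n_regions))
    for (i, j), fa in fa_pairs.items():
        cm[i, j] = cm[j, i] = count if fa > 0 else 0
        fm[i, j] = fm[j, i] = fa
    return SubjectConnectome(subject_id, cm, fm)
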