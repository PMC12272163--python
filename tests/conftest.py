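import numpy as np
import pandas as pd
import pytest

import nervemorph as nm


@pytest.fixture(scope="session")
def small_cfg() -> nm.CohortConfig:
    """A reduced cohort (12 participants, ~120 fibres each) for fast tests."""
    return nm.CohortConfig(
        n_participants=12,
        fibre_count_logmean=float(np.log(120.0)),
        fibre_count_logsd=0.3,
        fibre_count_min=50,
        fibre_count_max=400,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    participants, fibres = nm.sample_cohort_fibres(small_cfg)
    return participants, fibres


@pytest.fixture(scope="session")
def small_metrics(small_cohort):
    """Validity-filtered per-fibre metrics for the small cohort."""
    _, fibres = small_cohort
    metrics = nm.fibre_metrics_table(nm.fibres_to_area_table(fibres))
    kept, _ = nm.validity_filter(metrics)
    return kept


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (shared across the expensive tests)."""
    cfg = nm.CohortConfig(seed=11)
    participants, fibres = nm.sample_cohort_fibres(cfg)
    kept, _ = nm.validity_filter(
        nm.fibre_metrics_table(nm.fibres_to_area_table(fibres)))
    return cfg, participants, kept


@pytest.fixture()
def three_fibre_section():
    """A rendered section with three well-separated fibres + ground truth."""
    fib = pd.DataFrame({
        "participant_id": "P1",
        "axon_diameter_um": [4.0, 2.0, 6.0],
        "myelin_thickness_um": [1.0, 0.7, 1.5],
    })
    section, placed = nm.render_section(
        fib, pixel_size_um=0.05, field_um=(40.0, 40.0),
        rng=np.random.default_rng(0))
    return section, placed
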