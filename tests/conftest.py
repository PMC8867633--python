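import numpy as np
import pandas as pd
import pytest

import qitrend as q


@pytest.fixture(scope="session")
def small_panel():
    """Moderate synthetic panel: 4 regions (2 controls), 4 years."""
    cfg = q.ScenarioConfig(
        subjects_per_region=80, reference_subjects=150, n_controls=2, T=3, seed=4
    )
    panel, truth = q.generate_panel(cfg)
    return panel, truth


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """Covariate-adjusted outcome fit on the small panel."""
    panel, _ = small_panel
    design = q.build_design(panel)
    fit = q.fit_outcome_model(panel, design)
    return panel, fit


@pytest.fixture()
def toy_records():
    """Three handwritten subject-year records."""
    return pd.DataFrame(
        {
            "subject_id": ["a", "a", "b"],
            "t": [0, 1, 0],
            "region": ["KT", "KT", "C1"],
            "outcome": [0, 1, 1],
            "age": [60.0, 61.0, 55.0],
            "gender": [1, 1, 0],
            "comorbidity_entry": [2, 2, 0],
            "gisd": [5.0, 5.0, 6.0],
            "in_reference_sample": [False, False, False],
            "family_contract": [False, False, False],
            "practice_id": ["p1", "p1", "p2"],
        }
    )


@pytest.fixture()
def toy_registry():
    return q.RegionRegistry("KT", ("C1", "C2"), "BW")


@pytest.fixture()
def toy_indicator():
    return q.IndicatorDefinition(id="toy", direction="increase", t_min=0, T=3)
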