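import numpy as np
import pandas as pd
import pytest

import sphingoquant as sq


@pytest.fixture(scope="session")
def panel():
    return sq.generate_panel()


@pytest.fixture(scope="session")
def panel_names(panel):
    return panel["name"].tolist()


@pytest.fixture(scope="session")
def small_cohort():
    """40/40-sample cohort with the default effect map, fixed seed."""
    cfg = sq.GeneratorConfig(seed=11, n_per_group=40)
    table, truth = sq.generate_cohort(cfg)
    return table, truth


@pytest.fixture(scope="session")
def clean_run():
    """Noise-free, drift-free injection run of a tiny cohort."""
    cfg = sq.GeneratorConfig(
        seed=5, n_per_group=10, noise_cv=0.0, drift_amplitude=0.0, mz_jitter=0.0, rt_jitter=0.0
    )
    table, _ = sq.generate_cohort(cfg)
    peaks, sequence, library, truth = sq.generate_injection_run(table, cfg)
    return table, peaks, sequence, library, truth
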