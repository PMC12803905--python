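import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cardioresp.classify import build_trial_table
from cardioresp.signals import RRISeries
from cardioresp.synthetic import GeneratorConfig, simulate_cohort, simulate_subject

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="Random effects covariance is singular")
warnings.filterwarnings("ignore", message=".*covariance of random effects.*")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def one_subject(default_config):
    """One label-level subject (no waveforms) of the default cohort."""
    return simulate_subject(default_config, 1, default_config.subject_seeds()[0],
                            render_signals=False)


@pytest.fixture(scope="session")
def rendered_subject(default_config):
    """One fully rendered subject (flow + ECG waveforms at 1 kHz)."""
    return simulate_subject(default_config, 1, default_config.subject_seeds()[0],
                            render_signals=True)


@pytest.fixture(scope="session")
def cohort_trials() -> pd.DataFrame:
    """Classified trial table of a 12-subject label-level cohort."""
    cfg = GeneratorConfig(n_subjects=12, seed=23)
    parts = []
    for data in simulate_cohort(cfg, render_signals=False):
        tdf, _ = build_trial_table(data.subject, data.events, data.phases,
                                   RRISeries(data.r_times))
        parts.append(tdf)
    return pd.concat(parts, ignore_index=True)
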