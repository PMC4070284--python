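import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mdrecovery import (NoiseMovieSpec, build_grating_protocol,
                        sample_population, simulate_population_trials,
                        synthesize_noise_movie)

settings.register_profile("repro", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def short_movie():
    """20-s band-limited noise movie (two contrast cycles)."""
    return synthesize_noise_movie(NoiseMovieSpec(duration_s=20.0, seed=7))


@pytest.fixture(scope="session")
def protocol():
    """Standard 6-repeat grating protocol, both eyes."""
    return build_grating_protocol(repeats=6, seed=3)


@pytest.fixture(scope="session")
def small_trials(protocol):
    """Simulated grating trials for a small non-deprived population."""
    units = sample_population(8, "non-deprived", seed=21)
    return units, simulate_population_trials(units, protocol, seed=22)


@pytest.fixture()
def toy_trials():
    """Hand-built trial table with known rates for arithmetic checks."""
    rows = []
    # three blank trials with 3 spikes each over 1.5 s -> spont = 2.0 sp/s
    for i in range(3):
        rows.append(dict(unit_id=0, eye="contra", direction_deg=0.0,
                         sf_cpd=0.0, is_blank=True, trial_index=i,
                         spike_count=3, duration_s=1.5))
    # condition trials at 15 spikes / 1.5 s = 10 sp/s
    for i in range(3):
        rows.append(dict(unit_id=0, eye="contra", direction_deg=90.0,
                         sf_cpd=0.04, is_blank=False, trial_index=3 + i,
                         spike_count=15, duration_s=1.5))
    return pd.DataFrame(rows)
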