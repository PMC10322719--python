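import numpy as np
import pytest

from patchpop.features import extract_feature_table
from patchpop.simulate import (ARCHETYPES, PopulationDesign, ProtocolSpec,
                               archetype, simulate_population,
                               simulate_sweep_set)

#: trimmed protocol for bulk simulations in tests (coarser ladder, fewer tau
#: repeats, shorter spontaneous trace) — features stay well defined
FAST_PROTOCOL = ProtocolSpec(sampling_rate_hz=10_000.0,
                             ladder_pa=tuple(range(40, 321, 40)),
                             tau_n_repeats=3, spontaneous_duration_s=5.0)


@pytest.fixture(scope="session")
def small_cohort():
    """10 neurons per archetype with the trimmed protocol, plus labels."""
    rng = np.random.default_rng(7)
    sets, labels = [], []
    for name in ARCHETYPES:
        for _ in range(10):
            sets.append(simulate_sweep_set(archetype(name), FAST_PROTOCOL,
                                           seed=int(rng.integers(2**31))))
            labels.append(name)
    return sets, labels


@pytest.fixture(scope="session")
def small_features(small_cohort):
    sets, labels = small_cohort
    return extract_feature_table(sets, labels=labels)


@pytest.fixture(scope="session")
def task_dataset():
    """Scaled-down four-block task recording: 30 units, 5/10/5/5 trials."""
    gains = np.ones((30, 4))
    gains[:10, 1] = np.exp(0.8)   # opto-tuned third
    gains[10:20, 3] = np.exp(0.9)  # air-puff-tuned third
    design = PopulationDesign(n_units=30, block_trials=(5, 10, 5, 5),
                              trial_length_s=4.0, pre_s=2.0, baseline_hz=6.0,
                              gains=gains, seed=11)
    return simulate_population(design)
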