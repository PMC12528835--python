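import numpy as np
import pytest

from svdecode import (PreferenceParams, build_choice_set,
                      label_by_median_split, subjective_value)
from svdecode.atlas import make_atlas
from svdecode.synth import SignalSpec, simulate_beta_series, simulate_choices


@pytest.fixture(scope="session")
def schedule():
    return build_choice_set(n_runs=4, seed=7)


@pytest.fixture(scope="session")
def params():
    """A moderately risk- and ambiguity-averse, fairly consistent agent."""
    return PreferenceParams(alpha=0.6, beta=0.5, gamma=-2.0)


@pytest.fixture(scope="session")
def choices(schedule, params):
    return simulate_choices(schedule, params, missing_rate=0.0, seed=11)


@pytest.fixture(scope="session")
def small_atlas():
    """One ROI per network, small voxel counts — decoding test scale."""
    return make_atlas({n: 1 for n in
                       ("visual", "somatomotor", "dorsal-attention",
                        "salience/ventral-attention", "limbic", "control",
                        "default", "subcortical")},
                      voxels_per_roi=(12, 18), seed=3)


@pytest.fixture(scope="session")
def sv_labels(schedule, params):
    sv = np.atleast_1d(subjective_value(
        schedule.win_probs, schedule.ambiguities, schedule.lottery_values,
        params.alpha, params.beta))
    return label_by_median_split(sv, schedule.run_ids, schedule.contexts,
                                 split_kind="overall", seed=5)


@pytest.fixture(scope="session")
def strong_beta(schedule, params, small_atlas):
    """High-amplitude, low-noise patterns: decodable well above chance."""
    sig = SignalSpec(atlas=small_atlas, amplitude_per_roi=5.0, noise_sd=0.5,
                     voxel_weight_seed=21)
    return simulate_beta_series(schedule, params, sig, seed=13)


@pytest.fixture(scope="session")
def noise_beta(schedule, params, small_atlas):
    """Signal-free patterns: pure noise."""
    sig = SignalSpec(atlas=small_atlas, amplitude_per_roi=0.0, noise_sd=1.0,
                     voxel_weight_seed=21)
    return simulate_beta_series(schedule, params, sig, seed=17)
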