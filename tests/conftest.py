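import numpy as np
import pytest

from vburrow.core import DetectionConfig, Epoch, TrialRecord


@pytest.fixture
def cfg():
    return DetectionConfig()


def make_trial(rel_position, sample_rate=1000.0, baseline=1.0, stim=8.0,
               post=4.0, trial_index=1, stimulus_id=1):
    """TrialRecord from an already re-baselined position array.

    The array is assumed to start at baseline.start = 0 with the stimulus
    at t = baseline; it is padded with zeros to the full trial extent.
    """
    rel = np.asarray(rel_position, dtype=float)
    n_needed = int(round((baseline + stim + post) * sample_rate))
    if len(rel) < n_needed:
        rel = np.concatenate([rel, np.zeros(n_needed - len(rel))])
    return TrialRecord(
        trial_index=trial_index, stimulus_id=stimulus_id,
        baseline=Epoch(0.0, baseline),
        stim=Epoch(baseline, baseline + stim),
        post=Epoch(baseline + stim, baseline + stim + post),
        rel_position=rel[:n_needed], sample_rate=sample_rate,
    )


@pytest.fixture
def trial_factory():
    return make_trial
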