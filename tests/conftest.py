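"""Shared fixtures: tiny schedules, simulated epoch sets, reference pulses."""

import numpy as np
import pandas as pd
import pytest

from laterp.containers import EpochSet
from laterp.design import TrialCounts, generate_design
from laterp.synth import MINIMAL_CHANNELS, ComponentParams, GroundTruth, simulate_epochs

EPOCH_TIMES = -100.0 + 2.0 * np.arange(301)  # 500 Hz, -100..500 ms


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_schedule():
    """Two blocks with the study's per-block composition."""
    return generate_design(n_blocks=2, seed=11)


def make_epochs(data, channels=("PO7", "PO8", "HEOG", "VEOG"), trials=None,
                times=EPOCH_TIMES, sfreq=500.0):
    data = np.asarray(data, dtype=float)
    if trials is None:
        trials = pd.DataFrame(index=range(data.shape[0]))
    return EpochSet(data=data, channels=list(channels), times=times[: data.shape[2]],
                    sfreq=sfreq, trials=trials)


@pytest.fixture
def noiseless_left_trial():
    """One correct left-item Exemplar Match trial with a -2 uV pulse at 200-300 ms."""
    schedule = pd.DataFrame(
        [{"participant": "P01", "block": 1, "trial": 1, "trial_type": "exemplar_match",
          "item_side": "left", "pattern_side": "left", "symbol_position": "patterned",
          "symbol_count": 3, "response": "present", "correct": True, "rt_ms": 500.0}]
    )
    truth = GroundTruth(
        conditions={
            c: ComponentParams(amplitude_uv=-2.0, onset_ms=200.0, width_ms=100.0,
                               noise_sd_uv=0.0)
            for c in (("patterned", "exemplar_match"), ("random", "exemplar_match"),
                      ("patterned", "foil"), ("random", "foil"))
        },
        absent=ComponentParams(amplitude_uv=0.0, noise_sd_uv=0.0),
    )
    return simulate_epochs(schedule, truth, seed=0, channels=MINIMAL_CHANNELS)


def exemplar_only_schedule(n_blocks=1, seed=0, pattern_side="left"):
    """All-correct Exemplar Match trials only (the lateralized analysis set)."""
    sch = generate_design(n_blocks=n_blocks, counts=TrialCounts(28, 28, 0),
                          seed=seed, pattern_side=pattern_side)
    sch = sch[sch.trial_type == "exemplar_match"].reset_index(drop=True)
    sch["correct"] = True
    sch["response"] = "present"
    return sch
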