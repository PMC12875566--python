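import numpy as np
import pytest

from mostrip.synthetic_data import (
    Condition,
    SimulationParams,
    generate_trial,
    schedule_for_condition,
)


@pytest.fixture(scope="session")
def noise_free_params():
    return SimulationParams(marker_noise_sd=0.0)


@pytest.fixture(scope="session")
def perturbed_trial(noise_free_params):
    """One noise-free perturbed trial with exact ground truth."""
    cond = Condition("slow", "random", "buzzer")
    sched = schedule_for_condition(cond, noise_free_params.steps_per_trial, seed=3)
    rec, truth = generate_trial(
        noise_free_params, cond, sched, participant_risk=23.6, seed=5
    )
    return cond, sched, rec, truth


@pytest.fixture(scope="session")
def unperturbed_trial(noise_free_params):
    cond = Condition("slow", "none", "none")
    sched = schedule_for_condition(cond, noise_free_params.steps_per_trial, seed=1)
    rec, truth = generate_trial(
        noise_free_params, cond, sched, participant_risk=23.6, seed=11
    )
    return cond, sched, rec, truth


def match_events(truth_events, detected):
    """Per-ground-truth-event distance to the nearest detected event."""
    det = {}
    for ev in detected:
        det.setdefault((ev.kind, ev.side), []).append(ev.frame)
    dists = []
    for row in truth_events.itertuples():
        frames = np.asarray(det.get((row.kind, row.side), [np.inf]))
        dists.append(np.abs(frames - row.frame).min())
    return np.asarray(dists)
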