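import pytest

from tactile_decoding.decoder import DecoderParams, derive_windows
from tactile_decoding.synthetic import (NeuronModelSpec, generate_sweeps,
                                        make_schedule)

LABELS8 = [f"P{i}" for i in range(1, 9)]


@pytest.fixture(scope="session")
def labels8():
    return list(LABELS8)


@pytest.fixture(scope="session")
def small_params():
    """Reduced-scale decoder constants for fast unit tests (the full-scale
    constants are exercised in the acceptance suite)."""
    return DecoderParams(group_size=5, target_combinations=60,
                         n_iterations=6, seed=11)


def make_selective_sweepset(seed=0, repetitions=24, reliability=0.9,
                            separation=45.0, baseline=5.0):
    """One pattern-selective neuron: a single Gaussian response bump per
    pattern whose latency steps by `separation` ms across patterns."""
    resp = {lab: [(30.0 + separation * i, 70.0, 6.0)]
            for i, lab in enumerate(LABELS8)}
    spec = NeuronModelSpec(baseline, resp, reliability)
    sched = make_schedule(LABELS8, repetitions_per_pattern=repetitions,
                          seed=seed)
    return generate_sweeps(spec, sched, seed=1000 + seed)


@pytest.fixture(scope="session")
def selective_sweepset():
    return make_selective_sweepset()


@pytest.fixture(scope="session")
def selective_windows(selective_sweepset):
    return derive_windows(selective_sweepset)


@pytest.fixture(scope="session")
def flat_sweepset():
    """A neuron whose response statistics are identical for all patterns
    (same bump everywhere): the decoder should sit at chance."""
    resp = {lab: [(100.0, 50.0, 10.0)] for lab in LABELS8}
    spec = NeuronModelSpec(5.0, resp, 1.0)
    sched = make_schedule(LABELS8, repetitions_per_pattern=24, seed=3)
    return generate_sweeps(spec, sched, seed=33)
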