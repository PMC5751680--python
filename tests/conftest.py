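import numpy as np
import pytest

from sealrhythm.synth import Fixed, SyntheticSpec, emit_fixture

# 8 kHz keeps fixture rendering fast; the analysis is rate-agnostic
FAST_RATE = 8000.0


@pytest.fixture(scope="session")
def degenerate_fixture(tmp_path_factory):
    """One bout of three identical calls: IOI 2000 ms, duration 1000 ms,
    envelope peak at 30% of the call. Every derived quantity is known
    exactly."""
    spec = SyntheticSpec(
        n_bouts=1,
        calls_per_bout=3,
        within_ioi=Fixed(2000.0),
        duration=Fixed(1000.0),
        peak_rel_pos=0.3,
        rate=FAST_RATE,
        seed=7,
    )
    out = tmp_path_factory.mktemp("degenerate")
    paths = emit_fixture(spec, out)
    return spec, paths


@pytest.fixture(scope="session")
def stochastic_fixture(tmp_path_factory):
    """A small bout-structured recording with default distributions."""
    spec = SyntheticSpec(n_bouts=6, calls_per_bout=4, rate=FAST_RATE, seed=11)
    out = tmp_path_factory.mktemp("stochastic")
    paths = emit_fixture(spec, out)
    return spec, paths


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
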