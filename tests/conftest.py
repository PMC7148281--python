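import warnings

import pytest

from touchtrace import state_table, synthetic, tpa_coding
from touchtrace.log_io import Action, TouchEvent, TouchLog


@pytest.fixture(scope="session")
def stim_aois():
    return synthetic.make_stimulus(seed=0)


@pytest.fixture(scope="session")
def demo_corpus(stim_aois):
    """Demo gesture script rendered at 2 px jitter, with expanded rows."""
    stim, aois = stim_aois
    script = synthetic.build_demo_script(stim)
    log, truth = synthetic.render_script(script, stim, jitter_sigma=2.0, seed=11)
    rows = state_table.expand(log)
    return stim, aois, log, truth, rows


@pytest.fixture(scope="session")
def demo_codes(demo_corpus):
    _stim, aois, _log, _truth, rows = demo_corpus
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tpa_coding.auto_code(rows, aois)


def single_digit_log():
    """DOWN at t=0, MOVE at 16, UP at 33 for input ID 0."""
    return TouchLog(
        events=[
            TouchEvent(0, 100.0, 100.0, 0, Action.DOWN),
            TouchEvent(0, 103.0, 104.0, 16, Action.MOVE),
            TouchEvent(0, 103.0, 104.0, 33, Action.UP),
        ]
    )


@pytest.fixture
def three_event_log():
    return single_digit_log()
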