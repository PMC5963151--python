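"""Shared fixtures.

Heavy simulation products (twitches, the three circulation scenarios) are
session-scoped so each is computed once per test run.
"""

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cardioem.calcium import NORMAL_TRANSIENT, apply_hf_remodeling, make_transient
from cardioem.circulation import run_scenario
from cardioem.myofilament import run_twitch


@pytest.fixture(scope="session")
def normal_params():
    return NORMAL_TRANSIENT


@pytest.fixture(scope="session")
def hf_params():
    return apply_hf_remodeling(NORMAL_TRANSIENT)


@pytest.fixture(scope="session")
def normal_ct(normal_params):
    return make_transient(normal_params, dt=1.0)


@pytest.fixture(scope="session")
def hf_ct(hf_params):
    return make_transient(hf_params, dt=1.0)


@pytest.fixture(scope="session")
def twitches(normal_ct, hf_ct):
    """The four single-cell protocols: {(condition, mode): TwitchResult}."""
    out = {}
    for name, ct in (("normal", normal_ct), ("hf", hf_ct)):
        out[(name, "isometric")] = run_twitch(ct, mode="isometric", load_kpa=1000.0)
        out[(name, "isotonic")] = run_twitch(ct, mode="isotonic", load_kpa=10.0)
    return out


@pytest.fixture(scope="session")
def scenarios():
    """The three calibrated study conditions at full length (25 cycles)."""
    return {cond: run_scenario(cond, n_cycles=25) for cond in ("normal", "hf", "hf_lvad")}


@pytest.fixture(scope="session")
def summaries(scenarios):
    from cardioem.hemodynamics import summarize_beat

    return {
        cond: summarize_beat(res.last_beat(), res.bcl_ms)
        for cond, res in scenarios.items()
    }
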