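import numpy as np
import pytest

from ticstate import report, synth


def small_config(**overrides) -> synth.ScenarioConfig:
    """Desk-scale scenario for unit tests: short blocks, one electrode."""
    cfg = synth.paper_default()
    cfg.quiet_s, cfg.transition_s, cfg.sleep_s = 120.0, 40.0, 120.0
    cfg.n_spn, cfg.n_fsi = 1, 1
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def short_session():
    """One short synthetic session (LFP rendered directly at 1 kHz)."""
    cfg = small_config()
    rng = np.random.default_rng(11)
    session, truth = synth.generate_session(cfg, rng, "short")
    return cfg, session, truth


@pytest.fixture(scope="session")
def wideband_session():
    """One short session with the 10 kHz wideband trace rendered."""
    cfg = small_config(render_wideband=True, quiet_s=90.0, transition_s=30.0,
                       sleep_s=90.0)
    rng = np.random.default_rng(12)
    session, truth = synth.generate_session(cfg, rng, "wideband")
    return cfg, session, truth


@pytest.fixture(scope="session")
def study18():
    """The full 18-session default-scenario study, analyzed end to end."""
    cfg = synth.paper_default()
    return report.run_pipeline(cfg, seed=1, include_units=False)
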