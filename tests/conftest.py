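"""Shared fixtures: calendars and synthetic panels at the study conditions."""
from __future__ import annotations

import pytest

from aqattrib.calendar_windows import CnyCalendar
from aqattrib.synthetic import SyntheticConfig, generate_city, generate_panel


@pytest.fixture(scope="session")
def calendar() -> CnyCalendar:
    return CnyCalendar()


@pytest.fixture(scope="session")
def clean_city():
    """One city, default injected effects, no noise, no across-city scatter."""
    config = SyntheticConfig(n_cities=1, noise_sd=0.0, effect_scatter=0.0, seed=11)
    return generate_city(config, 0)


@pytest.fixture(scope="session")
def recovery_panel():
    """The 50-city panel at the default study conditions (noise_sd = 0.05)."""
    config = SyntheticConfig(seed=20)
    panels, truths = generate_panel(config)
    return config, panels, truths


@pytest.fixture(scope="session")
def small_panel():
    """A 4-city panel for pipeline-level tests."""
    config = SyntheticConfig(n_cities=4, seed=7)
    panels, truths = generate_panel(config)
    return config, panels, truths
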