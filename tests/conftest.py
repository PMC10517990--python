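"""Shared fixtures: closed-form oracle curves and small synthetic inputs."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

import thermoscape as ts

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

PARABOLA_LOW = 9.9
PARABOLA_HIGH = 39.2


def parabola(t):
    """Closed-form parabola zeroed at the anchors; peak at the midpoint.

    Independent oracle for the fitted performance curve: v(T) =
    (T - low)(high - T) / 100, clipped at 0 outside the anchors.
    """
    t = np.asarray(t, dtype=float)
    v = (t - PARABOLA_LOW) * (PARABOLA_HIGH - t) / 100.0
    return np.clip(v, 0.0, None)


@pytest.fixture(scope="session")
def parabola_curve():
    """Performance curve fitted to noise-free parabola samples."""
    temps = np.arange(12.0, 38.0, 2.0)
    pts = [(t, float(parabola(t))) for t in temps]
    return ts.fit_performance_curve(pts, PARABOLA_LOW, PARABOLA_HIGH)


@pytest.fixture(scope="session")
def trait_cfg():
    return ts.TraitSimConfig(seed=11)


@pytest.fixture(scope="session")
def small_stack():
    """3-winter daily weather stack on a 6x5 grid."""
    cfg = ts.WeatherSimConfig(
        nrow=6, ncol=5, seed=7,
        start=dt.date(2001, 12, 1), end=dt.date(2004, 3, 1),
    )
    return ts.simulate_weather(cfg)


@pytest.fixture(scope="session")
def small_metrics(small_stack, parabola_curve):
    return ts.project_metrics(
        small_stack, ts.season_windows(2001, 2003), parabola_curve
    )
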