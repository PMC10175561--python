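import numpy as np
import pytest

import thermogate as tg


@pytest.fixture
def default_params():
    """A steeply heat-activated channel with T_half = 36 degC."""
    return tg.GatingModelParams.from_t_half(36.0)


def make_two_segment_profile(baseline_y=np.log(5.0), steep_intercept=59.807,
                             steep_slope=-18041.4, t_lo=25.0, t_hi=45.0,
                             step=0.25):
    """Exact piecewise-linear Arrhenius profile with a known breakpoint.

    Returns (profile, breakpoint_C): the profile equals the horizontal
    baseline on the cold side and the steep line on the hot side of the
    analytic intersection.
    """
    t_c = np.arange(t_lo, t_hi + 1e-9, step)
    x = 1.0 / (t_c + 273.15)
    y = np.maximum(baseline_y, steep_intercept + steep_slope * x)
    order = np.argsort(x)
    profile = tg.ArrheniusProfile(inv_temp_K=x[order], log_current=y[order],
                                  source_index=np.arange(len(x))[order])
    x_star = (baseline_y - steep_intercept) / steep_slope
    return profile, 1.0 / x_star - 273.15


def make_exponential_trace(a=1.0, b=18041.3, t_lo=20.0, t_hi=45.0, step=0.25,
                           i_capsaicin=None):
    """Trace whose current magnitude is a pure exponential A*exp(-B/T_K)."""
    t_c = np.arange(t_lo, t_hi + 1e-9, step)
    mag = a * np.exp(-b / (t_c + 273.15))
    return tg.TemperatureTrace(trace_id="exp", time_s=np.arange(len(t_c), dtype=float),
                               temp_C=t_c, current_nA=-mag,
                               i_capsaicin_nA=i_capsaicin)
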