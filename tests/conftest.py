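import pytest

from afcua.parameters import apply_overrides, default_parameter_set


@pytest.fixture
def params():
    return default_parameter_set()


@pytest.fixture
def zero_risk_params(params):
    """No events can occur; closed-form accrual applies."""
    return apply_overrides(
        params,
        {"p_bleed_annual_inrange": 0.0, "p_te_annual_inrange": 0.0},
    )


@pytest.fixture
def short_params(params):
    """Baseline hazards on a 90-day horizon (fast runs)."""
    return apply_overrides(params, {"horizon_days": 90})
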