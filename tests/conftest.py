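import pytest
from hypothesis import HealthCheck, settings

import tcnet as tc

settings.register_profile(
    "tcnet",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("tcnet")


@pytest.fixture
def two_state_net():
    """Clamped input X feeding Y through a plain sum combiner."""
    return tc.NetworkSpec(
        states=[
            tc.StateConfig("X", clamped=True),
            tc.StateConfig("Y", speed=1.0, combiner=tc.CombinationFunctionSpec("sum")),
        ],
        connections=[tc.Connection("X", "Y", weight=1.0)],
    )


@pytest.fixture
def clamped_pair_homophily():
    """Two clamped persons with one adaptive connection under homophily."""

    def build(v_a, v_b, w0=0.5, alpha=20.0, tau_h=0.025, eta=0.3):
        net = tc.NetworkSpec(
            states=[
                tc.StateConfig("A", clamped=True),
                tc.StateConfig("B", clamped=True),
            ],
            connections=[tc.Connection("A", "B", weight=w0, adaptive=True)],
            adaptation=[
                tc.AdaptationBlock(
                    "homophily", "all", {"alpha": alpha, "tau_h": tau_h, "eta": eta}
                )
            ],
        )
        return tc.apply_adaptation(net), {"A": v_a, "B": v_b}

    return build
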