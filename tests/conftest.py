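import numpy as np
import pytest

import vplast as vp


@pytest.fixture(scope="session")
def clamp_params() -> vp.PlasticityParams:
    """Parameter set of the linear clamp illustration (three-regime demo)."""
    return vp.PRESETS["clamp-demo-linear"]


@pytest.fixture(scope="session")
def ca3_params() -> vp.PlasticityParams:
    """Best-fit set for the hippocampal CA3 protocols."""
    return vp.PRESETS["ca3-hippocampus"]


@pytest.fixture(scope="session")
def true_params() -> vp.PlasticityParams:
    """Ground-truth parameters (inside the search bounds) for synthetic
    fitting studies."""
    return vp.PlasticityParams(
        tau_x=8.0, tau_plus=6.0, tau_minus=20.0, theta_plus=11.0, theta_0=5.0,
        A_LTP=5e-4, A_LTD=8e-4, b_theta=2e4, tau_theta=15.0)


@pytest.fixture(scope="session")
def kernels() -> vp.KernelParams:
    return vp.KernelParams()


@pytest.fixture(scope="session")
def random_protocols(clamp_params, kernels):
    """A seeded bag of 24 protocols mixing clamps, pulses and pairings,
    used by the monotonicity/veto property tests."""
    rng = np.random.default_rng(1234)
    protocols = []
    for i in range(24):
        cls = i % 3
        if cls == 0:
            protocols.append(vp.make_clamp_protocol(
                float(rng.uniform(6, 28)), int(rng.integers(3, 8)),
                float(rng.choice([2.0, 10.0, 40.0]))))
        elif cls == 1:
            T = float(np.round(rng.uniform(5, 25), 1))
            off = float(rng.choice([-10.0, T / 2, T + 10.0]))
            protocols.append(vp.make_square_pulse_protocol(
                float(rng.uniform(10, 35)), T, off))
        else:
            comps = vp.make_pairing_protocol(vp.ProtocolSpec(
                interval_ms=float(rng.choice([-10.0, 0.0, 10.0, 25.0])),
                repetitions=3,
                frequency_hz=float(rng.choice([1.0, 10.0, 20.0])),
                post_pattern=(int(rng.choice([1, 3])), 200.0)), kernels)
            protocols.append((comps[0][0], comps[0][1]))
    return protocols


@pytest.fixture(scope="session")
def voltage_curves(clamp_params):
    """Clamp-voltage scans at 2 Hz and 40 Hz (100 pulses), shared by the
    regime and frequency tests."""
    from vplast.validation import voltage_plasticity_curve
    out = {}
    for f in (2.0, 40.0):
        out[f] = voltage_plasticity_curve(clamp_params, n_pulses=100, frequency_hz=f)
    return out
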