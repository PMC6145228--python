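import numpy as np
import pytest

from tpafish import (
    CohortSpec, FilletParams, ProbeProtocol, fresh_frozen_group, iqf_group,
    simulate_cohort, simulate_curve,
)


@pytest.fixture(scope="session")
def protocol():
    return ProbeProtocol()


@pytest.fixture(scope="session")
def quiet_fillet():
    """Default fillet with the force-noise channel switched off."""
    return FilletParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def quiet_curve(protocol, quiet_fillet):
    """Noise-free simulated trace plus its exact ground truth."""
    return simulate_curve(protocol, quiet_fillet, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Small two-treatment cohort (12 IQF + 10 FF fish, 8 points each)."""
    spec = CohortSpec(groups=(iqf_group(12), fresh_frozen_group(10)), seed=42)
    return simulate_cohort(spec)


def triangular_curve(peak=100.0, rise_s=5.0, gap_s=6.0, rate=200.0,
                     protocol=None):
    """Hand-built symmetric two-cycle triangular trace.

    Each cycle rises linearly 0 -> peak over ``rise_s`` and falls back;
    displacement tracks 1 mm/s downstroke/upstroke so distances equal
    rise_s in mm.
    """
    proto = protocol or ProbeProtocol()
    dt = 1.0 / rate
    seg = int(rise_s / dt)
    gap = int(gap_s / dt)
    up = np.linspace(0.0, peak, seg + 1)
    down = up[::-1][1:]
    zeros_gap = np.zeros(gap)
    force = np.concatenate([np.zeros(gap), up, down, zeros_gap, up, down,
                            np.zeros(gap)])
    n = force.size
    t = np.arange(n) * dt
    disp = np.empty(n)
    i = 0
    for block, slope in ((gap, 1.0), (seg + 1, 1.0), (seg, -1.0),
                         (gap, 0.0), (seg + 1, 1.0), (seg, -1.0), (gap, 0.0)):
        start = disp[i - 1] if i else 0.0
        disp[i:i + block] = start + slope * dt * np.arange(1, block + 1)
        i += block
    from tpafish import ForceTimeCurve
    return ForceTimeCurve(time_s=t, force_n=force, distance_mm=disp,
                          protocol=proto)
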