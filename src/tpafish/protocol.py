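"""Acquisition protocol for a double-compression (TPA) test.

The protocol mirrors the settings of a ball-probe texture analyzer run:
the probe approaches at ``pretest_speed``, starts recording when the
force exceeds ``trigger_force``, compresses the sample to a fixed
``strain`` of its initial height at ``test_speed``, withdraws at
``posttest_speed``, pauses, and repeats the compression.
"""

from __future__ import annotations

from dataclasses import dataclass

#: grams-force per newton (1 N = 101.97 gf)
GRAMS_PER_NEWTON = 101.97


@dataclass(frozen=True)
class ProbeProtocol:
    """Instrument settings for one two-cycle compression test.

    Parameters
    ----------
    trigger_force_g:
        Contact threshold in grams-force; recording and anchor logic
        treat the upward crossing of this force as sample contact.
    strain:
        Compression depth as a fraction of initial sample height.
    pretest_speed, test_speed, posttest_speed:
        Probe speeds in mm/s for approach, compression and withdrawal.
    pause_s:
        Dwell between the two compression cycles, seconds.
    sample_rate:
        Force-channel acquisition rate, Hz.
    """

    trigger_force_g: float = 5.0
    strain: float = 0.50
    pretest_speed: float = 3.0
    test_speed: float = 1.0
    posttest_speed: float = 1.0
    pause_s: float = 5.0
    sample_rate: float = 200.0

    def __post_init__(self) -> None:
        if not (0.0 < self.strain < 1.0):
            raise ValueError(f"strain must be in (0, 1), got {self.strain}")
        if self.trigger_force_g <= 0:
            raise ValueError("trigger_force_g must be positive")
        for name in ("pretest_speed", "test_speed", "posttest_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pause_s < 0:
            raise ValueError("pause_s must be non-negative")
        if self.sample_rate < 50:
            raise ValueError("sample_rate must be at least 50 Hz")

    @property
    def trigger_force_n(self) -> float:
        """Trigger force converted to newtons."""
        return self.trigger_force_g / GRAMS_PER_NEWTON
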