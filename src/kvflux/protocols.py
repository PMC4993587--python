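"""Voltage-step protocol and current-family containers.

A family is the set of whole-cell current sweeps elicited by a series of
depolarizing voltage steps from a fixed holding potential, each followed by
a repolarizing tail segment at a common tail voltage.  The default protocol
is the one used for cerebral-artery myocyte KV recordings: holding -80 mV,
10-mV steps from -70 to +60 mV, tail at -40 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ProtocolError


@dataclass(frozen=True)
class VoltageProtocol:
    """Step/tail protocol, all values in mV and ms."""

    holding_v: float = -80.0
    step_start: float = -70.0
    step_stop: float = 60.0
    step_increment: float = 10.0
    step_duration: float = 250.0
    tail_v: float = -40.0
    tail_duration: float = 200.0
    sample_interval: float = 0.1

    def __post_init__(self):
        if not self.step_increment > 0:
            raise ProtocolError(f"step_increment must be > 0, got {self.step_increment}")
        span = self.step_stop - self.step_start
        n = span / self.step_increment
        if abs(n - round(n)) > 1e-9:
            raise ProtocolError(
                f"(step_stop - step_start) = {span} not divisible by "
                f"step_increment = {self.step_increment}"
            )
        if not self.sample_interval > 0:
            raise ProtocolError(f"sample_interval must be > 0, got {self.sample_interval}")
        if self.step_duration <= 0 or self.tail_duration < 0:
            raise ProtocolError("durations must be positive")

    @property
    def step_voltages(self) -> np.ndarray:
        n = int(round((self.step_stop - self.step_start) / self.step_increment)) + 1
        return self.step_start + self.step_increment * np.arange(n)

    @property
    def total_duration(self) -> float:
        return self.step_duration + self.tail_duration

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms; t = 0 at step onset, tail starts at
        ``step_duration``."""
        n = int(round(self.total_duration / self.sample_interval))
        return np.arange(n) * self.sample_interval

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        return cls(**d)


@dataclass
class CurrentFamily:
    """A family of current sweeps keyed by step voltage.

    ``sweeps`` is a DataFrame indexed by time (ms) with one column per step
    voltage (mV, float column labels) holding current in pA.  ``meta`` may
    carry simulator ground truth or acquisition metadata.
    """

    protocol: VoltageProtocol
    sweeps: pd.DataFrame
    capacitance: float            # pF
    cell_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sweeps.empty:
            raise ProtocolError("empty current family")
        if not self.capacitance > 0:
            raise ProtocolError(f"capacitance must be > 0 pF, got {self.capacitance}")
        want = np.asarray(self.protocol.step_voltages, dtype=float)
        have = np.asarray(sorted(float(c) for c in self.sweeps.columns))
        if want.size != have.size or not np.allclose(want, have):
            raise ProtocolError(
                f"sweep columns {have.tolist()} do not match protocol steps {want.tolist()}"
            )

    @property
    def time(self) -> np.ndarray:
        return self.sweeps.index.to_numpy(dtype=float)

    def sweep(self, step_v: float) -> pd.Series:
        for c in self.sweeps.columns:
            if abs(float(c) - step_v) < 1e-6:
                return self.sweeps[c]
        raise ProtocolError(f"no sweep at step voltage {step_v} mV")

    def step_segment(self, step_v: float) -> pd.Series:
        s = self.sweep(step_v)
        t = self.time
        return s[t < self.protocol.step_duration]

    def tail_segment(self, step_v: float) -> pd.Series:
        """Tail-segment series re-indexed to time since tail onset (ms)."""
        if self.protocol.tail_duration <= 0:
            raise ProtocolError("protocol has no tail segment")
        s = self.sweep(step_v)
        t = self.time
        seg = s[t >= self.protocol.step_duration]
        if seg.empty:
            raise ProtocolError("protocol has no tail segment")
        seg = seg.copy()
        seg.index = seg.index - self.protocol.step_duration
        return seg
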