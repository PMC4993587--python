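"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates one recording modality and stores its generating
parameters ("ground truth") under ``meta["ground_truth"]`` on the returned
object, so recovery tests can compare estimates against what was simulated.

The voltage-clamp generator uses a single-gate Hodgkin-Huxley scheme: the
open fraction relaxes mono-exponentially toward a Boltzmann steady state at
each voltage, so the generative model matches the fitted models
(mono-exponential kinetics, Boltzmann activation).  The macroscopic current
is N * P(t) * i_GHK(V) plus an optional linear leak and additive gaussian
noise.  A ``gate_exponent`` toggle (e.g. 2) introduces deliberate
kinetic misspecification for robustness checks while preserving the
Boltzmann steady state.

All randomness flows from a single integer seed through named substreams,
one per modality, so families, traces and series drawn from the same
scenario seed are mutually independent yet fully reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .biophysics import (
    ChannelParams,
    IonConditions,
    PhysEnv,
    ghk_single_channel_current,
    permeability_from_conductance,
)
from .errors import DomainError, InvalidInputError
from .protocols import CurrentFamily, VoltageProtocol
from .units import MV, PA, PS
from .vascular import EvokedFieldTrace, LDFTrace, PressureDiameterSeries

__all__ = [
    "substream",
    "GatingParams",
    "SimScenario",
    "simulate_current_family",
    "analytic_steady_state_current",
    "simulate_pressure_diameter",
    "simulate_ldf_trace",
    "simulate_evoked_fields",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from one master seed.

    The stream key mixes the seed with a CRC32 of the name, so stages draw
    independent, reproducible streams from a single config seed.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class GatingParams:
    """Voltage-dependent gating of the simulated KV conductance.

    ``v_half``/``slope_k`` define the Boltzmann steady-state activation;
    ``tau_act`` may be a constant (ms), a {voltage: ms} mapping (linearly
    interpolated), or None for the default symmetric bell over voltage
    peaking near ``v_half``; ``tau_deact`` applies at the tail voltage.
    ``p_open_ref`` is the steady-state open probability at the reference
    (tail) voltage and anchors the counting convention.
    """

    v_half: float = -12.0          # mV
    slope_k: float = 7.0           # mV, > 0
    tau_act: Union[None, float, Mapping[float, float]] = None
    tau_deact: float = 25.0        # ms
    p_open_ref: float = 0.014      # at -40 mV

    def __post_init__(self):
        if not self.slope_k > 0:
            raise DomainError(f"slope_k must be > 0, got {self.slope_k}")
        if not self.tau_deact > 0:
            raise DomainError(f"tau_deact must be > 0, got {self.tau_deact}")
        if not (0.0 < self.p_open_ref <= 1.0):
            raise DomainError(f"p_open_ref must lie in (0, 1], got {self.p_open_ref}")

    def n_inf(self, v_mv: float) -> float:
        """Boltzmann steady-state activation at ``v_mv`` (dimensionless)."""
        return 1.0 / (1.0 + np.exp((self.v_half - v_mv) / self.slope_k))

    def tau_act_at(self, v_mv: float) -> float:
        if self.tau_act is None:
            # symmetric bell: slow near v_half, fast at extremes
            return 4.0 + 16.0 * float(np.exp(-(((v_mv - self.v_half) / 30.0) ** 2)))
        if isinstance(self.tau_act, Mapping):
            keys = np.array(sorted(self.tau_act), dtype=float)
            vals = np.array([self.tau_act[k] for k in sorted(self.tau_act)], dtype=float)
            return float(np.interp(v_mv, keys, vals))
        return float(self.tau_act)


@dataclass(frozen=True)
class SimScenario:
    """Complete description of one simulated voltage-clamp experiment.

    Defaults reproduce the reference recording conditions: 3120 channels of
    15 pS with P_o = 0.014 at -40 mV, 3 mM external / 140 mM internal K+ at
    23 C, a 15 pF cell, 5 pA recording noise, no leak.
    """

    channel: ChannelParams = field(
        default_factory=lambda: ChannelParams(gamma=15.0 * PS, p_open=0.014, n_channels=3120.0)
    )
    gating: GatingParams = field(default_factory=GatingParams)
    protocol: VoltageProtocol = field(default_factory=VoltageProtocol)
    conditions: IonConditions = field(default_factory=lambda: IonConditions.from_mm(3.0, 140.0))
    env: PhysEnv = field(default_factory=lambda: PhysEnv.from_celsius(23.0))
    capacitance: float = 15.0          # pF
    noise_sd: float = 5.0              # pA
    leak_conductance: float = 0.0      # nS
    gate_exponent: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise DomainError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.leak_conductance < 0:
            raise DomainError(f"leak_conductance must be >= 0, got {self.leak_conductance}")
        if self.channel.n_channels is None or self.channel.n_channels < 0:
            raise DomainError("scenario channel params must carry n_channels >= 0")
        if self.gate_exponent < 1:
            raise DomainError(f"gate_exponent must be >= 1, got {self.gate_exponent}")
        if self.gating.p_open_ref != self.channel.p_open:
            raise InvalidInputError(
                "gating.p_open_ref and channel.p_open must agree "
                f"({self.gating.p_open_ref} vs {self.channel.p_open})"
            )

    @property
    def p_k(self) -> float:
        """Single-channel permeability implied by gamma (symmetric [K+] =
        the internal concentration)."""
        return permeability_from_conductance(self.channel.gamma, self.conditions.k_in, self.env)

    @property
    def p_max(self) -> float:
        """Scale linking the Boltzmann gate to absolute open probability:
        p_max * n_inf(tail_v) = p_open_ref."""
        return self.gating.p_open_ref / self.gating.n_inf(self.protocol.tail_v)

    def i_ghk_pa(self, v_mv: float) -> float:
        """Open-channel GHK current at ``v_mv`` in pA."""
        return float(
            ghk_single_channel_current(self.p_k, v_mv * MV, self.conditions, self.env) / PA
        )

    def describe(self) -> dict:
        d = asdict(self)
        d["derived"] = {"p_k_cm3_s": self.p_k, "p_max": self.p_max}
        return d


def _open_fraction(n0: float, n_inf: float, t_ms: np.ndarray, tau_ms: float, q: int) -> np.ndarray:
    """Open fraction for a q-gate channel whose per-gate variable relaxes
    exponentially; steady state equals ``n_inf`` for any q."""
    if q == 1:
        return n_inf + (n0 - n_inf) * np.exp(-t_ms / tau_ms)
    m0, m_inf = n0 ** (1.0 / q), n_inf ** (1.0 / q)
    m = m_inf + (m0 - m_inf) * np.exp(-t_ms / tau_ms)
    return m ** q


def analytic_steady_state_current(s: SimScenario, v_mv: float) -> float:
    """Noise-free steady-state current (pA) at step voltage ``v_mv``:
    N * p_max * n_inf(V) * i_GHK(V) + leak."""
    n = s.channel.n_channels
    return (
        n * s.p_max * s.gating.n_inf(v_mv) * s.i_ghk_pa(v_mv)
        + s.leak_conductance * v_mv
    )


def simulate_current_family(s: SimScenario, cell_id: str = "sim") -> CurrentFamily:
    """Simulate one whole-cell KV current family under the scenario protocol.

    Per step voltage V: the gate relaxes from its holding-potential steady
    state toward n_inf(V) with tau_act(V); at the tail voltage it relaxes
    toward n_inf(tail) with tau_deact.  Current is
    N * p_max * open(t) * i_GHK(segment voltage) + leak * V + gaussian noise.
    Identical scenarios (including seed) give bit-identical families.
    """
    prot, gp = s.protocol, s.gating
    rng = substream(s.seed, "vclamp")
    t = prot.time
    step_mask = t < prot.step_duration
    t_step = t[step_mask]
    t_tail = t[~step_mask] - prot.step_duration

    n_ch = s.channel.n_channels
    scale = n_ch * s.p_max
    n_hold = gp.n_inf(prot.holding_v)
    n_tail_inf = gp.n_inf(prot.tail_v)
    i_tail = s.i_ghk_pa(prot.tail_v)

    data = {}
    truth_iv = []
    for v in prot.step_voltages:
        n_inf_v = gp.n_inf(v)
        open_step = _open_fraction(n_hold, n_inf_v, t_step, gp.tau_act_at(v), s.gate_exponent)
        n_end = float(open_step[-1]) if t_step.size else n_hold
        open_tail = _open_fraction(n_end, n_tail_inf, t_tail, gp.tau_deact, s.gate_exponent)
        i = np.concatenate([
            scale * open_step * s.i_ghk_pa(v) + s.leak_conductance * v,
            scale * open_tail * i_tail + s.leak_conductance * prot.tail_v,
        ])
        if s.noise_sd > 0:
            i = i + rng.normal(0.0, s.noise_sd, size=i.size)
        data[float(v)] = i
        truth_iv.append((float(v), analytic_steady_state_current(s, v)))

    sweeps = pd.DataFrame(data, index=pd.Index(t, name="time_ms"))
    truth = {
        "scenario": s.describe(),
        "n_channels": n_ch,
        "steady_tail_current_pA": n_ch * gp.p_open_ref * i_tail
        + s.leak_conductance * prot.tail_v,
        "analytic_iv_pA": truth_iv,
    }
    return CurrentFamily(
        protocol=prot,
        sweeps=sweeps,
        capacitance=s.capacitance,
        cell_id=cell_id,
        meta={"ground_truth": truth},
    )


def simulate_pressure_diameter(
    tone_by_pressure: Mapping[float, float],
    passive_by_pressure: Optional[Mapping[float, float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    vessel_id: str = "sim",
    condition: str = "",
) -> PressureDiameterSeries:
    """Pressure-myography session with programmed tone.

    active = passive * (1 - tone/100) + gaussian noise.  Default passive
    diameters emulate a posterior cerebral artery dilating passively with
    pressure (140-178 um over 20-100 mmHg).
    """
    if passive_by_pressure is None:
        passive_by_pressure = {20: 140.0, 40: 155.0, 60: 165.0, 80: 172.0, 100: 178.0}
    rng = substream(seed, "pressure")
    rows = []
    for p in sorted(tone_by_pressure):
        if p not in passive_by_pressure:
            raise InvalidInputError(f"no passive diameter for pressure {p} mmHg")
        tone = tone_by_pressure[p]
        if not (0.0 <= tone < 100.0):
            raise DomainError(f"tone must lie in [0, 100), got {tone}")
        passive = float(passive_by_pressure[p])
        active = passive * (1.0 - tone / 100.0)
        if noise_sd > 0:
            active += float(rng.normal(0.0, noise_sd))
        rows.append((float(p), active, passive))
    data = pd.DataFrame(rows, columns=["pressure_mmHg", "active_um", "passive_um"])
    truth = {"tone_by_pressure": dict(tone_by_pressure),
             "passive_by_pressure": {float(k): float(v) for k, v in passive_by_pressure.items()},
             "noise_sd": noise_sd, "seed": seed}
    return PressureDiameterSeries(data=data, vessel_id=vessel_id, condition=condition,
                                  meta={"ground_truth": truth})


def simulate_ldf_trace(
    resting: float = 100.0,
    percent_response: float = 20.0,
    zero_offset: float = 10.0,
    stim_epochs: Sequence[tuple] = ((120.0, 180.0),),
    duration: float = 300.0,
    fs: float = 10.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> LDFTrace:
    """Laser-Doppler trace with a programmed percent CBF response.

    flux = zero_offset + resting * (1 + percent/100 inside stimulation
    epochs) + gaussian noise.  The default emulates a 60 s whisker
    stimulation starting at 120 s with a 20% response and a biological zero
    of 10 LDFU.  The response steps on instantaneously (no hemodynamic
    ramp is modeled).
    """
    if resting <= 0:
        raise DomainError(f"resting must be > 0, got {resting}")
    if zero_offset < 0:
        raise DomainError(f"zero_offset must be >= 0, got {zero_offset}")
    rng = substream(seed, "ldf")
    t = np.arange(0.0, duration, 1.0 / fs)
    flux = np.full(t.size, float(resting))
    for start, end in stim_epochs:
        flux[(t >= start) & (t < end)] = resting * (1.0 + percent_response / 100.0)
    flux = flux + zero_offset
    if noise_sd > 0:
        flux = flux + rng.normal(0.0, noise_sd, size=flux.size)
    events = [("stim", float(a), float(b)) for a, b in stim_epochs]
    truth = {"resting": resting, "percent_response": percent_response,
             "zero_offset": zero_offset, "stim_epochs": [tuple(e) for e in stim_epochs],
             "noise_sd": noise_sd, "seed": seed}
    return LDFTrace(time=t, flux=flux, events=events, biological_zero=zero_offset,
                    meta={"ground_truth": truth})


def simulate_evoked_fields(
    n1_amp: float = 0.4,
    latency_ms: float = 20.0,
    n_sweeps: int = 4,
    noise_sd: float = 0.05,
    seed: int = 0,
    fs_khz: float = 2.0,
    t_range: tuple = (-50.0, 150.0),
) -> EvokedFieldTrace:
    """Stimulus-locked field-potential sweeps with a biphasic waveform.

    The template is a small positive deflection (P1) followed by the
    negative N1 trough at ``latency_ms``, both inside the first 80 ms; the
    template is scaled so the trough is exactly ``-n1_amp`` mV.  Each sweep
    adds independent gaussian noise.
    """
    if n1_amp < 0:
        raise DomainError(f"n1_amp must be >= 0, got {n1_amp}")
    if n_sweeps < 1:
        raise InvalidInputError("need >= 1 sweep")
    rng = substream(seed, "fields")
    t = np.arange(t_range[0], t_range[1], 1.0 / fs_khz)
    shape = (
        0.35 * np.exp(-((t - (latency_ms - 10.0)) / 3.0) ** 2)
        - np.exp(-((t - latency_ms) / 5.0) ** 2)
    )
    shape[t < 0] = 0.0
    template = np.zeros_like(t) if n1_amp == 0 else shape * (n1_amp / -shape.min())
    sweeps = np.tile(template, (n_sweeps, 1))
    if noise_sd > 0:
        sweeps = sweeps + rng.normal(0.0, noise_sd, size=sweeps.shape)
    truth = {"n1_amp": n1_amp, "latency_ms": latency_ms, "n_sweeps": n_sweeps,
             "noise_sd": noise_sd, "seed": seed}
    return EvokedFieldTrace(time_ms=t, sweeps=sweeps, meta={"ground_truth": truth})
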