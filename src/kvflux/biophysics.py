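"""Closed-form single-channel biophysics and functional channel counting.

The chain implemented here estimates the number of functional voltage-gated
K+ (KV) channels per arterial myocyte from a whole-cell recording:

1. single-channel permeability from single-channel conductance measured in
   symmetric K+ solutions,  P_K = gamma / [K+] * RT / F^2;
2. single-channel current at a reference voltage from the
   Goldman-Hodgkin-Katz (GHK) constant-field flux equation under the
   physiological K+ gradient;
3. channel number from the macroscopic current amplitude, I = i * N * P_o,
   with the open probability P_o at the same reference voltage.

Sign convention: membrane potential is inside minus outside, and outward K+
flux (efflux) is positive, matching whole-cell outward-current records.

Units: concentrations are stored in mol/cm^3 (numerically mol/mL), voltages
in volts, currents in amperes, conductances in siemens.  With P_K in cm^3/s
the GHK flux expression then yields amperes.  The permeability defined by
gamma/[K+] * RT/F^2 is dimensionally a volume flux per channel (cm^3/s);
the conventional per-area label "cm/s" is kept as a display alias only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import DomainError, InvalidInputError, ProtocolError
from .units import MM_TO_MOL_PER_CM3, ZERO_CELSIUS, PA, PS, MV

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "PhysEnv",
    "IonConditions",
    "ChannelParams",
    "ChannelCountEstimate",
    "nernst_potential",
    "permeability_from_conductance",
    "conductance_from_permeability",
    "ghk_single_channel_current",
    "estimate_channel_count",
    "channel_count_pipeline",
    "channel_count_from_config",
]

GAS_CONSTANT = 8.314     # J mol^-1 K^-1
FARADAY = 96485.0        # C mol^-1


@dataclass(frozen=True)
class PhysEnv:
    """Thermodynamic context: absolute temperature plus the fixed physical
    constants R and F."""

    temperature: float                    # kelvin
    gas_constant: float = GAS_CONSTANT    # J mol^-1 K^-1
    faraday: float = FARADAY              # C mol^-1

    def __post_init__(self):
        if not self.temperature > 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")

    @classmethod
    def from_celsius(cls, t_celsius: float) -> "PhysEnv":
        return cls(temperature=t_celsius + ZERO_CELSIUS)

    @property
    def thermal_voltage(self) -> float:
        """RT/F in volts (~25.5 mV at 23 C)."""
        return self.gas_constant * self.temperature / self.faraday


@dataclass(frozen=True)
class IonConditions:
    """Transmembrane K+ concentrations, stored in mol/cm^3.

    Use :meth:`from_mm` to construct from millimolar bench values
    (1 mM = 1e-6 mol/cm^3).
    """

    k_out: float          # mol/cm^3
    k_in: float           # mol/cm^3
    valence: int = 1      # K+ charge

    def __post_init__(self):
        if not (self.k_out > 0 and self.k_in > 0):
            raise DomainError(
                f"concentrations must be positive, got k_out={self.k_out}, k_in={self.k_in}"
            )

    @classmethod
    def from_mm(cls, k_out_mm: float, k_in_mm: float) -> "IonConditions":
        return cls(k_out=k_out_mm * MM_TO_MOL_PER_CM3, k_in=k_in_mm * MM_TO_MOL_PER_CM3)

    @property
    def k_out_mm(self) -> float:
        return self.k_out / MM_TO_MOL_PER_CM3

    @property
    def k_in_mm(self) -> float:
        return self.k_in / MM_TO_MOL_PER_CM3


@dataclass(frozen=True)
class ChannelParams:
    """Single-channel parameters used by the counting chain.

    gamma is the single-channel conductance in siemens (measured in
    inside-out patches under symmetric high K+); p_open is the open
    probability at the counting reference voltage.  p_k and n_channels are
    filled on the output side.
    """

    gamma: float                        # siemens
    p_open: float                       # dimensionless, at reference voltage
    p_k: Optional[float] = None         # cm^3/s
    n_channels: Optional[float] = None

    def __post_init__(self):
        if self.gamma < 0:
            raise DomainError(f"gamma must be >= 0, got {self.gamma}")
        if not (0.0 <= self.p_open <= 1.0):
            raise DomainError(f"p_open must lie in [0, 1], got {self.p_open}")
        if self.p_k is not None and self.p_k < 0:
            raise DomainError(f"p_k must be >= 0, got {self.p_k}")

    @classmethod
    def from_bench(cls, gamma_ps: float, p_open: float) -> "ChannelParams":
        return cls(gamma=gamma_ps * PS, p_open=p_open)


@dataclass(frozen=True)
class ChannelCountEstimate:
    """Result of the P_K -> i -> N chain with full input provenance."""

    p_k: float                   # cm^3/s
    i_single: float              # amperes at v_ref
    v_ref: float                 # volts
    n_channels: float            # dimensionless
    macroscopic_current: float   # amperes
    inputs: dict = field(default_factory=dict)

    @property
    def n_rounded(self) -> int:
        """Channel count rounded to the nearest 10, as usually reported."""
        return int(round(self.n_channels / 10.0) * 10)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_rounded"] = self.n_rounded
        d["i_single_pA"] = self.i_single / PA
        d["macroscopic_current_pA"] = self.macroscopic_current / PA
        d["v_ref_mV"] = self.v_ref / MV
        return d


def nernst_potential(cond: IonConditions, env: PhysEnv) -> float:
    """Equilibrium (reversal) potential in volts: (RT/zF) ln([K]o/[K]i).

    Inside-minus-outside convention; for the physiological K+ gradient
    (3 mM out / 140 mM in) this is about -98 mV at 23 C.
    """
    if not (cond.k_out > 0 and cond.k_in > 0):
        raise DomainError("concentrations must be positive")
    return env.thermal_voltage / cond.valence * math.log(cond.k_out / cond.k_in)


def permeability_from_conductance(gamma: float, k_symmetric: float, env: PhysEnv) -> float:
    """Single-channel permeability P_K = gamma / [K+] * RT / F^2.

    Parameters
    ----------
    gamma : siemens
        Single-channel conductance measured in symmetric K+ solutions.
    k_symmetric : mol/cm^3
        The symmetric K+ concentration of that measurement.

    Returns
    -------
    float
        P_K in cm^3/s (the per-channel volume flux; conventionally printed
        with the per-area label cm/s).
    """
    if gamma < 0:
        raise DomainError(f"gamma must be >= 0, got {gamma}")
    if not k_symmetric > 0:
        raise DomainError(f"k_symmetric must be > 0, got {k_symmetric}")
    return gamma / k_symmetric * env.gas_constant * env.temperature / env.faraday ** 2


def conductance_from_permeability(p_k: float, k_symmetric: float, env: PhysEnv) -> float:
    """Inverse of :func:`permeability_from_conductance`: gamma in siemens."""
    if p_k < 0:
        raise DomainError(f"p_k must be >= 0, got {p_k}")
    if not k_symmetric > 0:
        raise DomainError(f"k_symmetric must be > 0, got {k_symmetric}")
    return p_k * k_symmetric * env.faraday ** 2 / (env.gas_constant * env.temperature)


def _phi(u):
    """u / (1 - exp(-u)) with its removable singularity at u = 0.

    For |u| < 1e-4 the series 1 + u/2 + u^2/12 is used (error O(u^4)),
    keeping the GHK current continuous through 0 mV.
    """
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-4
    u_safe = np.where(small, 1.0, u)
    out = np.where(
        small,
        1.0 + u / 2.0 + u * u / 12.0,
        u_safe / (-np.expm1(-u_safe)),
    )
    return out if out.ndim else float(out)


def ghk_single_channel_current(p_k: float, v, cond: IonConditions, env: PhysEnv):
    """Goldman-Hodgkin-Katz flux current through one open channel.

    i = P_K * F * phi(u) * ([K]i - [K]o * exp(-u)),  u = z V F / (R T),
    with phi(u) = u / (1 - exp(-u)).  Outward K+ flux is positive.  Accepts
    a scalar or array of voltages (volts) and returns amperes.

    The current vanishes exactly at the Nernst potential and reduces to the
    ohmic form gamma*V (with gamma = P_K [K] F^2 / RT) when the
    concentrations are symmetric.
    """
    if p_k < 0:
        raise DomainError(f"p_k must be >= 0, got {p_k}")
    v = np.asarray(v, dtype=float)
    u = cond.valence * v * env.faraday / (env.gas_constant * env.temperature)
    i = p_k * cond.valence * env.faraday * _phi(u) * (cond.k_in - cond.k_out * np.exp(-u))
    return i if i.ndim else float(i)


def estimate_channel_count(macroscopic_current: float, i_single: float, p_open: float) -> float:
    """Number of functional channels from I = i * N * P_o.

    ``macroscopic_current`` and ``i_single`` are in amperes and must share
    sign (both outward or both inward); ``p_open`` is the open probability
    at the voltage where both currents are taken.
    """
    if i_single == 0:
        raise InvalidInputError("i_single must be nonzero")
    if not (0.0 < p_open <= 1.0):
        raise InvalidInputError(f"p_open must lie in (0, 1], got {p_open}")
    if macroscopic_current * i_single < 0:
        raise InvalidInputError(
            "macroscopic_current and i_single must share sign "
            f"(got {macroscopic_current} vs {i_single})"
        )
    return macroscopic_current / (i_single * p_open)


def channel_count_pipeline(
    family,
    gamma: float,
    p_open: float,
    cond: IonConditions,
    env: PhysEnv,
    v_ref: float = -40.0 * MV,
    k_symmetric: Optional[float] = None,
) -> ChannelCountEstimate:
    """Full counting chain on a recorded current family.

    The macroscopic current is the steady-state current at the tail voltage
    (the reference voltage where P_o is defined), estimated as the offset of
    a mono-exponential fit to each sweep's tail segment and pooled across
    sweeps by the median.  The instantaneous tail *peak* is deliberately not
    used: it reflects the activation reached during the preceding step, not
    the equilibrium open probability at v_ref.

    Parameters
    ----------
    family : CurrentFamily
        Whole-cell recording with a tail segment at ``v_ref``.
    gamma : siemens
        Single-channel conductance (symmetric-K+ measurement).
    p_open : dimensionless
        Open probability at ``v_ref``.
    v_ref : volts
        Counting reference voltage; must equal the protocol's tail voltage.
    k_symmetric : mol/cm^3, optional
        Symmetric K+ of the gamma measurement; defaults to ``cond.k_in``.
    """
    from .vclamp import fit_deactivation_tau  # deferred: vclamp builds on this module

    if abs(family.protocol.tail_v * MV - v_ref) > 1e-9:
        raise ProtocolError(
            f"no tail segment at v_ref = {v_ref / MV:g} mV "
            f"(protocol tail is {family.protocol.tail_v:g} mV)"
        )

    offsets_pa = []
    for step_v in family.protocol.step_voltages:
        fit = fit_deactivation_tau(family, step_v)
        if fit.converged:
            offsets_pa.append(fit.offset)
    if not offsets_pa:
        raise ProtocolError("no tail fit converged; cannot measure steady tail current")
    macroscopic = float(np.median(offsets_pa)) * PA

    if k_symmetric is None:
        k_symmetric = cond.k_in
    p_k = permeability_from_conductance(gamma, k_symmetric, env)
    i_single = ghk_single_channel_current(p_k, v_ref, cond, env)
    n = estimate_channel_count(macroscopic, i_single, p_open)

    inputs = {
        "gamma_S": gamma,
        "p_open": p_open,
        "k_symmetric_mol_cm3": k_symmetric,
        "k_out_mM": cond.k_out_mm,
        "k_in_mM": cond.k_in_mm,
        "temperature_K": env.temperature,
        "capacitance_pF": family.capacitance,
        "cell_id": family.cell_id,
        "n_tail_fits": len(offsets_pa),
    }
    return ChannelCountEstimate(
        p_k=p_k,
        i_single=float(i_single),
        v_ref=v_ref,
        n_channels=float(n),
        macroscopic_current=macroscopic,
        inputs=inputs,
    )


#: recognized keys for config-driven counting
COUNT_CONFIG_KEYS = {
    "gamma_pS", "p_open", "k_out_mM", "k_in_mM", "temperature_C", "v_ref_mV",
}

_COUNT_DEFAULTS = {
    "gamma_pS": 15.0,
    "p_open": 0.014,
    "k_out_mM": 3.0,
    "k_in_mM": 140.0,
    "temperature_C": 23.0,
    "v_ref_mV": -40.0,
}


def channel_count_from_config(family, config: Optional[dict] = None) -> ChannelCountEstimate:
    """Config-driven wrapper around :func:`channel_count_pipeline`.

    Recognized keys (bench units): gamma_pS, p_open, k_out_mM, k_in_mM,
    temperature_C, v_ref_mV.  Unknown keys are rejected.
    """
    cfg = dict(_COUNT_DEFAULTS)
    if config:
        unknown = set(config) - COUNT_CONFIG_KEYS
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    env = PhysEnv.from_celsius(cfg["temperature_C"])
    cond = IonConditions.from_mm(cfg["k_out_mM"], cfg["k_in_mM"])
    return channel_count_pipeline(
        family,
        gamma=cfg["gamma_pS"] * PS,
        p_open=cfg["p_open"],
        cond=cond,
        env=env,
        v_ref=cfg["v_ref_mV"] * MV,
    )
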