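"""Run configuration: validated keys, scenario building, config snapshots.

A run config is a plain dict (from YAML or JSON) with known top-level
sections only; unknown keys are rejected so typos fail loudly instead of
being silently ignored.  A full snapshot of the effective config is written
next to the outputs of every CLI run.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

from .biophysics import COUNT_CONFIG_KEYS, ChannelParams, IonConditions, PhysEnv
from .errors import InvalidInputError
from .io import read_json, read_yaml, write_json
from .protocols import VoltageProtocol
from .synthetic import GatingParams, SimScenario
from .units import PS

PathLike = Union[str, Path]

#: recognized top-level config sections
KNOWN_SECTIONS = {"seed", "log_level", "scenario", "count", "vclamp", "cbf"}

#: recognized scenario keys (bench units)
SCENARIO_KEYS = {
    "n_channels", "gamma_pS", "p_open",
    "v_half_mV", "slope_k_mV", "tau_act_ms", "tau_deact_ms",
    "k_out_mM", "k_in_mM", "temperature_C",
    "capacitance_pF", "noise_sd_pA", "leak_nS", "gate_exponent", "seed",
    "protocol",
}

PROTOCOL_KEYS = {
    "holding_v", "step_start", "step_stop", "step_increment",
    "step_duration", "tail_v", "tail_duration", "sample_interval",
}


def load_config(path: Optional[PathLike]) -> dict:
    """Load and validate a YAML/JSON run config; None gives the defaults."""
    if path is None:
        cfg = {}
    else:
        p = Path(path)
        cfg = read_json(p) if p.suffix == ".json" else read_yaml(p)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - KNOWN_SECTIONS
    if unknown:
        raise InvalidInputError(f"unknown config sections: {sorted(unknown)}")
    if "count" in cfg:
        bad = set(cfg["count"]) - COUNT_CONFIG_KEYS
        if bad:
            raise InvalidInputError(f"unknown count keys: {sorted(bad)}")
    if "scenario" in cfg:
        scenario_from_dict(cfg["scenario"])  # raises on unknown keys
    cfg.setdefault("seed", 0)
    cfg.setdefault("log_level", "INFO")
    return cfg


def scenario_from_dict(d: Optional[dict], seed: Optional[int] = None) -> SimScenario:
    """Build a :class:`SimScenario` from bench-unit config keys.

    Unspecified keys keep the scenario defaults; ``seed`` (if given)
    overrides any seed in the dict.
    """
    d = dict(d or {})
    unknown = set(d) - SCENARIO_KEYS
    if unknown:
        raise InvalidInputError(f"unknown scenario keys: {sorted(unknown)}")

    proto_d = d.pop("protocol", None)
    if proto_d is not None:
        bad = set(proto_d) - PROTOCOL_KEYS
        if bad:
            raise InvalidInputError(f"unknown protocol keys: {sorted(bad)}")
        base = VoltageProtocol().to_dict()
        base.update(proto_d)
        protocol = VoltageProtocol.from_dict(base)
    else:
        protocol = VoltageProtocol()

    defaults = SimScenario()
    p_open = d.get("p_open", defaults.channel.p_open)
    channel = ChannelParams(
        gamma=d.get("gamma_pS", defaults.channel.gamma / PS) * PS,
        p_open=p_open,
        n_channels=float(d.get("n_channels", defaults.channel.n_channels)),
    )
    tau_act = d.get("tau_act_ms", defaults.gating.tau_act)
    if isinstance(tau_act, dict):
        tau_act = {float(k): float(v) for k, v in tau_act.items()}
    gating = GatingParams(
        v_half=d.get("v_half_mV", defaults.gating.v_half),
        slope_k=d.get("slope_k_mV", defaults.gating.slope_k),
        tau_act=tau_act,
        tau_deact=d.get("tau_deact_ms", defaults.gating.tau_deact),
        p_open_ref=p_open,
    )
    return SimScenario(
        channel=channel,
        gating=gating,
        protocol=protocol,
        conditions=IonConditions.from_mm(
            d.get("k_out_mM", defaults.conditions.k_out_mm),
            d.get("k_in_mM", defaults.conditions.k_in_mm),
        ),
        env=PhysEnv.from_celsius(d.get("temperature_C", defaults.env.temperature - 273.15)),
        capacitance=d.get("capacitance_pF", defaults.capacitance),
        noise_sd=d.get("noise_sd_pA", defaults.noise_sd),
        leak_conductance=d.get("leak_nS", defaults.leak_conductance),
        gate_exponent=int(d.get("gate_exponent", defaults.gate_exponent)),
        seed=seed if seed is not None else int(d.get("seed", defaults.seed)),
    )


def write_snapshot(outdir: PathLike, cfg: dict) -> Path:
    """Write the effective config next to the outputs; returns the path."""
    out = Path(outdir) / "config_snapshot.json"
    write_json(out, cfg)
    return out
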