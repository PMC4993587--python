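"""Voltage-clamp family analysis.

Stages: steady-state I-V extraction and capacitance normalization
(current density, pA/pF), tail-current peak extraction, Boltzmann fitting
of the steady-state activation curve, and mono-exponential fitting of
activation/deactivation kinetics.  Nonlinear fits go through
``scipy.optimize.curve_fit`` with deterministic, derivative-free starting
values; non-convergence is flagged on the result, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InvalidInputError, ProtocolError, StageError
from .protocols import CurrentFamily

__all__ = [
    "BoltzmannFit",
    "TauFit",
    "FamilyAnalysis",
    "extract_steady_state",
    "extract_tail_peaks",
    "fit_boltzmann",
    "fit_activation_tau",
    "fit_deactivation_tau",
    "fit_all_taus",
    "analyze_family",
]

_FIT_KW = dict(xtol=1e-8, ftol=1e-8, maxfev=500 * 10)


@dataclass(frozen=True)
class BoltzmannFit:
    """Steady-state activation curve I = I_max / (1 + exp((V0.5 - V)/k)).

    ``slope_k`` is positive for an activation curve that increases with
    depolarization.  ``residual_norm`` is the RMS residual of the
    normalized curve; predictions are in [0, 1].
    """

    v_half: float          # mV
    slope_k: float         # mV, > 0
    i_max: float           # pA
    residual_norm: float
    converged: bool

    def predict_normalized(self, v):
        v = np.asarray(v, dtype=float)
        out = 1.0 / (1.0 + np.exp((self.v_half - v) / self.slope_k))
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class TauFit:
    """Mono-exponential time-constant fit for one sweep segment."""

    tau: float             # ms
    amplitude: float       # pA
    offset: float          # pA
    which: str             # "activation" | "deactivation"
    fit_window: tuple      # (start, stop) ms within the segment
    converged: bool


def extract_steady_state(family: CurrentFamily, window_ms: Optional[tuple] = None) -> pd.DataFrame:
    """Steady-state I-V table with current density.

    The steady-state amplitude is the mean current over a terminal window of
    the step (default: its last 10%), i.e. the current "at the end of the
    pulse"; density divides by cell capacitance.

    Returns a DataFrame with columns ``step_v``, ``i_steady_pA``,
    ``density_pA_per_pF``.
    """
    dur = family.protocol.step_duration
    if window_ms is None:
        window_ms = (0.9 * dur, dur)
    lo, hi = window_ms
    if not (0 <= lo < hi <= dur):
        raise InvalidInputError(
            f"steady-state window {window_ms} must lie within the step [0, {dur}] ms"
        )
    rows = []
    for v in family.protocol.step_voltages:
        seg = family.step_segment(v)
        t = seg.index.to_numpy(dtype=float)
        sel = seg[(t >= lo) & (t < hi)]
        if sel.empty:
            raise InvalidInputError(f"window {window_ms} contains no samples")
        i_ss = float(sel.mean())
        rows.append((float(v), i_ss, i_ss / family.capacitance))
    return pd.DataFrame(rows, columns=["step_v", "i_steady_pA", "density_pA_per_pF"])


def extract_tail_peaks(
    family: CurrentFamily,
    search_ms: float = 10.0,
    blank_ms: float = 0.5,
    smooth_ms: float = 1.0,
) -> pd.DataFrame:
    """Peak tail current per step voltage.

    Looks at the first ``search_ms`` of the tail segment after a
    ``blank_ms`` blanking interval (capacitive transient), smooths with a
    ``smooth_ms`` boxcar to keep the extremum from riding on single noise
    samples, and takes the extremum (largest absolute excursion, signed).

    Returns a DataFrame with columns ``step_v``, ``tail_peak_pA``.
    """
    rows = []
    for v in family.protocol.step_voltages:
        tail = family.tail_segment(v)
        t = tail.index.to_numpy(dtype=float)
        y = tail.to_numpy(dtype=float)
        sel = (t >= blank_ms) & (t < blank_ms + search_ms)
        if not sel.any():
            raise ProtocolError("tail search window contains no samples")
        yw = y[sel]
        nk = max(1, int(round(smooth_ms / family.protocol.sample_interval)))
        if nk > 1 and yw.size >= nk:
            kernel = np.ones(nk) / nk
            yw = np.convolve(yw, kernel, mode="valid")
        peak = yw[int(np.argmax(np.abs(yw)))]
        rows.append((float(v), float(peak)))
    return pd.DataFrame(rows, columns=["step_v", "tail_peak_pA"])


def _boltzmann(v, i_max, v_half, k):
    return i_max / (1.0 + np.exp((v_half - v) / k))


def _boltzmann_printed(v, i_max, v_half, k):
    # printed-convention variant, decreasing in V for k > 0
    return i_max / (1.0 + np.exp((v_half + v) / k))


def fit_boltzmann(tail_peaks, printed_convention: bool = False) -> BoltzmannFit:
    """Fit tail peaks vs step voltage to the Boltzmann activation curve.

    Normalization is by the *fitted* I_max (a free parameter), not by the
    largest observed peak.  Initialization: V0.5 from the half-amplitude
    crossing, k = 10 mV, I_max = max peak.  Non-convergence returns a result
    with ``converged=False`` rather than raising.

    ``printed_convention`` switches the exponent to (V0.5 + V)/k, the form
    sometimes printed in methods sections; it is the standard form under
    k -> -k, V0.5 -> -V0.5 and is provided for cross-checking only.
    """
    if isinstance(tail_peaks, pd.DataFrame):
        v = tail_peaks["step_v"].to_numpy(dtype=float)
        y = tail_peaks["tail_peak_pA"].to_numpy(dtype=float)
    else:
        arr = np.asarray(tail_peaks, dtype=float)
        v, y = arr[:, 0], arr[:, 1]
    if np.unique(v).size < 5:
        raise InvalidInputError("need >= 5 distinct step voltages for a Boltzmann fit")

    i_max0 = float(y.max())
    half = 0.5 * i_max0
    above = np.nonzero(y >= half)[0]
    if above.size and above[0] > 0:
        j = above[0]
        # linear interpolation of the half-amplitude crossing
        v_half0 = v[j - 1] + (half - y[j - 1]) * (v[j] - v[j - 1]) / (y[j] - y[j - 1])
    else:
        v_half0 = float(np.median(v))
    if printed_convention:
        v_half0 = -v_half0

    if printed_convention:
        # standard form under k -> -k, V0.5 -> -V0.5: k comes out negative
        model, k0, k_bounds = _boltzmann_printed, -10.0, (-500.0, 500.0)
    else:
        model, k0, k_bounds = _boltzmann, 10.0, (1e-3, 500.0)
    try:
        popt, _ = curve_fit(
            model, v, y,
            p0=[max(i_max0, 1e-9), v_half0, k0],
            bounds=([1e-12, -500.0, k_bounds[0]], [np.inf, 500.0, k_bounds[1]]),
            **_FIT_KW,
        )
        i_max, v_half, k = (float(p) for p in popt)
        resid = (y - model(v, *popt)) / i_max
        return BoltzmannFit(
            v_half=v_half, slope_k=k, i_max=i_max,
            residual_norm=float(np.sqrt(np.mean(resid ** 2))),
            converged=True,
        )
    except (RuntimeError, ValueError):
        return BoltzmannFit(
            v_half=float("nan"), slope_k=float("nan"), i_max=float("nan"),
            residual_norm=float("inf"), converged=False,
        )


def _rise(t, a, tau, c):
    return a * (1.0 - np.exp(-t / tau)) + c


def _decay(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _tau_init_from_crossing(t, y, y0, y_end) -> float:
    """Time at which the trace covers 63% of its excursion (deterministic,
    derivative-free start for tau)."""
    target = y0 + 0.632 * (y_end - y0)
    if y_end >= y0:
        hit = np.nonzero(y >= target)[0]
    else:
        hit = np.nonzero(y <= target)[0]
    if hit.size:
        return max(float(t[hit[0]]), float(t[1] - t[0]) if t.size > 1 else 1e-3)
    return max(float(t[-1]) / 5.0, 1e-3)


def _fit_exponential(t, y, which: str, window: tuple) -> TauFit:
    y0, y_end = float(y[0]), float(np.mean(y[-max(1, y.size // 10):]))
    if which == "activation":
        model, a0, c0 = _rise, y_end - y0, y0
    else:
        model, a0, c0 = _decay, y0 - y_end, y_end
    tau0 = _tau_init_from_crossing(t, y, y0, y_end)
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=[a0, tau0, c0],
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 1e7, np.inf]),
            **_FIT_KW,
        )
        a, tau, c = (float(p) for p in popt)
        perr = np.sqrt(np.diag(pcov))
        # a tau pinned to a bound means no resolvable relaxation in the segment
        at_bound = tau <= 2e-6 or tau >= 5e6
        degenerate = (not np.all(np.isfinite(perr))) or abs(a) < 1e-9 or at_bound
        return TauFit(tau=tau, amplitude=a, offset=c, which=which,
                      fit_window=window, converged=not degenerate)
    except (RuntimeError, ValueError):
        return TauFit(tau=float("nan"), amplitude=float("nan"), offset=float("nan"),
                      which=which, fit_window=window, converged=False)


def fit_activation_tau(family: CurrentFamily, step_v: float, blank_ms: float = 0.5) -> TauFit:
    """Activation time constant: fit I(t) = A(1 - exp(-t/tau)) + C over the
    step segment (after a blanking interval), t measured from the fit start."""
    seg = family.step_segment(step_v)
    t = seg.index.to_numpy(dtype=float)
    sel = t >= blank_ms
    t, y = t[sel], seg.to_numpy(dtype=float)[sel]
    t = t - t[0]
    return _fit_exponential(t, y, "activation", (blank_ms, family.protocol.step_duration))


def fit_deactivation_tau(family: CurrentFamily, step_v: float, blank_ms: float = 0.5) -> TauFit:
    """Deactivation time constant: fit I(t) = A exp(-t/tau) + C over the
    tail segment (after a blanking interval).

    The fitted ``offset`` is the steady-state current at the tail voltage,
    which the channel-counting chain uses as its macroscopic amplitude.
    """
    tail = family.tail_segment(step_v)
    t = tail.index.to_numpy(dtype=float)
    sel = t >= blank_ms
    t, y = t[sel], tail.to_numpy(dtype=float)[sel]
    t = t - t[0]
    return _fit_exponential(t, y, "deactivation", (blank_ms, family.protocol.tail_duration))


def fit_all_taus(family: CurrentFamily) -> pd.DataFrame:
    """Activation and deactivation tau per step voltage (one row per step;
    non-converged fits carry NaN tau and converged=False)."""
    rows = []
    for v in family.protocol.step_voltages:
        fa = fit_activation_tau(family, v)
        fd = fit_deactivation_tau(family, v)
        rows.append((float(v), fa.tau, fa.converged, fd.tau, fd.converged))
    return pd.DataFrame(
        rows,
        columns=["step_v", "tau_act_ms", "act_converged", "tau_deact_ms", "deact_converged"],
    )


@dataclass
class FamilyAnalysis:
    """Bundle of all per-cell voltage-clamp results with provenance."""

    iv: pd.DataFrame
    tail_peaks: pd.DataFrame
    boltzmann: BoltzmannFit
    taus: pd.DataFrame
    count: Optional[object] = None     # ChannelCountEstimate when requested
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "iv": self.iv.to_dict(orient="list"),
            "tail_peaks": self.tail_peaks.to_dict(orient="list"),
            "boltzmann": asdict(self.boltzmann),
            "taus": self.taus.to_dict(orient="list"),
            "provenance": self.provenance,
        }
        if self.count is not None:
            d["channel_count"] = self.count.to_dict()
        return d


def analyze_family(family: CurrentFamily, config: Optional[dict] = None) -> FamilyAnalysis:
    """Run every analysis stage on one family.

    ``config`` may carry a ``count`` sub-dict (keys: gamma_pS, p_open,
    k_out_mM, k_in_mM, temperature_C, v_ref_mV) to enable channel counting,
    and a ``steady_state_window_ms`` pair.  Stage failures re-raise as
    :class:`StageError` with the stage label.
    """
    from .biophysics import channel_count_from_config

    config = dict(config or {})
    count_cfg = config.pop("count", None)
    window = config.pop("steady_state_window_ms", None)
    if config:
        raise InvalidInputError(f"unknown analyze_family config keys: {sorted(config)}")

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage label
            raise StageError(stage, str(exc)) from exc

    iv = run("steady_state", extract_steady_state, family, window)
    peaks = run("tail_peaks", extract_tail_peaks, family)
    boltz = run("boltzmann", fit_boltzmann, peaks)
    taus = run("tau_fits", fit_all_taus, family)
    count = None
    if count_cfg is not None:
        count = run("channel_count", channel_count_from_config, family, count_cfg)

    prov = {
        "cell_id": family.cell_id,
        "capacitance_pF": family.capacitance,
        "protocol": family.protocol.to_dict(),
        "config": {"count": count_cfg, "steady_state_window_ms": window},
    }
    return FamilyAnalysis(iv=iv, tail_peaks=peaks, boltzmann=boltz, taus=taus,
                          count=count, provenance=prov)
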