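"""Vascular and neurovascular readout quantification.

Three measurement families:

* pressure myography: myogenic tone as percent constriction from the
  passive (Ca2+-free) diameter at each intraluminal pressure;
* laser-Doppler flowmetry (LDF): biological-zero correction and percent
  cerebral-blood-flow (CBF) responses to a stimulus;
* evoked field potentials: N1 (negative wave) amplitude within a
  post-stimulus window on trial-averaged sweeps.

Group summaries (mean +/- SEM with a delegated standard test) live here
too; no bespoke inferential statistics are implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, IncompleteRecordError, InvalidInputError

__all__ = [
    "PressureDiameterSeries",
    "LDFTrace",
    "CBFResponse",
    "EvokedFieldTrace",
    "N1Measurement",
    "GroupSummary",
    "compute_myogenic_tone",
    "zero_correct",
    "compute_cbf_response",
    "measure_n1_amplitude",
    "summarize_group",
]


@dataclass
class PressureDiameterSeries:
    """Active and passive internal diameters per intraluminal pressure.

    ``data`` columns: pressure_mmHg, active_um, passive_um.  Active diameter
    is measured in normal physiological salt solution; passive diameter is
    the maximal dilation in Ca2+-free solution at the same pressure.
    """

    data: pd.DataFrame
    vessel_id: str = ""
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        need = {"pressure_mmHg", "active_um", "passive_um"}
        missing = need - set(self.data.columns)
        if missing:
            raise IncompleteRecordError(f"missing columns: {sorted(missing)}")


def compute_myogenic_tone(series: PressureDiameterSeries) -> pd.DataFrame:
    """Myogenic tone per pressure as percent of passive diameter:
    (passive - active) / passive * 100.

    Returns a DataFrame with columns ``pressure_mmHg``, ``tone_percent``.
    """
    df = series.data
    if df["passive_um"].isna().any() or df["active_um"].isna().any():
        bad = df.loc[df[["active_um", "passive_um"]].isna().any(axis=1), "pressure_mmHg"]
        raise IncompleteRecordError(
            f"missing diameter at pressure(s) {bad.tolist()} mmHg"
        )
    if (df["passive_um"] <= 0).any() or (df["active_um"] <= 0).any():
        raise InvalidInputError("diameters must be positive")
    tone = (df["passive_um"] - df["active_um"]) / df["passive_um"] * 100.0
    return pd.DataFrame({
        "pressure_mmHg": df["pressure_mmHg"].to_numpy(dtype=float),
        "tone_percent": tone.to_numpy(dtype=float),
    })


@dataclass
class LDFTrace:
    """Laser-Doppler flux trace in arbitrary perfusion units (LDFU).

    ``events`` is a list of (label, start_s, end_s) annotations;
    ``biological_zero`` is the residual flux recorded after cardiac arrest
    and is subtracted before any percent computation.
    """

    time: np.ndarray            # s, uniform
    flux: np.ndarray            # LDFU
    events: list = field(default_factory=list)
    biological_zero: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if self.time.shape != self.flux.shape:
            raise InvalidInputError("time and flux must have the same length")
        if self.biological_zero < 0:
            raise CalibrationError(f"biological_zero must be >= 0, got {self.biological_zero}")

    def resting_mean(self) -> float:
        """Mean raw flux before the first event (whole trace if no events)."""
        if self.events:
            t0 = min(ev[1] for ev in self.events)
            pre = self.flux[self.time < t0]
            if pre.size:
                return float(pre.mean())
        return float(self.flux.mean())


def zero_correct(trace: LDFTrace) -> LDFTrace:
    """Subtract the biological zero, clipping at 0.

    Idempotent: the returned trace carries ``biological_zero = 0``, so
    correcting twice is the same as correcting once.
    """
    if trace.biological_zero == 0.0:
        return trace
    if trace.biological_zero >= trace.resting_mean():
        raise CalibrationError(
            f"biological_zero ({trace.biological_zero}) is not below the "
            f"resting flux ({trace.resting_mean():.3g})"
        )
    return replace(
        trace,
        flux=np.clip(trace.flux - trace.biological_zero, 0.0, None),
        biological_zero=0.0,
    )


@dataclass(frozen=True)
class CBFResponse:
    """Percent CBF response: 100 * (stimulus - resting) / resting, both
    levels zero-corrected."""

    resting: float          # LDFU, zero-corrected
    stimulus: float         # LDFU, zero-corrected
    percent_increase: float
    warning: Optional[str] = None


def compute_cbf_response(
    trace: LDFTrace,
    baseline_window: Optional[tuple] = None,
    response_window: Optional[tuple] = None,
    statistic: str = "mean",
) -> CBFResponse:
    """Percent CBF response to a stimulation epoch.

    Defaults: baseline = the 30 s immediately before the first annotated
    event; response = that event's epoch, summarized by its plateau mean
    (``statistic="peak"`` uses the maximum instead).  The trace is
    zero-corrected internally (a no-op if already corrected).
    """
    if statistic not in ("mean", "peak"):
        raise InvalidInputError(f"statistic must be 'mean' or 'peak', got {statistic!r}")
    if (baseline_window is None or response_window is None) and not trace.events:
        raise InvalidInputError("windows not given and trace has no events")
    if response_window is None:
        _, start, end = min(trace.events, key=lambda ev: ev[1])
        response_window = (start, end)
    if baseline_window is None:
        baseline_window = (max(response_window[0] - 30.0, trace.time[0]), response_window[0])
    b0, b1 = baseline_window
    r0, r1 = response_window
    if not (b0 < b1 and r0 < r1):
        raise InvalidInputError("windows must have positive length")
    if b1 > r0:
        raise InvalidInputError(
            f"baseline window {baseline_window} must precede response window {response_window}"
        )

    corrected = zero_correct(trace)
    t, f = corrected.time, corrected.flux
    base = f[(t >= b0) & (t < b1)]
    resp = f[(t >= r0) & (t < r1)]
    if base.size == 0 or resp.size == 0:
        raise InvalidInputError("a window contains no samples")

    warning = None
    if trace.events and not any(r0 < ev[2] and ev[1] < r1 for ev in trace.events):
        warning = "response window overlaps no annotated event"

    resting = float(base.mean())
    stimulus = float(resp.max()) if statistic == "peak" else float(resp.mean())
    if resting <= 0:
        raise CalibrationError("resting level is not positive after zero correction")
    return CBFResponse(
        resting=resting,
        stimulus=stimulus,
        percent_increase=100.0 * (stimulus - resting) / resting,
        warning=warning,
    )


@dataclass
class EvokedFieldTrace:
    """Stimulus-locked field-potential sweeps.

    ``sweeps`` has shape (n_sweeps, n_samples) in mV on a common
    ``time_ms`` axis with the stimulus at t = 0; the analysis window is the
    post-stimulus interval searched for the N1 trough (default 0-80 ms).
    """

    time_ms: np.ndarray
    sweeps: np.ndarray
    analysis_window: tuple = (0.0, 80.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if self.sweeps.shape[1] != self.time_ms.size:
            raise InvalidInputError("sweeps and time axis disagree in length")
        lo, hi = self.analysis_window
        if not (self.time_ms[0] <= lo < hi <= self.time_ms[-1]):
            raise InvalidInputError(
                f"analysis window {self.analysis_window} outside sweep extent"
            )


@dataclass(frozen=True)
class N1Measurement:
    """N1 (negative wave) amplitude of the trial-averaged field potential."""

    amplitude: float        # mV, |trough - baseline|
    latency_ms: float
    detected: bool
    baseline: float
    baseline_sd: float


def measure_n1_amplitude(trace: EvokedFieldTrace) -> N1Measurement:
    """N1 amplitude on the average of all sweeps.

    Baseline is the pre-stimulus (t < 0) mean; the trough is the minimum of
    the averaged sweep within the analysis window.  A trough not below
    baseline - 2 * baseline SD is flagged as not detected (its amplitude is
    still reported for inspection).
    """
    avg = trace.sweeps.mean(axis=0)
    t = trace.time_ms
    pre = avg[t < 0]
    if pre.size == 0:
        raise InvalidInputError("no pre-stimulus samples for a baseline")
    baseline = float(pre.mean())
    baseline_sd = float(pre.std(ddof=0))

    lo, hi = trace.analysis_window
    sel = (t >= lo) & (t <= hi)
    win = avg[sel]
    idx = int(np.argmin(win))
    trough = float(win[idx])
    latency = float(t[sel][idx])
    detected = trough < baseline - 2.0 * baseline_sd
    return N1Measurement(
        amplitude=abs(trough - baseline),
        latency_ms=latency,
        detected=detected,
        baseline=baseline,
        baseline_sd=baseline_sd,
    )


@dataclass
class GroupSummary:
    """Per-group mean +/- SEM plus a delegated standard test."""

    table: pd.DataFrame
    test_name: str
    p_value: float


def summarize_group(
    groups: Mapping[str, Sequence[float]],
    design: str = "between",
) -> GroupSummary:
    """Summarize >= 2 groups of scalar results.

    ``design="between"`` delegates to Welch's t-test (2 groups) or one-way
    ANOVA (scipy); ``design="repeated"`` to the paired t-test (2 groups) or
    a repeated-measures ANOVA (statsmodels).  Singleton groups get NaN SEM
    (flagged in the ``sem_defined`` column) and p-value NaN.
    """
    if design not in ("between", "repeated"):
        raise InvalidInputError(f"design must be 'between' or 'repeated', got {design!r}")
    if len(groups) < 2:
        raise InvalidInputError("need >= 2 groups")

    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    rows = []
    for name, a in arrays.items():
        sem = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else float("nan")
        rows.append((name, a.size, float(a.mean()), sem, a.size > 1))
    table = pd.DataFrame(rows, columns=["group", "n", "mean", "sem", "sem_defined"])

    vals = list(arrays.values())
    if any(a.size < 2 for a in vals):
        return GroupSummary(table=table, test_name="none (singleton group)", p_value=float("nan"))
    if design == "between":
        if len(vals) == 2:
            test, p = "Welch t-test", stats.ttest_ind(vals[0], vals[1], equal_var=False).pvalue
        else:
            test, p = "one-way ANOVA", stats.f_oneway(*vals).pvalue
    else:
        if len({a.size for a in vals}) != 1:
            raise InvalidInputError("repeated design requires equal group sizes")
        if len(vals) == 2:
            test, p = "paired t-test", stats.ttest_rel(vals[0], vals[1]).pvalue
        else:
            from statsmodels.stats.anova import AnovaRM

            n = vals[0].size
            long = pd.DataFrame({
                "subject": np.tile(np.arange(n), len(vals)),
                "condition": np.repeat(list(arrays.keys()), n),
                "value": np.concatenate(vals),
            })
            res = AnovaRM(long, depvar="value", subject="subject",
                          within=["condition"]).fit()
            test, p = "repeated-measures ANOVA", float(res.anova_table["Pr > F"].iloc[0])
    return GroupSummary(table=table, test_name=test, p_value=float(p))
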