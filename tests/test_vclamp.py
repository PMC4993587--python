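"""Voltage-clamp analysis: I-V, tail peaks, Boltzmann and tau fits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import kvflux as kf
from kvflux.errors import InvalidInputError, ProtocolError, StageError
from kvflux.protocols import CurrentFamily, VoltageProtocol
from kvflux.vclamp import _boltzmann


def _constant_family(step_value=500.0, tail_values=None, capacitance=15.0):
    """Family whose step segments are constant and whose tails are constant
    per sweep: every extraction is exact arithmetic."""
    prot = VoltageProtocol(step_duration=20.0, tail_duration=20.0, sample_interval=0.5)
    t = prot.time
    data = {}
    for v in prot.step_voltages:
        y = np.full(t.size, float(step_value))
        if tail_values is not None:
            y[t >= prot.step_duration] = tail_values[float(v)]
        data[float(v)] = y
    sweeps = pd.DataFrame(data, index=pd.Index(t, name="time_ms"))
    return CurrentFamily(protocol=prot, sweeps=sweeps, capacitance=capacitance)


class TestExtractSteadyState:
    def test_constant_sweep_density(self):
        fam = _constant_family(step_value=500.0, capacitance=15.0)
        iv = kf.extract_steady_state(fam)
        assert np.allclose(iv["i_steady_pA"], 500.0)
        assert np.allclose(iv["density_pA_per_pF"], 500.0 / 15.0)

    def test_zero_current(self):
        fam = _constant_family(step_value=0.0)
        iv = kf.extract_steady_state(fam)
        assert np.allclose(iv["density_pA_per_pF"], 0.0)

    def test_window_outside_step_rejected(self, default_family):
        with pytest.raises(InvalidInputError):
            kf.extract_steady_state(default_family, window_ms=(200.0, 400.0))

    def test_matches_analytic_steady_state(self, default_scenario, default_family):
        iv = kf.extract_steady_state(default_family)
        # noise SE of the window mean: sd / sqrt(n_window)
        n_win = int(0.1 * default_scenario.protocol.step_duration
                    / default_scenario.protocol.sample_interval)
        se = default_scenario.noise_sd / np.sqrt(n_win)
        for _, row in iv.iterrows():
            expected = kf.analytic_steady_state_current(default_scenario, row["step_v"])
            # the gate has settled well within 10 tau; allow 5 SE
            assert row["i_steady_pA"] == pytest.approx(expected, abs=5 * se)

    def test_density_invariant_to_cell_doubling(self, default_family):
        """Two identical cells in parallel (2x current, 2x capacitance) have
        the same current density."""
        doubled = CurrentFamily(
            protocol=default_family.protocol,
            sweeps=default_family.sweeps * 2.0,
            capacitance=default_family.capacitance * 2.0,
        )
        a = kf.extract_steady_state(default_family)["density_pA_per_pF"]
        b = kf.extract_steady_state(doubled)["density_pA_per_pF"]
        assert np.array_equal(a.to_numpy(), b.to_numpy())


class TestExtractTailPeaks:
    def test_exact_recovery_of_constant_tails(self):
        prot = VoltageProtocol(step_duration=20.0, tail_duration=20.0, sample_interval=0.5)
        tails = {float(v): 10.0 + i for i, v in enumerate(prot.step_voltages)}
        fam = _constant_family(tail_values=tails)
        peaks = kf.extract_tail_peaks(fam)
        for _, row in peaks.iterrows():
            assert row["tail_peak_pA"] == tails[row["step_v"]]

    def test_linearity_under_scaling(self):
        prot = VoltageProtocol(step_duration=20.0, tail_duration=20.0, sample_interval=0.5)
        tails = {float(v): 5.0 + i for i, v in enumerate(prot.step_voltages)}
        fam = _constant_family(tail_values=tails)
        doubled = CurrentFamily(protocol=fam.protocol, sweeps=fam.sweeps * 2.0,
                                capacitance=fam.capacitance)
        p1 = kf.extract_tail_peaks(fam)["tail_peak_pA"].to_numpy()
        p2 = kf.extract_tail_peaks(doubled)["tail_peak_pA"].to_numpy()
        assert np.allclose(p2, 2.0 * p1)

    def test_peaks_track_steady_state_activation(self, noiseless_family, default_scenario):
        """Tail peaks are proportional to the activation n_inf(V_step)
        reached during the step."""
        gp = default_scenario.gating
        peaks = kf.extract_tail_peaks(noiseless_family)
        v = peaks["step_v"].to_numpy()
        y = peaks["tail_peak_pA"].to_numpy()
        n_inf = np.array([gp.n_inf(vv) for vv in v])
        # regress peaks on n_inf: near-perfect proportionality
        slope = np.sum(y * n_inf) / np.sum(n_inf ** 2)
        assert np.corrcoef(y, n_inf)[0, 1] > 0.9999
        assert np.max(np.abs(y - slope * n_inf)) < 0.05 * np.max(np.abs(y))


class TestFitBoltzmann:
    V = np.arange(-70.0, 61.0, 10.0)

    def test_noiseless_exact_recovery(self):
        y = _boltzmann(self.V, 450.0, -10.0, 7.0)
        fit = kf.fit_boltzmann(np.column_stack([self.V, y]))
        assert fit.converged
        assert abs(fit.v_half - (-10.0)) < 1e-6
        assert abs(fit.slope_k - 7.0) < 1e-6
        assert fit.i_max == pytest.approx(450.0, rel=1e-8)

    def test_midpoint_prediction_is_half(self):
        y = _boltzmann(self.V, 450.0, -10.0, 7.0)
        fit = kf.fit_boltzmann(np.column_stack([self.V, y]))
        assert fit.predict_normalized(fit.v_half) == pytest.approx(0.5, abs=1e-9)
        pred = fit.predict_normalized(self.V)
        assert np.all((pred >= 0) & (pred <= 1))

    def test_invariance_under_positive_scaling(self):
        rng = np.random.default_rng(3)
        y = _boltzmann(self.V, 450.0, -10.0, 7.0) + rng.normal(0, 5.0, self.V.size)
        f1 = kf.fit_boltzmann(np.column_stack([self.V, y]))
        f2 = kf.fit_boltzmann(np.column_stack([self.V, 7.3 * y]))
        assert f2.v_half == pytest.approx(f1.v_half, abs=1e-6)
        assert f2.slope_k == pytest.approx(f1.slope_k, abs=1e-6)
        assert f2.i_max == pytest.approx(7.3 * f1.i_max, rel=1e-6)

    def test_monte_carlo_bias_small_at_2pct_noise(self):
        """200 seeded replicates at noise SD 2% of I_max: mean V0.5 bias
        under 0.5 mV."""
        rng = np.random.default_rng(2024)
        truth = _boltzmann(self.V, 1.0, -10.0, 7.0)
        v_halves = []
        for _ in range(200):
            y = truth + rng.normal(0.0, 0.02, self.V.size)
            fit = kf.fit_boltzmann(np.column_stack([self.V, y]))
            if fit.converged:
                v_halves.append(fit.v_half)
        assert len(v_halves) >= 195
        assert abs(np.mean(v_halves) - (-10.0)) < 0.5

    def test_too_few_voltages_rejected(self):
        v = np.array([-40.0, -20.0, 0.0, 20.0])
        y = _boltzmann(v, 1.0, -10.0, 7.0)
        with pytest.raises(InvalidInputError):
            kf.fit_boltzmann(np.column_stack([v, y]))

    def test_printed_convention_is_sign_flip(self):
        y = _boltzmann(self.V, 450.0, -10.0, 7.0)
        fit = kf.fit_boltzmann(np.column_stack([self.V, y]), printed_convention=True)
        assert fit.converged
        assert fit.v_half == pytest.approx(10.0, abs=1e-5)
        assert fit.slope_k == pytest.approx(-7.0, abs=1e-5)


def _exp_family(tau_act=12.0, tau_deact=30.0, sample_interval=0.1, a=400.0, c=20.0):
    """Single-step family with exact mono-exponential rise and decay."""
    prot = VoltageProtocol(step_start=60.0, step_stop=60.0, step_duration=100.0,
                           tail_duration=150.0, sample_interval=sample_interval)
    t = prot.time
    step = t < prot.step_duration
    y = np.empty(t.size)
    y[step] = a * (1.0 - np.exp(-t[step] / tau_act)) + c
    t_tail = t[~step] - prot.step_duration
    y0 = a * (1.0 - np.exp(-prot.step_duration / tau_act))
    y[~step] = y0 * np.exp(-t_tail / tau_deact) + c
    sweeps = pd.DataFrame({60.0: y}, index=pd.Index(t, name="time_ms"))
    return CurrentFamily(protocol=prot, sweeps=sweeps, capacitance=15.0)


class TestTauFits:
    def test_noiseless_activation_recovery(self):
        fam = _exp_family(tau_act=12.0)
        fit = kf.fit_activation_tau(fam, 60.0)
        assert fit.converged
        assert abs(fit.tau - 12.0) / 12.0 < 1e-6

    def test_noiseless_deactivation_recovery(self):
        fam = _exp_family(tau_deact=30.0)
        fit = kf.fit_deactivation_tau(fam, 60.0)
        assert fit.converged
        assert abs(fit.tau - 30.0) / 30.0 < 1e-6

    def test_time_rescaling_equivariance(self):
        f1 = kf.fit_activation_tau(_exp_family(tau_act=12.0, sample_interval=0.1), 60.0)
        # stretching the time axis by 2 doubles tau
        fam2 = _exp_family(tau_act=12.0, sample_interval=0.1)
        stretched = CurrentFamily(
            protocol=VoltageProtocol(step_start=60.0, step_stop=60.0, step_duration=200.0,
                                     tail_duration=300.0, sample_interval=0.2),
            sweeps=pd.DataFrame(
                {60.0: fam2.sweeps[60.0].to_numpy()},
                index=pd.Index(fam2.time * 2.0, name="time_ms"),
            ),
            capacitance=15.0,
        )
        f2 = kf.fit_activation_tau(stretched, 60.0)
        assert f2.tau == pytest.approx(2.0 * f1.tau, rel=1e-6)

    def test_current_rescaling_invariance(self):
        fam = _exp_family(tau_act=12.0)
        scaled = CurrentFamily(protocol=fam.protocol, sweeps=fam.sweeps * 3.5,
                               capacitance=fam.capacitance)
        f1 = kf.fit_activation_tau(fam, 60.0)
        f2 = kf.fit_activation_tau(scaled, 60.0)
        assert f2.tau == pytest.approx(f1.tau, rel=1e-8)
        assert f2.amplitude == pytest.approx(3.5 * f1.amplitude, rel=1e-8)

    def test_constant_tail_flagged_degenerate(self):
        fam = _constant_family(step_value=100.0)
        fit = kf.fit_deactivation_tau(fam, -70.0)
        assert not fit.converged

    def test_simulated_gating_tau_recovery(self, default_scenario, default_family):
        gp = default_scenario.gating
        fa = kf.fit_activation_tau(default_family, 60.0)
        fd = kf.fit_deactivation_tau(default_family, 60.0)
        assert fa.converged and fd.converged
        assert fa.tau == pytest.approx(gp.tau_act_at(60.0), rel=0.05)
        assert fd.tau == pytest.approx(gp.tau_deact, rel=0.05)


class TestAnalyzeFamily:
    def test_default_scenario_bundle(self, default_scenario, default_family):
        res = kf.analyze_family(default_family, {"count": {}})
        gp = default_scenario.gating
        assert res.boltzmann.converged
        assert res.boltzmann.v_half == pytest.approx(gp.v_half, abs=1.5)
        assert res.boltzmann.slope_k == pytest.approx(gp.slope_k, abs=1.0)
        assert res.count is not None
        assert res.count.n_channels == pytest.approx(
            default_scenario.channel.n_channels, rel=0.05
        )
        assert len(res.iv) == len(default_family.protocol.step_voltages)
        assert res.provenance["capacitance_pF"] == default_family.capacitance
        d = res.to_dict()
        assert "boltzmann" in d and "channel_count" in d

    def test_programmed_density_difference_at_plus60(self):
        """Two groups whose channel number differs by 38% differ by
        38 +/- 3% in current density at +60 mV."""
        from kvflux.config import scenario_from_dict

        dens = {}
        for n in (3510, 4840):
            fam = kf.simulate_current_family(scenario_from_dict({"n_channels": n, "seed": 5}))
            iv = kf.extract_steady_state(fam)
            dens[n] = float(iv.loc[iv["step_v"] == 60.0, "density_pA_per_pF"].iloc[0])
        pct = kf.percent_change(dens[3510], dens[4840])
        assert pct == pytest.approx(37.9, abs=3.0)

    def test_empty_family_rejected(self):
        with pytest.raises(ProtocolError):
            CurrentFamily(protocol=VoltageProtocol(), sweeps=pd.DataFrame(),
                          capacitance=15.0)

    def test_stage_errors_carry_stage_label(self, default_family):
        with pytest.raises(StageError) as exc:
            kf.analyze_family(default_family, {"steady_state_window_ms": (500.0, 600.0)})
        assert exc.value.stage == "steady_state"

    def test_unknown_config_key_rejected(self, default_family):
        with pytest.raises(InvalidInputError):
            kf.analyze_family(default_family, {"bogus": 1})
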