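"""Reservoir ODE solution, diastolic decay fit and R_prox*C identification."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import pulsewk as pw
from pulsewk.reservoir_model import (BeatFlagged, fit_diastolic_decay,
                                     identify_rproxc, reservoir_ode_residual,
                                     solve_reservoir_pressure)

from conftest import TRUE_PMSF, TRUE_RC, TRUE_RPROXC, TRUE_SV


# ---------------------------------------------------------------------------
# solve_reservoir_pressure
# ---------------------------------------------------------------------------

def random_smooth_pressure(rng, fs=200.0, duration=1.5):
    """Band-limited random pressure: a few low-frequency harmonics."""
    t = np.arange(int(duration * fs)) / fs
    p = np.full(t.size, rng.uniform(60, 100))
    for _ in range(rng.integers(2, 6)):
        f = rng.uniform(0.5, 8.0)
        p = p + rng.uniform(1, 12) * np.sin(2 * np.pi * f * t + rng.uniform(0, 7))
    return t, p


def reference_reservoir(t, p, fs, rc, rproxc, p_msf, p0):
    """Adaptive high-accuracy integration with linearly interpolated forcing."""
    beta = 1.0 / rproxc + 1.0 / rc

    def rhs(s, y):
        pa = np.interp(s, t, p)
        return -beta * y + pa / rproxc + p_msf / rc

    sol = solve_ivp(rhs, (t[0], t[-1]), [p0], t_eval=t, method="LSODA",
                    rtol=1e-10, atol=1e-12, max_step=1.0 / fs)
    return sol.y[0]


class TestSolveReservoirPressure:
    def test_equilibrium_is_a_fixed_point(self):
        p = np.full(300, TRUE_PMSF)
        out = solve_reservoir_pressure(p, 200.0, TRUE_RC, TRUE_RPROXC,
                                       TRUE_PMSF, p0=TRUE_PMSF)
        np.testing.assert_allclose(out, TRUE_PMSF, rtol=0, atol=1e-10)

    def test_ode_residual_small_on_smooth_input(self):
        # heart-rate-scale harmonics: the finite-difference residual is an
        # O(h^2 f''') diagnostic, so the check needs band-limited content
        rng = np.random.default_rng(5)
        t = np.arange(300) / 200.0
        p = np.full(t.size, 85.0)
        for _ in range(3):
            f = rng.uniform(0.5, 2.5)
            p = p + rng.uniform(2, 10) * np.sin(2 * np.pi * f * t + rng.uniform(0, 7))
        out = solve_reservoir_pressure(p, 200.0, TRUE_RC, TRUE_RPROXC, TRUE_PMSF)
        resid = reservoir_ode_residual(out, p, 200.0, TRUE_RC, TRUE_RPROXC,
                                       TRUE_PMSF)
        # interior samples only: np.gradient is first-order at the ends
        assert np.max(np.abs(resid[2:-2])) < 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_adaptive_reference_integrator(self, seed):
        rng = np.random.default_rng(seed)
        t, p = random_smooth_pressure(rng)
        rc = rng.uniform(0.3, 3.0)
        rproxc = rng.uniform(0.01, 0.15)
        mine = solve_reservoir_pressure(p, 200.0, rc, rproxc, TRUE_PMSF)
        ref = reference_reservoir(t, p, 200.0, rc, rproxc, TRUE_PMSF, p[0])
        assert np.max(np.abs(mine - ref)) < 0.05

    def test_nonpositive_time_constants_rejected(self):
        p = np.full(50, 80.0)
        with pytest.raises(ValueError):
            solve_reservoir_pressure(p, 200.0, -1.0, 0.05, 20.0)
        with pytest.raises(ValueError):
            solve_reservoir_pressure(p, 200.0, 1.0, 0.0, 20.0)


# ---------------------------------------------------------------------------
# fit_diastolic_decay
# ---------------------------------------------------------------------------

def synthetic_decay_beat(rc=TRUE_RC, p_msf=TRUE_PMSF, amp=60.0, fs=200.0,
                         noise=0.0, rng=None, n_dia=80):
    """A stylised beat: linear upstroke, brief peak, exponential diastole."""
    n_sys = 50
    t = np.arange(n_sys + n_dia) / fs
    p_sys = np.linspace(p_msf + 40.0, p_msf + amp, n_sys)
    x = (np.arange(n_dia) + 1) / fs
    p_dia = amp * np.exp(-x / rc) + p_msf
    p = np.concatenate([p_sys, p_dia])
    if noise:
        p = p + rng.normal(0, noise, p.size)
    t_d = t[n_sys]
    return pw.Beat(t=t, p=p, fs=fs, t0=0.0, t_peak=float(t[n_sys - 1]),
                   t_d=float(t_d), t_f=float(t[-1] + 1 / fs))


class TestFitDiastolicDecay:
    def test_noiseless_exponential_recovered_to_1e6(self):
        beat = synthetic_decay_beat(rc=0.886, p_msf=20.0)
        fit = fit_diastolic_decay(beat)
        assert fit.rc == pytest.approx(0.886, rel=1e-6)
        assert fit.p_msf == pytest.approx(20.0, rel=1e-6)
        assert fit.rmse < 1e-8

    def test_constant_window_flagged_unidentifiable(self):
        fs = 200.0
        t = np.arange(130) / fs
        p = np.concatenate([np.linspace(60, 100, 50), np.full(80, 20.0)])
        beat = pw.Beat(t=t, p=p, fs=fs, t0=0.0, t_peak=float(t[49]),
                       t_d=float(t[50]), t_f=float(t[-1] + 1 / fs))
        with pytest.raises(BeatFlagged, match="decay"):
            fit_diastolic_decay(beat)

    def test_monte_carlo_noisy_rc_recovery(self):
        # 0.6 s diastolic window (slow heart rate): RC identifiability from a
        # noisy partial decay improves steeply with window length
        rng = np.random.default_rng(21)
        errors = []
        for _ in range(200):
            beat = synthetic_decay_beat(noise=0.5, rng=rng, n_dia=120)
            try:
                fit = fit_diastolic_decay(beat)
            except BeatFlagged:
                continue
            errors.append(abs(fit.rc / TRUE_RC - 1.0))
        assert len(errors) > 150
        assert np.median(errors) < 0.05


# ---------------------------------------------------------------------------
# identify_rproxc and decompose_beat
# ---------------------------------------------------------------------------

class TestIdentifyRproxc:
    def test_table2_beat_recovered_within_2pct(self, clean_decomposition):
        _, ident, _ = clean_decomposition
        assert ident.rproxc == pytest.approx(TRUE_RPROXC, rel=0.02)

    def test_flow_balance_at_tau(self, clean_decomposition, true_params):
        beat, ident, decomp = clean_decomposition
        flows = pw.compute_flows(decomp, true_params)
        q_in_tau = np.interp(ident.tau, flows.t, flows.q_in)
        q_out_tau = np.interp(ident.tau, flows.t, flows.q_out)
        assert abs(q_in_tau - q_out_tau) / np.max(flows.q_in) < 1e-3

    def test_tau_inside_systolic_window(self, clean_decomposition):
        beat, ident, _ = clean_decomposition
        assert beat.t_peak < ident.tau < beat.t_d

    def test_monotone_rising_systole_flagged(self):
        # reservoir pressure keeps rising to t_d: no interior maximum
        beat = synthetic_decay_beat()
        fit = fit_diastolic_decay(beat)
        rising = pw.Beat(t=beat.t, p=beat.p, fs=beat.fs, t0=beat.t0,
                         t_peak=float(beat.t[5]), t_d=beat.t_d, t_f=beat.t_f)
        with pytest.raises(BeatFlagged):
            identify_rproxc(rising, fit)


class TestDecomposeBeat:
    def test_identity_to_machine_precision(self, clean_decomposition):
        _, _, decomp = clean_decomposition
        np.testing.assert_array_equal(decomp.p_res + decomp.p_ex, decomp.p_ao)

    def test_diastolic_excess_pressure_near_zero(self, clean_decomposition):
        beat, _, decomp = clean_decomposition
        pulse = beat.p.max() - beat.p.min()
        dia = decomp.p_ex[beat.t >= beat.t_d + 0.02]
        assert np.mean(np.abs(dia)) < 0.01 * pulse

    def test_reservoir_meets_decay_curve_at_valve_closure(
            self, clean_decomposition):
        beat, ident, decomp = clean_decomposition
        fit = fit_diastolic_decay(beat)
        decay_at_td = fit.amplitude + fit.p_msf
        p_res_at_td = decomp.p_res[beat.index_of(beat.t_d)]
        assert abs(p_res_at_td - decay_at_td) < 0.5

    def test_msf_never_above_reservoir(self, clean_decomposition):
        _, ident, decomp = clean_decomposition
        assert np.all(decomp.p_res >= ident.p_msf - 1e-9)

    def test_flagged_beat_reports_reason(self):
        fs = 200.0
        t = np.arange(120) / fs
        p = 80 + 30 * np.sin(2 * np.pi * t / t[-1]) ** 2
        beat = pw.Beat(t=t, p=p, fs=fs, t0=0.0, t_peak=float(t[30]),
                       t_d=float(t[60]), t_f=float(t[-1] + 1 / fs))
        ident, decomp = pw.decompose_beat(beat)
        if not ident.converged:
            assert ident.reason
            assert decomp is None


class TestComputeFlows:
    def test_zero_excess_gives_zero_inflow(self, true_params):
        t = np.arange(10) / 200.0
        decomp = pw.ReservoirDecomposition(t=t, p_ao=np.full(10, 80.0),
                                           p_res=np.full(10, 80.0),
                                           p_ex=np.zeros(10))
        flows = pw.compute_flows(decomp, true_params)
        np.testing.assert_array_equal(flows.q_in, 0.0)

    def test_reservoir_at_msf_gives_zero_outflow(self, true_params):
        t = np.arange(10) / 200.0
        p_res = np.full(10, true_params.p_msf)
        decomp = pw.ReservoirDecomposition(t=t, p_ao=p_res, p_res=p_res,
                                           p_ex=np.zeros(10))
        flows = pw.compute_flows(decomp, true_params)
        np.testing.assert_array_equal(flows.q_out, 0.0)

    def test_recovers_true_inflow_within_3pct_of_peak(
            self, sim_clean, clean_decomposition, true_params):
        beat, ident, decomp = clean_decomposition
        flows = pw.compute_flows(decomp, true_params)
        # phase the true inflow from the simulator's beat start (the detected
        # onset may sit one sample before ejection begins)
        truth = sim_clean.truth
        t0_true = truth.t0.iloc[(truth.t0 - beat.t0).abs().idxmin()]
        q_true = pw.inflow_profile(TRUE_SV, 60.0 / 90.0, 0.375)(beat.t - t0_true)
        assert np.max(np.abs(flows.q_in - q_true)) < 0.03 * q_true.max()

    def test_mass_balance_over_one_cycle(self, clean_decomposition, true_params):
        _, _, decomp = clean_decomposition
        flows = pw.compute_flows(decomp, true_params)
        v_in = np.trapezoid(flows.q_in, flows.t)
        v_out = np.trapezoid(flows.q_out, flows.t)
        assert v_in == pytest.approx(v_out, rel=0.02)


def test_parameter_recovery_across_physiological_ranges():
    """RC and R_prox*C recovered beat-wise over a span of Windkessel triples."""
    rng = np.random.default_rng(123)
    for _ in range(12):
        r = rng.uniform(1.0, 3.0)
        c = rng.uniform(0.3, 1.0)
        r_prox = rng.uniform(0.03, 0.15)
        params = pw.WindkesselParams(r=r, c=c, r_prox=r_prox, p_msf=20.0)
        ds = pw.simulate_recording(pw.SimulationConfig(params=params,
                                                       sv_trend=(TRUE_SV,) * 8))
        beats = pw.split_beats(ds.pressure)
        ident, _ = pw.decompose_beat(beats[len(beats) // 2])
        assert ident.converged, ident.reason
        assert ident.rc == pytest.approx(r * c, rel=0.02)
        assert ident.rproxc == pytest.approx(r_prox * c, rel=0.05)
        assert ident.beta == pytest.approx(1 / ident.rproxc + 1 / ident.rc)
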