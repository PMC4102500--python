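"""Forward three-element Windkessel simulator with exact ground truth.

The simulator drives the Windkessel balance

    C dP_res/dt = Q_in(t) - (P_res - P_msf)/R,
    P_ao = P_res + R_prox * Q_in,

with a parametric systolic inflow: a half-sine ejection over the systolic
fraction of each cycle, zero during diastole, whose peak is chosen so the
inflow integrates exactly to the prescribed per-beat stroke volume
(Q_peak = pi * SV / (2 * T_sys)).  Because the forcing is piecewise
sine/zero, the ODE has a closed-form solution within each beat, which is
evaluated directly on the sample grid -- the emitted pressure is exact to
machine precision and the per-beat truth (SV, valve-closure time t_d,
zero-net-flow time tau) is analytic, independent of any integration step.

A matching synthetic left-ventricular volume trace is emitted whose
per-beat max-min equals the prescribed SV, and per-beat SV staircases
emulate the stepwise preload reductions produced by PEEP recruitment
manoeuvres.  Gaussian measurement noise is added to the sampled pressure
only.

Defaults place the simulator in the reported porcine operating regime:
R = 1.663 mmHg.s/ml, C = 0.533 ml/mmHg, R_prox = 0.088 mmHg.s/ml, a median
SV of 25.3 ml, and P_msf = 20 mmHg with HR 90 bpm so the mean pressure
lands near the reported median MAP of ~84 mmHg (MAP ~ P_msf + R*SV*HR/60).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .reservoir_model import WindkesselParams
from .waveform_io import PressureWaveform, VolumeWaveform

#: defaults for the porcine-like operating point
DEFAULT_PARAMS = WindkesselParams(r=1.663, c=0.533, r_prox=0.088, p_msf=20.0)
DEFAULT_HEART_RATE = 90.0        # bpm
DEFAULT_SYSTOLIC_FRACTION = 0.375
DEFAULT_SV_ML = 25.3
DEFAULT_FS = 200.0               # Hz
DEFAULT_WARMUP_BEATS = 5
#: end-diastolic volume of the synthetic LV trace (ml)
DEFAULT_EDV_ML = 60.0


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulated multi-beat recording."""

    params: WindkesselParams = DEFAULT_PARAMS
    heart_rate: float = DEFAULT_HEART_RATE            # bpm
    systolic_fraction: float = DEFAULT_SYSTOLIC_FRACTION
    sv_trend: tuple = (DEFAULT_SV_ML,) * 30           # per-beat target SV (ml)
    fs: float = DEFAULT_FS                            # Hz
    noise_sigma: float = 0.0                          # mmHg
    seed: int = 0
    warmup_beats: int = DEFAULT_WARMUP_BEATS

    def __post_init__(self) -> None:
        object.__setattr__(self, "sv_trend", tuple(float(s) for s in self.sv_trend))
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        if not (0.2 <= self.systolic_fraction <= 0.5):
            raise ValueError("systolic fraction must lie in [0.2, 0.5]")
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")
        if len(self.sv_trend) == 0 or any(s <= 0 for s in self.sv_trend):
            raise ValueError("all SV targets must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.warmup_beats < 0:
            raise ValueError("warmup_beats must be non-negative")

    @property
    def period(self) -> float:
        """Cardiac cycle length (s)."""
        return 60.0 / self.heart_rate

    @property
    def t_sys(self) -> float:
        """Systolic (ejection) duration (s)."""
        return self.systolic_fraction * self.period


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated recording plus exact per-beat ground truth."""

    pressure: PressureWaveform
    volume: VolumeWaveform
    truth: pd.DataFrame   # beat_index, t0, sv_true_ml, t_d_true_s, tau_true_s, R, C, R_prox, P_msf
    config: SimulationConfig


def inflow_profile(sv: float, period: float, systolic_fraction: float):
    """Half-sine ejection profile integrating exactly to ``sv``.

    Returns a vectorised callable Q_in(t) for t in [0, period), with
    Q_peak = pi*sv/(2*T_sys) over the ejection window [0, T_sys] and zero
    during diastole.
    """
    if sv < 0 or period <= 0 or not (0 < systolic_fraction < 1):
        raise ValueError("inflow profile requires sv >= 0, period > 0, "
                         "0 < systolic_fraction < 1")
    t_sys = systolic_fraction * period
    q_peak = np.pi * sv / (2.0 * t_sys)
    omega = np.pi / t_sys

    def q_in(t):
        t = np.asarray(t, dtype=float)
        return np.where((t >= 0) & (t <= t_sys), q_peak * np.sin(omega * t), 0.0)

    return q_in


def sv_staircase(levels, beats_per_level: int):
    """Piecewise-constant per-beat SV sequence (PEEP-recruitment-like steps)."""
    levels = [float(v) for v in levels]
    if any(v <= 0 for v in levels):
        raise ValueError("all SV levels must be positive")
    if beats_per_level < 1:
        raise ValueError("beats_per_level must be >= 1")
    return tuple(v for v in levels for _ in range(beats_per_level))


def _beat_coefficients(cfg: SimulationConfig, sv: float):
    """Closed-form pieces of the reservoir solution within one beat.

    Systole (0 <= u <= T_sys), forcing k*sin(omega*u) with k = Q_peak/C:
        P_res(u) = P_msf + A sin(omega u) + B cos(omega u)
                   + (P0 - P_msf - B) exp(-a u),
    with a = 1/(RC), A = k a/(a^2+omega^2), B = -k omega/(a^2+omega^2).
    Diastole: pure exponential relaxation toward P_msf.
    """
    p = cfg.params
    a = 1.0 / (p.r * p.c)
    t_sys = cfg.t_sys
    omega = np.pi / t_sys
    q_peak = np.pi * sv / (2.0 * t_sys)
    k = q_peak / p.c
    denom = a * a + omega * omega
    coef_a = k * a / denom
    coef_b = -k * omega / denom
    return a, omega, q_peak, coef_a, coef_b, t_sys


def _reservoir_in_beat(u, p0, cfg, sv):
    """Reservoir pressure at beat-local times u, starting from P_res = p0."""
    p = cfg.params
    a, omega, _, ca, cb, t_sys = _beat_coefficients(cfg, sv)
    u = np.asarray(u, dtype=float)
    sys_mask = u <= t_sys
    out = np.empty_like(u)
    out[sys_mask] = (p.p_msf + ca * np.sin(omega * u[sys_mask])
                     + cb * np.cos(omega * u[sys_mask])
                     + (p0 - p.p_msf - cb) * np.exp(-a * u[sys_mask]))
    # value at end of ejection seeds the diastolic decay
    p_end = (p.p_msf + cb * np.cos(np.pi) + (p0 - p.p_msf - cb) * np.exp(-a * t_sys))
    out[~sys_mask] = p.p_msf + (p_end - p.p_msf) * np.exp(-a * (u[~sys_mask] - t_sys))
    return out


def _true_tau(p0: float, cfg: SimulationConfig, sv: float):
    """Beat-local time where dP_res/dt = 0 (inflow equals outflow), if any."""
    p = cfg.params
    a, omega, _, ca, cb, t_sys = _beat_coefficients(cfg, sv)

    def dpdt(u):
        return (omega * ca * np.cos(omega * u) - omega * cb * np.sin(omega * u)
                - a * (p0 - p.p_msf - cb) * np.exp(-a * u))

    lo, hi = 0.5 * t_sys, t_sys - 1e-12
    if dpdt(lo) > 0 > dpdt(hi):
        return float(brentq(dpdt, lo, hi, xtol=1e-12))
    # fall back to a scan over the whole ejection window
    u = np.linspace(1e-9, t_sys - 1e-9, 2001)
    d = dpdt(u)
    sign_change = np.flatnonzero(np.diff(np.sign(d)) < 0)
    if sign_change.size:
        i = sign_change[-1]
        return float(brentq(dpdt, u[i], u[i + 1], xtol=1e-12))
    return np.nan


def simulate_recording(config: SimulationConfig) -> SimulatedDataset:
    """Simulate a multi-beat aortic pressure + LV volume recording.

    Warm-up beats (at the first SV level) are run first and discarded so the
    emitted recording starts in periodic steady state at t = 0.  Per-beat
    ground truth records the exact prescribed SV, the valve-closure time
    (end of ejection) and the zero-net-flow time tau.
    """
    p = config.params
    period = config.period
    t_sys = config.t_sys
    n_beats = len(config.sv_trend)

    # The beat map P_res(start) -> P_res(end) is affine for this linear ODE,
    # so the periodic steady state is its fixed point b/(1 - a); starting
    # there makes the discarded warm-up beats exactly periodic already.
    u_end = np.array([period - 1e-15])
    sv0 = config.sv_trend[0]
    y0 = float(_reservoir_in_beat(u_end, 0.0, config, sv0)[0])
    y1 = float(_reservoir_in_beat(u_end, 1.0, config, sv0)[0])
    slope = y1 - y0
    p_res0 = y0 / (1.0 - slope) if slope < 1.0 else p.p_msf
    for _ in range(config.warmup_beats):
        p_res0 = float(_reservoir_in_beat(u_end, p_res0, config, sv0)[0])

    total = n_beats * period
    n_samples = int(np.floor(total * config.fs))
    t = np.arange(n_samples) / config.fs
    p_ao = np.empty(n_samples)
    vol = np.empty(n_samples)
    truth_rows = []

    p0 = p_res0
    for b, sv in enumerate(config.sv_trend):
        t0 = b * period
        sel = (t >= t0) & (t < t0 + period)
        u = t[sel] - t0
        q = inflow_profile(sv, period, config.systolic_fraction)(u)
        p_res = _reservoir_in_beat(u, p0, config, sv)
        p_ao[sel] = p_res + p.r_prox * q
        if np.any(~np.isfinite(p_ao[sel])):
            raise FloatingPointError("forward simulation diverged (non-physical config)")

        # LV volume: eject the cumulative inflow, refill smoothly in diastole
        omega = np.pi / t_sys
        ejected = np.where(u <= t_sys, sv * 0.5 * (1.0 - np.cos(omega * u)), sv)
        t_dia = period - t_sys
        refill = np.where(u > t_sys,
                          sv * 0.5 * (1.0 - np.cos(np.pi * (u - t_sys) / t_dia)), 0.0)
        vol[sel] = DEFAULT_EDV_ML - ejected + refill

        tau_local = _true_tau(p0, config, sv)
        truth_rows.append({
            "beat_index": b,
            "t0": t0,
            "sv_true_ml": sv,
            "t_d_true_s": t0 + t_sys,
            "tau_true_s": t0 + tau_local if np.isfinite(tau_local) else np.nan,
            "R": p.r, "C": p.c, "R_prox": p.r_prox, "P_msf": p.p_msf,
        })
        p0 = float(_reservoir_in_beat(np.array([period - 1e-15]), p0, config, sv)[0])

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        p_ao = p_ao + rng.normal(0.0, config.noise_sigma, size=n_samples)

    pressure = PressureWaveform(t=t, p=p_ao, fs=config.fs)
    volume = VolumeWaveform(t=t, v=vol, fs=config.fs)
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(pressure=pressure, volume=volume, truth=truth,
                            config=config)
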