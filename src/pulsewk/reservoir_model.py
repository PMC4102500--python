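"""Reservoir-excess decomposition of aortic pressure under a three-element Windkessel.

Aortic pressure is modelled as the sum of a *reservoir* pressure P_res,
driven by elastic storage and release of the arterial walls, and an
*excess* pressure P_ex = P_ao - P_res proportional to the aortic inflow,

    P_ex = R_prox * Q_in,

where R_prox is the characteristic impedance.  The reservoir obeys the
Windkessel balance  C dP_res/dt = Q_in - (P_res - P_msf)/R, which combines
with the excess-pressure relation into a linear ODE driven by P_ao alone:

    dP_res/dt + beta * P_res = P_ao/(R_prox C) + P_msf/(R C),
    beta = 1/(R_prox C) + 1/(R C).

The decomposition therefore depends only on the two time constants RC and
R_prox*C and on the mean systemic filling pressure P_msf, all of which are
identifiable per beat from the pressure contour:

* RC and P_msf from the exponential diastolic decay (zero inflow after
  aortic valve closure at t_d),
* R_prox*C from the zero-net-flow condition: between the pressure peak and
  t_d there is an instant tau where inflow equals outflow, i.e. the
  reservoir pressure is stationary.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import expm1

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import lfilter

from .waveform_io import Beat

#: seconds trimmed from the start of the diastolic window to avoid
#: valve-closure (dicrotic notch) ringing
DIASTOLE_TRIM_S = 0.02
#: minimum number of samples required in the diastolic fit window
MIN_DIASTOLE_SAMPLES = 10
#: search bounds for the diastolic time constant RC (s)
RC_BOUNDS = (0.1, 10.0)
#: R_prox*C search bracket: [RPROXC_MIN, RPROXC_MAX_FRAC * RC]
RPROXC_MIN = 1e-3
RPROXC_MAX_FRAC = 0.9


class BeatFlagged(RuntimeError):
    """A beat failed identification and is excluded from SV output."""


@dataclass(frozen=True)
class WindkesselParams:
    """Full three-element Windkessel triple plus mean systemic filling pressure.

    Units: r, r_prox in mmHg.s/ml; c in ml/mmHg; p_msf in mmHg.  Parameters
    are treated as constant within a single heartbeat.
    """

    r: float
    c: float
    r_prox: float
    p_msf: float

    def __post_init__(self) -> None:
        for name in ("r", "c", "r_prox"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.p_msf < 0:
            raise ValueError("p_msf must be non-negative")

    @property
    def rc(self) -> float:
        """Diastolic time constant R*C (s)."""
        return self.r * self.c

    @property
    def rproxc(self) -> float:
        """Proximal time constant R_prox*C (s)."""
        return self.r_prox * self.c

    @property
    def beta(self) -> float:
        """Decay rate of the reservoir ODE, 1/(R_prox C) + 1/(R C) (1/s)."""
        return 1.0 / self.rproxc + 1.0 / self.rc


@dataclass(frozen=True)
class DiastolicFit:
    """Result of the diastolic decay fit ``A exp(-(t-t_d)/RC) + P_msf``."""

    rc: float         # diastolic time constant (s)
    p_msf: float      # mean systemic filling pressure (mmHg)
    amplitude: float  # decay amplitude A at t_d (mmHg)
    rmse: float       # fit residual (mmHg)


@dataclass(frozen=True)
class IdentifiedBeatParams:
    """Per-beat identifiable quantities and fit diagnostics."""

    rc: float                  # diastolic time constant (s)
    rproxc: float              # proximal time constant (s)
    p_msf: float               # mean systemic filling pressure (mmHg)
    beta: float                # 1/rproxc + 1/rc (1/s)
    tau: float                 # zero-net-flow time (absolute s)
    diastolic_fit_rmse: float  # mmHg
    converged: bool
    reason: str = ""


@dataclass(frozen=True)
class ReservoirDecomposition:
    """Reservoir/excess pressure split on the beat's sample grid (mmHg)."""

    t: np.ndarray
    p_ao: np.ndarray
    p_res: np.ndarray
    p_ex: np.ndarray


@dataclass(frozen=True)
class FlowSeries:
    """Aortic inflow and compartment outflow (ml/s) on the beat's grid."""

    t: np.ndarray
    q_in: np.ndarray
    q_out: np.ndarray


# ---------------------------------------------------------------------------
# Reservoir ODE solution
# ---------------------------------------------------------------------------

def solve_reservoir_pressure(p_ao: np.ndarray, fs: float, rc: float, rproxc: float,
                             p_msf: float, p0: float | None = None) -> np.ndarray:
    """Integrate the reservoir ODE along a sampled pressure trace.

    The forcing P_ao is treated as piecewise linear between samples, for
    which the exponential-integrator update is exact:

        P_res[i+1] = a P_res[i] + f[i] (I0 - I1) + f[i+1] I1,

    with f = P_ao/rproxc + p_msf/rc, a = exp(-beta dt),
    I0 = (1 - a)/beta and I1 = (1/beta)(1 - (1 - a)/(beta dt)).

    Parameters
    ----------
    p_ao : ndarray
        Aortic pressure samples (mmHg) on a uniform grid.
    fs : float
        Sampling rate (Hz).
    rc, rproxc : float
        Time constants (s); must be strictly positive.
    p_msf : float
        Mean systemic filling pressure (mmHg).
    p0 : float, optional
        Initial reservoir pressure; defaults to ``p_ao[0]`` (the beat foot
        lies at end-diastole where the excess pressure vanishes).
    """
    if rc <= 0 or rproxc <= 0:
        raise ValueError("time constants must be strictly positive")
    p_ao = np.asarray(p_ao, dtype=float)
    if p_ao.ndim != 1 or p_ao.size < 2:
        raise ValueError("p_ao must be a 1-D array with at least 2 samples")
    dt = 1.0 / fs
    beta = 1.0 / rproxc + 1.0 / rc
    x = beta * dt
    a = np.exp(-x)
    one_minus_a = -expm1(-x)
    i0 = one_minus_a / beta
    i1 = (1.0 - one_minus_a / x) / beta

    f = p_ao / rproxc + p_msf / rc
    b = f[:-1] * (i0 - i1) + f[1:] * i1
    p_start = float(p_ao[0]) if p0 is None else float(p0)
    # linear recurrence y[n] = b[n] + a*y[n-1], y[-1] = p_start
    tail, _ = lfilter([1.0], [1.0, -a], b, zi=np.array([a * p_start]))
    out = np.empty_like(p_ao)
    out[0] = p_start
    out[1:] = tail
    return out


def reservoir_ode_residual(p_res: np.ndarray, p_ao: np.ndarray, fs: float,
                           rc: float, rproxc: float, p_msf: float) -> np.ndarray:
    """Finite-difference residual of the reservoir ODE (mmHg/s), for diagnostics."""
    beta = 1.0 / rproxc + 1.0 / rc
    dpdt = np.gradient(p_res, 1.0 / fs)
    return dpdt + beta * p_res - p_ao / rproxc - p_msf / rc


# ---------------------------------------------------------------------------
# Diastolic decay fit: RC and P_msf
# ---------------------------------------------------------------------------

def _decay_model(x, rc, p_msf, amp):
    return amp * np.exp(-x / rc) + p_msf


def fit_diastolic_decay(beat: Beat, trim_s: float = DIASTOLE_TRIM_S,
                        min_samples: int = MIN_DIASTOLE_SAMPLES) -> DiastolicFit:
    """Fit the diastolic pressure decay; returns RC, P_msf, amplitude and RMSE.

    After valve closure the inflow is zero, so the reservoir (and hence the
    measured aortic) pressure relaxes exponentially toward P_msf with time
    constant RC.  The window ``[t_d + trim, t_f)`` is fitted with
    ``A exp(-(t - t_d)/RC) + P_msf`` by bounded nonlinear least squares; the
    amplitude A is a free parameter so a small error in locating t_d does
    not bias the fit.

    Raises
    ------
    BeatFlagged
        If the window is too short, does not decay, or the fit fails.
    """
    sel = (beat.t >= beat.t_d + trim_s) & (beat.t < beat.t_f)
    tw = beat.t[sel]
    pw = beat.p[sel]
    if tw.size < min_samples:
        raise BeatFlagged(f"diastolic window has {tw.size} < {min_samples} samples")
    x = tw - beat.t_d
    pmin, pmax = float(pw.min()), float(pw.max())
    spread = pmax - pmin
    slope = float(np.polyfit(x, pw, 1)[0])
    if slope >= 0.0 or spread <= 1e-9:
        raise BeatFlagged("diastolic window does not decay (RC unidentifiable)")

    lo = np.array([RC_BOUNDS[0], 0.0, 1e-9])
    hi = np.array([RC_BOUNDS[1], pmin, np.inf])

    def initial_guesses():
        for frac in (0.0, 0.5, 0.9):
            pm0 = frac * pmin
            amp0 = max(pw[0] - pm0, 1e-6)
            y = np.log(np.maximum(pw - pm0, 1e-9))
            s = float(np.polyfit(x, y, 1)[0])
            rc0 = -1.0 / s if s < 0 else 1.0
            rc0 = float(np.clip(rc0, RC_BOUNDS[0], RC_BOUNDS[1]))
            yield [rc0, min(pm0, pmin), amp0]

    best = None
    for p0 in initial_guesses():
        try:
            popt, _ = curve_fit(_decay_model, x, pw, p0=p0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except (RuntimeError, ValueError):
            continue
        resid = _decay_model(x, *popt) - pw
        sse = float(resid @ resid)
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise BeatFlagged("diastolic decay fit did not converge")
    (rc, p_msf, amp), sse = best
    if amp <= 0 or rc <= 0:
        raise BeatFlagged("diastolic decay fit degenerate")
    rmse = float(np.sqrt(sse / pw.size))
    # sanity: fit must explain the decay better than a flat line
    if rmse > max(0.5 * spread, 1e-6) and rmse > 5.0:
        raise BeatFlagged(f"diastolic fit rmse {rmse:.2f} mmHg too large")
    return DiastolicFit(rc=float(rc), p_msf=float(p_msf), amplitude=float(amp),
                        rmse=rmse)


# ---------------------------------------------------------------------------
# Zero-net-flow identification of R_prox*C
# ---------------------------------------------------------------------------

def identify_rproxc(beat: Beat, fit: DiastolicFit, rel_tol: float = 1e-6,
                    n_scan: int = 25,
                    continuity_offset_s: float = 0.01,
                    continuity_width_s: float = 0.025):
    """Identify R_prox*C from valve-closure continuity and zero net flow.

    During diastole the fitted decay curve ``D(t) = A exp(-(t-t_d)/RC) +
    P_msf`` is an exact solution of the reservoir ODE whatever R_prox*C is,
    so the diastolic tail itself cannot distinguish candidates; the
    identifying condition is that the reservoir pressure integrated through
    systole arrives on the decay curve at valve closure.  The continuity
    residual is evaluated as the mean of ``P_res - D`` over a short window
    starting ``continuity_offset_s`` after the detected t_d (so that a
    detection landing a sample or two early, while inflow has not quite
    ceased, does not bias the root) and ``continuity_width_s`` long (short
    against the post-closure relaxation rate beta, which is what carries
    the R_prox*C information).

    The residual has a single sign change in R_prox*C (small values
    over-track the still-elevated measured pressure, large values
    under-charge the reservoir), located by a coarse logarithmic scan and
    refined by bisection to relative width ``rel_tol``.  The zero-net-flow
    time tau -- where inflow equals outflow and the reservoir pressure is
    maximal -- is then read off inside (t_peak, t_d), refined to sub-sample
    precision by parabolic interpolation; a beat whose reservoir pressure
    has no interior maximum is flagged.

    Returns ``(rproxc, tau)``; raises :class:`BeatFlagged` on failure.
    """
    rc, p_msf = fit.rc, fit.p_msf
    i_peak = beat.index_of(beat.t_peak)
    i_d = beat.index_of(beat.t_d)
    if i_d - i_peak < 3:
        raise BeatFlagged("systolic window (t_peak, t_d) too short")
    lo, hi = RPROXC_MIN, RPROXC_MAX_FRAC * rc
    if hi <= lo:
        raise BeatFlagged("RC too small to bracket R_prox*C")
    p = beat.p
    fs = beat.fs
    w0 = i_d + max(1, int(round(continuity_offset_s * fs)))
    w1 = min(p.size, w0 + max(2, int(round(continuity_width_s * fs))))
    if w1 - w0 < 2:
        raise BeatFlagged("diastole too short for the continuity window")
    widx = np.arange(w0, w1)
    decay = _decay_model(beat.t[widx] - beat.t_d, rc, p_msf, fit.amplitude)

    def solve(rproxc: float) -> np.ndarray:
        return solve_reservoir_pressure(p, fs, rc, rproxc, p_msf, p0=p[0])

    def h(rproxc: float) -> float:
        return float(np.mean(solve(rproxc)[widx] - decay))

    grid = np.geomspace(lo, hi, n_scan)
    hv = [h(x) for x in grid]
    bracket = None
    for x0, h0, x1, h1 in zip(grid, hv, grid[1:], hv[1:]):
        if h0 == 0.0:
            bracket = (x0, x0)
            break
        if np.sign(h0) != np.sign(h1):
            bracket = (x0, x1)
            break
    if bracket is None:
        raise BeatFlagged("no continuity root for R_prox*C in search bounds")
    a, b_ = bracket
    if a != b_:
        ha = h(a)
        while (b_ - a) > rel_tol * a:
            m = 0.5 * (a + b_)
            hm = h(m)
            if hm == 0.0:
                a = b_ = m
            elif np.sign(hm) == np.sign(ha):
                a, ha = m, hm
            else:
                b_ = m
    rproxc = 0.5 * (a + b_)

    p_res = solve(rproxc)
    interior = p_res[i_peak + 1:i_d]
    k = int(np.argmax(interior))
    if k == 0 or k == interior.size - 1:
        raise BeatFlagged("reservoir pressure has no interior maximum "
                          "(no zero-net-flow point in (t_peak, t_d))")
    i_tau = i_peak + 1 + k
    # parabolic vertex through the three samples around the maximum
    y0, y1, y2 = p_res[i_tau - 1], p_res[i_tau], p_res[i_tau + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    tau = float(beat.t[i_tau] + np.clip(shift, -0.5, 0.5) / fs)
    if not (beat.t_peak < tau < beat.t_d):
        raise BeatFlagged("zero-net-flow time outside (t_peak, t_d)")
    if not (0 < rproxc < rc):
        raise BeatFlagged("identified R_prox*C outside (0, RC)")
    return float(rproxc), tau


# ---------------------------------------------------------------------------
# Full per-beat decomposition
# ---------------------------------------------------------------------------

def decompose_beat(beat: Beat):
    """Identify (RC, R_prox*C, P_msf) and split the beat into P_res + P_ex.

    Returns ``(IdentifiedBeatParams, ReservoirDecomposition | None)``; a
    flagged beat carries ``converged=False`` with the failure reason and no
    decomposition.
    """
    try:
        fit = fit_diastolic_decay(beat)
        rproxc, tau = identify_rproxc(beat, fit)
    except BeatFlagged as err:
        params = IdentifiedBeatParams(
            rc=np.nan, rproxc=np.nan, p_msf=np.nan, beta=np.nan, tau=np.nan,
            diastolic_fit_rmse=np.nan, converged=False, reason=str(err))
        return params, None
    rc, p_msf = fit.rc, fit.p_msf
    beta = 1.0 / rproxc + 1.0 / rc
    p_res = solve_reservoir_pressure(beat.p, beat.fs, rc, rproxc, p_msf, p0=beat.p[0])
    p_ex = beat.p - p_res
    params = IdentifiedBeatParams(rc=rc, rproxc=rproxc, p_msf=p_msf, beta=beta,
                                  tau=tau, diastolic_fit_rmse=fit.rmse, converged=True)
    decomp = ReservoirDecomposition(t=beat.t, p_ao=beat.p, p_res=p_res, p_ex=p_ex)
    return params, decomp


def compute_flows(decomp: ReservoirDecomposition, params: WindkesselParams) -> FlowSeries:
    """Aortic inflow and outflow from a decomposition and a full parameter triple.

    q_in = P_ex / R_prox (Ohm's law across the characteristic impedance);
    q_out = (P_res - P_msf) / R (flow leaving the compartment).
    """
    if params.r_prox <= 0 or params.r <= 0:
        raise ValueError("resistances must be strictly positive")
    q_in = decomp.p_ex / params.r_prox
    q_out = (decomp.p_res - params.p_msf) / params.r
    return FlowSeries(t=decomp.t, q_in=q_in, q_out=q_out)
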