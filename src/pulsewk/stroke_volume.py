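"""Stroke volume estimation with a single fixed Windkessel parameter.

The decomposition identifies only the products RC and R_prox*C, so the
triple (R, C, R_prox) is determined up to one degree of freedom.  Fixing
any one element closes the system:

* R fixed:      C = RC / R,          R_prox = R_prox*C / C
* C fixed:      R = RC / C,          R_prox = R_prox*C / C
* R_prox fixed: C = R_prox*C / R_prox,  R = RC / C

Stroke volume is then the integral of the aortic inflow over the beat,

    SV = integral Q_in dt = (1 / R_prox) * integral P_ex dt,

evaluated with the trapezoidal rule on the sample grid.  The fixed value is
calibrated (once, population-wide) by an exhaustive grid search at 0.001
resolution over a physiological range, minimising the summed squared error
against measured SV across all analysed beats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reservoir_model import (BeatFlagged, IdentifiedBeatParams,
                              ReservoirDecomposition, WindkesselParams)

PARAM_NAMES = ("r", "c", "r_prox")

#: physiological grid-search ranges (units: R, R_prox in mmHg.s/ml; C in ml/mmHg),
#: wide enough to bracket reported optima for ~30 kg pigs with ample margin
DEFAULT_SEARCH_RANGES = {
    "r": (0.5, 4.0),
    "c": (0.1, 2.0),
    "r_prox": (0.010, 0.300),
}
#: grid resolution, in each parameter's native units
GRID_STEP = 0.001


@dataclass(frozen=True)
class FixedParameterSet:
    """The one Windkessel element held constant across beats."""

    which: str   # one of "r", "c", "r_prox"
    value: float

    def __post_init__(self) -> None:
        if self.which not in PARAM_NAMES:
            raise ValueError(f"which must be one of {PARAM_NAMES}, got {self.which!r}")
        if self.value <= 0:
            raise ValueError("fixed parameter value must be strictly positive")
        lo, hi = DEFAULT_SEARCH_RANGES[self.which]
        if not (lo <= self.value <= hi):
            warnings.warn(
                f"fixed {self.which}={self.value} outside the declared "
                f"physiological range [{lo}, {hi}]", stacklevel=2)


@dataclass(frozen=True)
class CalibrationResult:
    """Grid-search optima for the three candidate fixed parameters."""

    values: dict        # parameter name -> optimal fixed value
    objectives: dict    # parameter name -> summed squared SV error (ml^2)
    t_beats: int        # number of beats entering the objective
    ranges: dict
    step: float


def close_parameters(identified: IdentifiedBeatParams,
                     fixed: FixedParameterSet) -> WindkesselParams:
    """Reconstruct the full (R, C, R_prox, P_msf) from one fixed element."""
    if not identified.converged:
        raise BeatFlagged("cannot close parameters for a non-converged beat")
    rc, rproxc = identified.rc, identified.rproxc
    if rc <= 0 or rproxc <= 0:
        raise ValueError("identified time constants must be strictly positive")
    if fixed.which == "r":
        c = rc / fixed.value
        return WindkesselParams(r=fixed.value, c=c, r_prox=rproxc / c,
                                p_msf=identified.p_msf)
    if fixed.which == "c":
        return WindkesselParams(r=rc / fixed.value, c=fixed.value,
                                r_prox=rproxc / fixed.value, p_msf=identified.p_msf)
    c = rproxc / fixed.value
    return WindkesselParams(r=rc / c, c=c, r_prox=fixed.value, p_msf=identified.p_msf)


def excess_pressure_integral(decomp: ReservoirDecomposition) -> float:
    """Trapezoidal integral of P_ex over the beat (mmHg.s).

    Raises :class:`BeatFlagged` when the integral is negative beyond 5 % of
    the integral of |P_ex| -- a decomposition failure rather than a small
    numerical cancellation.
    """
    integ = float(np.trapezoid(decomp.p_ex, decomp.t))
    abs_integ = float(np.trapezoid(np.abs(decomp.p_ex), decomp.t))
    if integ < -0.05 * abs_integ:
        raise BeatFlagged("negative excess-pressure integral (decomposition failure)")
    return integ


def estimate_sv(decomp: ReservoirDecomposition, identified: IdentifiedBeatParams,
                fixed: FixedParameterSet) -> float:
    """Estimate one beat's stroke volume (ml) under the given closure."""
    params = close_parameters(identified, fixed)
    return excess_pressure_integral(decomp) / params.r_prox


def _sv_coefficients(integrals, rcs, rproxcs):
    """Per-beat coefficients k such that SV = k*x (C closure) or k/x (R, R_prox)."""
    a = np.asarray(integrals, dtype=float)
    rc = np.asarray(rcs, dtype=float)
    rpc = np.asarray(rproxcs, dtype=float)
    return {
        "r": a * rc / rpc,    # SV_R = (a * RC / RproxC) / R_fixed
        "c": a / rpc,         # SV_C = (a / RproxC) * C_fixed
        "r_prox": a,          # SV_Rprox = a / Rprox_fixed
    }


def calibrate_fixed_params(identified_list, decomps, sv_measured,
                           ranges=None, step: float = GRID_STEP,
                           min_beats: int = 10) -> CalibrationResult:
    """Grid-search each candidate fixed parameter against measured SV.

    For each parameter independently, the summed squared difference between
    estimated and measured SV over all converged beats is evaluated on an
    exhaustive grid at ``step`` resolution and the argmin returned.  The
    per-beat estimate reduces to ``k_b * x`` (C) or ``k_b / x`` (R, R_prox)
    with precomputed coefficients, so each scan is a closed-form quadratic
    in the grid vector.

    Parameters
    ----------
    identified_list : sequence of IdentifiedBeatParams
    decomps : sequence of ReservoirDecomposition or None
    sv_measured : array-like of per-beat measured SV (ml); NaN entries and
        non-converged beats are dropped.
    """
    ranges = dict(DEFAULT_SEARCH_RANGES if ranges is None else ranges)
    sv_measured = np.asarray(sv_measured, dtype=float)
    integrals, rcs, rpcs, meas = [], [], [], []
    for ident, decomp, m in zip(identified_list, decomps, sv_measured):
        if not ident.converged or decomp is None or not np.isfinite(m):
            continue
        try:
            a = excess_pressure_integral(decomp)
        except BeatFlagged:
            continue
        integrals.append(a)
        rcs.append(ident.rc)
        rpcs.append(ident.rproxc)
        meas.append(m)
    t_beats = len(meas)
    if t_beats < min_beats:
        raise ValueError(f"calibration needs >= {min_beats} converged paired beats, "
                         f"got {t_beats}")
    coeffs = _sv_coefficients(integrals, rcs, rpcs)
    m = np.asarray(meas, dtype=float)
    s_mm = float(m @ m)

    values, objectives = {}, {}
    for name in PARAM_NAMES:
        lo, hi = ranges[name]
        n_pts = int(round((hi - lo) / step)) + 1
        grid = np.linspace(lo, hi, n_pts)
        k = coeffs[name]
        if name == "c":  # SV = k*x: obj(x) = x^2 Sum k^2 - 2x Sum k m + Sum m^2
            obj = grid**2 * float(k @ k) - 2.0 * grid * float(k @ m) + s_mm
        else:            # SV = k/x: obj(x) = Sum k^2 / x^2 - 2 Sum k m / x + Sum m^2
            obj = float(k @ k) / grid**2 - 2.0 * float(k @ m) / grid + s_mm
        finite = np.isfinite(obj)
        if not finite.all():
            warnings.warn(f"skipping {int((~finite).sum())} non-finite grid points "
                          f"for {name}", stacklevel=2)
            obj = np.where(finite, obj, np.inf)
        i_best = int(np.argmin(obj))  # first minimum -> ties break to smaller value
        if i_best in (0, n_pts - 1):
            warnings.warn(f"calibration optimum for {name} lies on the search "
                          "boundary; consider widening the range", stacklevel=2)
        values[name] = float(grid[i_best])
        objectives[name] = float(obj[i_best])
    return CalibrationResult(values=values, objectives=objectives,
                             t_beats=t_beats, ranges=ranges, step=step)
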