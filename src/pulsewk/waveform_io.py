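"""Waveform containers, CSV I/O, artifact exclusion and beat segmentation.

The analysis operates on a continuous aortic pressure recording sampled on a
uniform time grid (the reference acquisition rate is 200 Hz).  This module
provides the containers for pressure and left-ventricular volume traces,
reads/writes the plain-CSV interchange format, drops user-flagged artifact
regions, splits a recording into individual heartbeats and annotates each
beat with the landmarks the decomposition needs:

* ``t0``     -- beat onset, the foot of the systolic upstroke,
* ``t_peak`` -- time of maximum aortic pressure,
* ``t_d``    -- diastole onset (aortic valve closure), located at the
  minimum rate of change of pressure after the systolic peak,
* ``t_f``    -- beat end, which equals the next beat's onset.

All intervals are half-open ``[t0, t_f)`` and times are absolute recording
seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: absolute tolerance (s) on the deviation of the sample grid from 1/fs
GRID_ATOL = 1e-9
#: zero-phase moving-average smoothing window (samples) used before
#: differentiating pressure; 5 samples = 25 ms at 200 Hz
SMOOTH_WINDOW = 5
#: refractory period (s) between successive upstroke (max dP/dt) detections
UPSTROKE_REFRACTORY_S = 0.25
#: plausible single-beat duration bounds (s)
MIN_BEAT_S = 0.25
MAX_BEAT_S = 2.5
#: minimum foot-to-peak pulse amplitude (mmHg) for a plausible aortic beat
MIN_PULSE_MMHG = 10.0


def _validate_grid(t: np.ndarray, v: np.ndarray, fs: float) -> None:
    if t.ndim != 1 or v.shape != t.shape:
        raise ValueError("time and value arrays must be 1-D with equal length")
    if t.size < 2:
        raise ValueError("waveform requires at least 2 samples")
    if not (np.isfinite(t).all() and np.isfinite(v).all()):
        raise ValueError("waveform contains non-finite values")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    if np.max(np.abs(dt - 1.0 / fs)) > GRID_ATOL:
        raise ValueError("non-uniform sample grid (beyond tolerance)")


@dataclass(frozen=True)
class PressureWaveform:
    """Uniformly sampled aortic pressure series.

    Attributes
    ----------
    t : ndarray
        Sample times (s), strictly increasing, uniform within ``GRID_ATOL``.
    p : ndarray
        Aortic pressure (mmHg), finite everywhere.
    fs : float
        Sampling rate (Hz).
    """

    t: np.ndarray
    p: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        _validate_grid(self.t, self.p, self.fs)

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Span between first and last sample (s)."""
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class VolumeWaveform:
    """Uniformly sampled left-ventricular volume series (ml)."""

    t: np.ndarray
    v: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        _validate_grid(self.t, self.v, self.fs)

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class Beat:
    """One heartbeat slice of a pressure recording with annotated landmarks.

    ``samples``/``t`` cover the half-open interval ``[t0, t_f)`` on the
    parent grid; ``t_f`` itself is the onset of the next beat and lies one
    sample beyond the slice.
    """

    t: np.ndarray
    p: np.ndarray
    fs: float
    t0: float
    t_peak: float
    t_d: float
    t_f: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        _validate_grid(self.t, self.p, self.fs)
        if not (self.t0 < self.t_peak < self.t_d < self.t_f):
            raise ValueError(
                "beat landmarks must satisfy t0 < t_peak < t_d < t_f "
                f"(got {self.t0}, {self.t_peak}, {self.t_d}, {self.t_f})"
            )
        dur = self.t_f - self.t0
        if not (MIN_BEAT_S <= dur <= MAX_BEAT_S):
            raise ValueError(f"implausible beat duration {dur:.3f} s")

    def index_of(self, time: float) -> int:
        """Index of the beat sample nearest to an absolute time."""
        return int(np.clip(round((time - self.t[0]) * self.fs), 0, self.t.size - 1))

    @property
    def duration(self) -> float:
        return float(self.t_f - self.t0)


@dataclass(frozen=True)
class ExclusionMask:
    """Time intervals ``(start_s, end_s)`` to drop before any analysis."""

    intervals: tuple

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        for a, b in ivs:
            if b <= a:
                raise ValueError(f"exclusion interval ({a}, {b}) has non-positive length")
        ivs = tuple(sorted(ivs))
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError("exclusion intervals overlap")
        object.__setattr__(self, "intervals", ivs)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_waveform_csv(path, time_col: str = "time_s", value_col: str = "pressure_mmhg",
                      kind: str = "pressure"):
    """Read a waveform CSV (comma-separated, header row, UTF-8).

    The sampling rate is inferred from the median time step and snapped to
    an integer when within rounding error of one.

    Parameters
    ----------
    path : str or Path
    time_col, value_col : str
        Column names for the time (s) and value axes.
    kind : {"pressure", "volume"}
        Selects the returned container type.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no samples")
    for col in (time_col, value_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} (have {list(df.columns)})")
    t = df[time_col].to_numpy(dtype=float)
    v = df[value_col].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: waveform requires at least 2 samples")
    if not (np.isfinite(t).all() and np.isfinite(v).all()):
        raise ValueError(f"{path}: non-finite values")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time not strictly increasing")
    fs = 1.0 / float(np.median(dt))
    if abs(fs - round(fs)) < 1e-6 * max(1.0, abs(fs)):
        fs = float(round(fs))
    if np.max(np.abs(dt - 1.0 / fs)) > GRID_ATOL:
        raise ValueError(f"{path}: non-uniform sample grid")
    if kind == "pressure":
        return PressureWaveform(t=t, p=v, fs=fs)
    if kind == "volume":
        return VolumeWaveform(t=t, v=v, fs=fs)
    raise ValueError(f"unknown waveform kind {kind!r}")


def write_waveform_csv(wave, path, value_col: str | None = None) -> None:
    """Write a waveform to CSV with full float precision (round-trips bit-exactly)."""
    if isinstance(wave, PressureWaveform):
        value_col = value_col or "pressure_mmhg"
        values = wave.p
    elif isinstance(wave, VolumeWaveform):
        value_col = value_col or "volume_ml"
        values = wave.v
    else:
        raise TypeError(f"unsupported waveform type {type(wave)!r}")
    pd.DataFrame({"time_s": wave.t, value_col: values}).to_csv(
        path, index=False, float_format="%.17g")


def read_mask_csv(path) -> ExclusionMask:
    """Read an exclusion mask CSV with columns ``start_s,end_s``."""
    df = pd.read_csv(path)
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return ExclusionMask(tuple(zip(df["start_s"], df["end_s"])))


# ---------------------------------------------------------------------------
# Exclusions and beat segmentation
# ---------------------------------------------------------------------------

def apply_exclusions(wave: PressureWaveform, mask: ExclusionMask) -> list:
    """Split a recording into contiguous segments that avoid masked intervals.

    Samples with ``start <= t < end`` for any mask interval are dropped;
    the surviving contiguous runs (of at least 2 samples) are returned as
    independent waveforms so no beat analysis ever crosses a cut.
    """
    keep = np.ones(len(wave), dtype=bool)
    for a, b in mask.intervals:
        keep &= ~((wave.t >= a) & (wave.t < b))
    segments = []
    idx = np.flatnonzero(keep)
    if idx.size:
        # contiguous runs of kept indices
        breaks = np.flatnonzero(np.diff(idx) != 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [idx.size]))
        for s, e in zip(starts, ends):
            run = idx[s:e]
            if run.size >= 2:
                segments.append(PressureWaveform(t=wave.t[run], p=wave.p[run], fs=wave.fs))
    if not segments:
        raise ValueError("exclusion mask leaves no data")
    return segments


#: white-noise level (mmHg) above which a recording is low-pass filtered
#: before decomposition
NOISE_SIGMA_THRESHOLD = 0.25
#: zero-phase Butterworth low-pass cutoff (Hz) used for denoising; at 90 bpm
#: this retains the first ~6 pressure harmonics
LOWPASS_CUTOFF_HZ = 10.0


def estimate_noise_sigma(p: np.ndarray) -> float:
    """Robust estimate of additive white-noise sigma (mmHg).

    Uses the median absolute deviation of second differences, which for a
    smooth signal plus i.i.d. Gaussian noise concentrates at
    ``sigma * sqrt(6)``; the pressure signal's own curvature contributes
    little at physiological sampling rates.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 8:
        return 0.0
    d2 = np.diff(p, n=2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(1.4826 * mad / np.sqrt(6.0))


def denoise_pressure(wave: PressureWaveform, cutoff_hz: float = LOWPASS_CUTOFF_HZ,
                     order: int = 4) -> PressureWaveform:
    """Zero-phase Butterworth low-pass of a pressure recording."""
    from scipy.signal import butter, filtfilt

    if wave.fs <= 2 * cutoff_hz:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = butter(order, cutoff_hz / (wave.fs / 2.0))
    return PressureWaveform(t=wave.t, p=filtfilt(b, a, wave.p), fs=wave.fs)


def _smooth(p: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Zero-phase moving average with reflective edge padding."""
    if window <= 1 or p.size < window:
        return p.astype(float)
    kernel = np.full(window, 1.0 / window)
    half = window // 2
    padded = np.pad(p.astype(float), half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def _smoothed_derivative(p: np.ndarray, fs: float) -> np.ndarray:
    """Central-difference derivative of the smoothed pressure (mmHg/s)."""
    return np.gradient(_smooth(p), 1.0 / fs)


def detect_diastole_onset(t: np.ndarray, p: np.ndarray, fs: float,
                          t_peak: float | None = None) -> float:
    """Locate diastole onset (aortic valve closure) within one beat slice.

    Diastole is taken to start at the time of the minimum rate of change of
    aortic pressure after the systolic peak, evaluated on the smoothed
    derivative to suppress sample noise.

    Raises
    ------
    ValueError
        If the slice never decays after its peak ("no diastole").
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    if t.size < 4:
        raise ValueError("no diastole: slice too short")
    if t_peak is None:
        ip = int(np.argmax(p))
    else:
        ip = int(np.clip(round((t_peak - t[0]) * fs), 0, t.size - 1))
    if ip >= t.size - 2:
        raise ValueError("no diastole: peak at end of slice")
    dp = _smoothed_derivative(p, fs)
    window = dp[ip + 1:]
    i_min = ip + 1 + int(np.argmin(window))
    if dp[i_min] >= 0:
        raise ValueError("no diastole: pressure never decays after the peak")
    # smoothing drags the minimum a little early; refine on the raw derivative
    # within the smoothing half-width around the smoothed minimum
    half = SMOOTH_WINDOW // 2
    lo = max(ip + 1, i_min - half)
    hi = min(p.size, i_min + half + 1)
    dp_raw = np.gradient(p.astype(float), 1.0 / fs)
    i_min = lo + int(np.argmin(dp_raw[lo:hi]))
    return float(t[i_min])


def split_beats(wave: PressureWaveform) -> list:
    """Split a contiguous recording into annotated beats.

    Beat onsets are the feet of the systolic upstrokes: each local maximum
    of the smoothed dP/dt (with a refractory period between detections) is
    traced back to the pressure minimum immediately preceding it.  Beats run
    between consecutive onsets; partial beats at the segment edges are
    discarded, as are slices with implausible durations or pulse amplitudes
    and slices on which landmark annotation fails.
    """
    from scipy.signal import find_peaks

    dp = _smoothed_derivative(wave.p, wave.fs)
    dmax = float(dp.max(initial=0.0))
    if dmax <= 0.0:
        warnings.warn("no systolic upstrokes detected", stacklevel=2)
        return []
    distance = max(1, int(round(UPSTROKE_REFRACTORY_S * wave.fs)))
    peaks, _ = find_peaks(dp, height=0.3 * dmax, distance=distance)
    if peaks.size == 0:
        warnings.warn("no systolic upstrokes detected", stacklevel=2)
        return []

    ps = _smooth(wave.p)
    onsets = []
    for k in peaks:
        j = int(k)
        while j > 0 and ps[j - 1] <= ps[j]:
            j -= 1
        if j > 0:  # onset at the segment edge would be a partial beat
            onsets.append(j)
    onsets = sorted(set(onsets))

    beats = []
    for j0, j1 in zip(onsets, onsets[1:]):
        t0 = float(wave.t[j0])
        t_f = float(wave.t[j1])
        dur = t_f - t0
        if not (MIN_BEAT_S <= dur <= MAX_BEAT_S):
            continue
        t_sl = wave.t[j0:j1]
        p_sl = wave.p[j0:j1]
        ipk = int(np.argmax(p_sl))
        if ipk == 0 or ipk >= p_sl.size - 2:
            continue
        if p_sl[ipk] - p_sl[0] < MIN_PULSE_MMHG:
            continue
        t_peak = float(t_sl[ipk])
        try:
            t_d = detect_diastole_onset(t_sl, p_sl, wave.fs, t_peak=t_peak)
        except ValueError:
            continue
        if not (t0 < t_peak < t_d < t_f):
            continue
        beats.append(Beat(t=t_sl, p=p_sl, fs=wave.fs,
                          t0=t0, t_peak=t_peak, t_d=t_d, t_f=t_f))
    return beats


def compute_sv_from_volume(volume: VolumeWaveform, beats) -> np.ndarray:
    """Per-beat measured stroke volume: max minus min of the LV volume slice."""
    out = np.empty(len(beats), dtype=float)
    for i, beat in enumerate(beats):
        sel = (volume.t >= beat.t0) & (volume.t < beat.t_f)
        if not sel.any():
            raise ValueError(f"beat {i}: volume slice [{beat.t0}, {beat.t_f}) is empty")
        v = volume.v[sel]
        out[i] = float(v.max() - v.min())
    return out
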