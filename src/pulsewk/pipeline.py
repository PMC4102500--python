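"""End-to-end convenience wrappers: recording -> per-beat result table.

These functions wire segmentation, decomposition, SV estimation and
calibration together for scripted use and for the command-line interface.
The per-beat table columns are::

    beat_index, t0, t_peak, t_d, t_f,
    rc_s, rproxc_s, pmsf_mmhg, tau_s, fit_rmse_mmhg, converged, reason,
    sv_r_ml, sv_c_ml, sv_rprox_ml, sv_measured_ml
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import reservoir_model, stroke_volume, waveform_io
from .reservoir_model import BeatFlagged
from .stroke_volume import FixedParameterSet

logger = logging.getLogger("pulsewk")

_CLOSURE_COLUMNS = {"r": "sv_r_ml", "c": "sv_c_ml", "r_prox": "sv_rprox_ml"}


def segment_recording(wave, mask=None):
    """Apply exclusions (if any) and split every surviving segment into beats."""
    segments = [wave] if mask is None else waveform_io.apply_exclusions(wave, mask)
    beats = []
    for seg in segments:
        beats.extend(waveform_io.split_beats(seg))
    return beats


def maybe_denoise(wave, denoise="auto"):
    """Low-pass the recording when its estimated noise warrants it.

    ``denoise`` may be "auto" (filter when the estimated white-noise level
    exceeds :data:`waveform_io.NOISE_SIGMA_THRESHOLD`), True or False.
    """
    if denoise is False:
        return wave
    sigma = waveform_io.estimate_noise_sigma(wave.p)
    if denoise == "auto" and sigma <= waveform_io.NOISE_SIGMA_THRESHOLD:
        return wave
    logger.info("denoising recording (estimated noise %.2f mmHg)", sigma)
    return waveform_io.denoise_pressure(wave)


def decompose_recording(wave, mask=None, denoise="auto"):
    """Segment and decompose a recording; returns (beats, params, decomps).

    The recording is low-pass filtered first when measurement noise is
    detected (see :func:`maybe_denoise`); the per-beat decomposition then
    refers to the denoised pressure.
    """
    wave = maybe_denoise(wave, denoise)
    beats = segment_recording(wave, mask)
    identified, decomps = [], []
    for i, beat in enumerate(beats):
        params, decomp = reservoir_model.decompose_beat(beat)
        if not params.converged:
            logger.info("beat %d at t0=%.3f s flagged: %s", i, beat.t0, params.reason)
        identified.append(params)
        decomps.append(decomp)
    return beats, identified, decomps


def estimate_recording(wave, fixed_sets, mask=None, volume=None,
                       denoise="auto") -> pd.DataFrame:
    """Produce the per-beat result table for one or more closures.

    Parameters
    ----------
    wave : PressureWaveform
    fixed_sets : sequence of FixedParameterSet
    volume : VolumeWaveform, optional
        When given, measured SV (max-min of the per-beat volume slice) is
        added as ``sv_measured_ml``.
    """
    beats, identified, decomps = decompose_recording(wave, mask, denoise=denoise)
    sv_meas = (waveform_io.compute_sv_from_volume(volume, beats)
               if volume is not None and beats else None)

    rows = []
    for i, (beat, ident, decomp) in enumerate(zip(beats, identified, decomps)):
        row = {
            "beat_index": i,
            "t0": beat.t0, "t_peak": beat.t_peak, "t_d": beat.t_d, "t_f": beat.t_f,
            "rc_s": ident.rc, "rproxc_s": ident.rproxc, "pmsf_mmhg": ident.p_msf,
            "tau_s": ident.tau, "fit_rmse_mmhg": ident.diastolic_fit_rmse,
            "converged": ident.converged, "reason": ident.reason,
        }
        for fixed in fixed_sets:
            col = _CLOSURE_COLUMNS[fixed.which]
            if ident.converged and decomp is not None:
                try:
                    row[col] = stroke_volume.estimate_sv(decomp, ident, fixed)
                except BeatFlagged as err:
                    logger.info("beat %d SV (%s) flagged: %s", i, fixed.which, err)
                    row[col] = np.nan
            else:
                row[col] = np.nan
        if sv_meas is not None:
            row["sv_measured_ml"] = sv_meas[i]
        rows.append(row)
    columns = ["beat_index", "t0", "t_peak", "t_d", "t_f", "rc_s", "rproxc_s",
               "pmsf_mmhg", "tau_s", "fit_rmse_mmhg", "converged", "reason"]
    columns += [_CLOSURE_COLUMNS[f.which] for f in fixed_sets]
    if sv_meas is not None:
        columns.append("sv_measured_ml")
    return pd.DataFrame(rows, columns=columns)


def calibrate_recording(wave, volume, mask=None, ranges=None,
                        step=stroke_volume.GRID_STEP, denoise="auto"):
    """Identify optimal fixed R, C and R_prox against measured SV."""
    beats, identified, decomps = decompose_recording(wave, mask, denoise=denoise)
    if not beats:
        raise ValueError("no beats detected in recording")
    sv_meas = waveform_io.compute_sv_from_volume(volume, beats)
    return stroke_volume.calibrate_fixed_params(identified, decomps, sv_meas,
                                                ranges=ranges, step=step)


def match_beats_to_truth(table: pd.DataFrame, truth: pd.DataFrame,
                         max_offset_s: float | None = None) -> pd.DataFrame:
    """Align detected beats with simulator truth records by onset time.

    Each detected beat is matched to the truth beat with the nearest start
    time; matches farther than ``max_offset_s`` (default: half the median
    truth period) are dropped.  Returns the table with ``sv_true_ml``,
    ``t_d_true_s`` and ``truth_index`` columns appended.
    """
    t0_truth = truth["t0"].to_numpy(dtype=float)
    if max_offset_s is None:
        max_offset_s = 0.5 * float(np.median(np.diff(t0_truth)))
    t0_det = table["t0"].to_numpy(dtype=float)
    idx = np.abs(t0_det[:, None] - t0_truth[None, :]).argmin(axis=1)
    offset = np.abs(t0_det - t0_truth[idx])
    ok = offset <= max_offset_s
    out = table.copy()
    out["truth_index"] = np.where(ok, idx, -1)
    out["sv_true_ml"] = np.where(ok, truth["sv_true_ml"].to_numpy()[idx], np.nan)
    out["t_d_true_s"] = np.where(ok, truth["t_d_true_s"].to_numpy()[idx], np.nan)
    return out


def all_closures(values: dict) -> list:
    """FixedParameterSet list for a {"r": ..., "c": ..., "r_prox": ...} mapping."""
    return [FixedParameterSet(which=k, value=v) for k, v in values.items()]
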