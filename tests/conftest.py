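"""Shared fixtures: simulated recordings at the porcine-like operating point."""

import numpy as np
import pytest

import pulsewk as pw

TRUE_R = 1.663
TRUE_C = 0.533
TRUE_RPROX = 0.088
TRUE_PMSF = 20.0
TRUE_SV = 25.3
TRUE_RC = TRUE_R * TRUE_C            # 0.886379 s
TRUE_RPROXC = TRUE_RPROX * TRUE_C    # 0.046904 s


@pytest.fixture(scope="session")
def true_params():
    return pw.WindkesselParams(r=TRUE_R, c=TRUE_C, r_prox=TRUE_RPROX,
                               p_msf=TRUE_PMSF)


@pytest.fixture(scope="session")
def sim_clean(true_params):
    """Noiseless 12-beat recording at the reference operating point."""
    cfg = pw.SimulationConfig(params=true_params, sv_trend=(TRUE_SV,) * 12)
    return pw.simulate_recording(cfg)


@pytest.fixture(scope="session")
def sim_noisy(true_params):
    """30-beat recording with 1 mmHg Gaussian pressure noise."""
    cfg = pw.SimulationConfig(params=true_params, sv_trend=(TRUE_SV,) * 30,
                              noise_sigma=1.0, seed=11)
    return pw.simulate_recording(cfg)


@pytest.fixture(scope="session")
def clean_beats(sim_clean):
    beats = pw.split_beats(sim_clean.pressure)
    assert beats, "segmentation found no beats in the clean recording"
    return beats


@pytest.fixture(scope="session")
def clean_decomposition(clean_beats):
    """(beat, identified, decomposition) for one interior noiseless beat."""
    beat = clean_beats[len(clean_beats) // 2]
    ident, decomp = pw.decompose_beat(beat)
    assert ident.converged, ident.reason
    return beat, ident, decomp


def make_beat(t, p, fs, t_peak=None, t_d=None):
    """Construct a Beat from arrays, auto-annotating missing landmarks."""
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    if t_peak is None:
        t_peak = float(t[np.argmax(p)])
    if t_d is None:
        t_d = pw.detect_diastole_onset(t, p, fs, t_peak=t_peak)
    return pw.Beat(t=t, p=p, fs=fs, t0=float(t[0]), t_peak=t_peak, t_d=t_d,
                   t_f=float(t[-1] + 1.0 / fs))
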