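# pulsewk

Beat-to-beat left-ventricular stroke volume (SV) from an aortic pressure
waveform alone, using a three-element Windkessel model and
reservoir–excess pressure decomposition.

Continuous SV is the quantity an intensivist actually wants when titrating
fluids, inotropes or ventilation, but direct measurement needs a ventricular
admittance catheter and indicator-dilution methods only give averages over
many beats. Aortic pressure, in contrast, is routinely available. `pulsewk`
turns each beat of that pressure signal into an SV estimate, and ships a
forward Windkessel simulator with exact ground truth so that every inverse
step is verifiable by parameter- and SV-recovery experiments — no animal
data required.

## Model

Aortic pressure is split into a *reservoir* component, the pressure stored
and released by the elastic arterial walls, and an *excess* component
proportional to aortic inflow:

```
P_ao(t) = P_res(t) + P_ex(t),          P_ex = R_prox · Q_in
C · dP_res/dt = Q_in − (P_res − P_msf) / R
```

with `R` the systemic resistance (mmHg·s/ml), `C` the arterial compliance
(ml/mmHg), `R_prox` the characteristic impedance (mmHg·s/ml) and `P_msf`
the mean systemic filling pressure (mmHg). Eliminating `Q_in` yields a
linear ODE for `P_res` driven by `P_ao` that depends only on `RC`,
`R_prox·C` and `P_msf` — all identifiable per beat:

* `RC` and `P_msf` from the exponential diastolic decay (inflow is zero
  after aortic valve closure at `t_d`, located at the minimum of dP/dt);
* `R_prox·C` from the condition that the reservoir pressure integrated
  through systole arrives on the diastolic decay curve at valve closure,
  with the zero-net-flow time `τ` (where `Q_in = Q_out` and `P_res` is
  maximal) read off between the pressure peak and `t_d`.

The products leave one degree of freedom in `(R, C, R_prox)`. Fixing any
one element — at a population-representative value found by a 0.001-step
grid search against measured SV — closes the system, and

```
SV = ∫_beat Q_in dt = (1 / R_prox) ∫_beat P_ex dt .
```

## Worked example

Simulate a 60-beat recording whose per-beat SV steps 25→20→14→20→25 ml
(a PEEP-recruitment-like staircase), with 1 mmHg of added pressure noise;
then estimate SV from the pressure trace alone with `R_prox` fixed at its
true value, calibrate all three fixed parameters against the measured
volume trace, and evaluate agreement and trend tracking:

```
$ cat config.yaml
sv_levels: [25, 20, 14, 20, 25]
beats_per_level: 12
noise_sigma: 1.0
seed: 3

$ pulsewk simulate --config config.yaml --out-dir data
wrote 60 beats to data
$ pulsewk estimate --input data/pressure.csv --volume data/volume.csv \
      --fixed-param rprox --fixed-value 0.088 --out-dir out
wrote 58 beats (47 converged) to out/beats.csv
$ pulsewk calibrate --input data/pressure.csv --volume data/volume.csv --out-dir out
calibration over 47 beats: {'r': 1.957, 'c': 0.536, 'r_prox': 0.092}
$ printf 'start_beat,end_beat,label\n0,48,staircase\n' > regions.csv
$ pulsewk evaluate --input out/beats.csv --regions regions.csv --out-dir out
wrote report for 1 estimator(s) to out/report.yaml
$ cat out/report.yaml
sv_rprox_ml:
  median_diff_ml: -0.7787700906055761
  n_beats: 47
  p5_diff_ml: -3.187413095010729
  p95_diff_ml: 1.4602187738212553
  trend:
    staircase:
      end_beat: 48
      r: 0.9331996804980106
      start_beat: 0
```

Reading the output: of 58 detected beats, 47 pass per-beat identification
(noisy diastoles that do not decay cleanly are flagged and excluded, not
guessed). The Bland-Altman summary says measured-minus-estimated SV has a
median of −0.8 ml with a 5th–95th percentile range of −3.2 to +1.5 ml, and
the zero-lag cross-correlation of 0.93 over the staircase shows the induced
SV trend is tracked closely. The calibrated `c` (0.536 ml/mmHg) and
`r_prox` (0.092 mmHg·s/ml) land near the generating values (0.533, 0.088)
even at this noise level and short record; `r` is the least identifiable of
the three from noisy data (here 1.957 vs 1.663), which is why its closure
relies most on calibration.

The same pipeline is available as a library (`pulsewk.simulate_recording`,
`pulsewk.decompose_beat`, `pulsewk.estimate_sv`,
`pulsewk.pipeline.estimate_recording`, ...); see the docstrings and
`docs/methods.md`.

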