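# Methods

## Model and identification

`pulsewk` treats the proximal aorta as a three-element Windkessel: a
characteristic impedance `R_prox` in series with a parallel
resistance–compliance pair `(R, C)` discharging toward the mean systemic
filling pressure `P_msf`. Aortic pressure decomposes as
`P_ao = P_res + P_ex` with `P_ex = R_prox·Q_in`; the reservoir pressure
obeys

    dP_res/dt + β·P_res = P_ao/(R_prox·C) + P_msf/(R·C),
    β = 1/(R_prox·C) + 1/(R·C),

so the decomposition of a beat depends only on `RC`, `R_prox·C` and
`P_msf`. All parameters are assumed constant within a beat.

Per beat, identification proceeds in three stages:

1. **Diastolic decay** (`fit_diastolic_decay`). With the aortic valve
   closed, `Q_in = 0` and pressure relaxes exponentially toward `P_msf`
   with time constant `RC`. The window from 20 ms after `t_d` to beat end
   is fitted with `A·exp(−(t−t_d)/RC) + P_msf` by bounded nonlinear least
   squares (`RC ∈ [0.1, 10] s`, `P_msf ∈ [0, min window pressure]`,
   `A > 0`), started from a log-linear regression with three asymptote
   guesses to avoid local minima in shallow decays. The amplitude `A` is a
   free parameter rather than pinned to the measured sample at `t_d`: a
   one-to-two-sample error in locating valve closure then costs nothing,
   and on noiseless model data the fit recovers `RC` and `P_msf` to
   machine precision. The 20 ms trim keeps valve-closure (dicrotic-notch)
   ringing out of the fitted window.

2. **Valve-closure continuity** (`identify_rproxc`). The fitted decay
   curve `D(t)` is an exact solution of the reservoir ODE *for any*
   `R_prox·C` (substituting `P_ao = D` reduces the ODE to the pure decay),
   so the diastolic tail itself cannot distinguish candidates — and
   enforcing a stationary point of `P_res` at any chosen sample in
   `(t_peak, t_d)` yields a self-consistent pair for *every* sample. The
   identifying information is the boundary condition: the reservoir
   pressure integrated through systole from `P_res(t0) = P_ao(t0)` must
   arrive on `D` at valve closure. The continuity residual, averaged over
   a short window 10–35 ms after the detected `t_d` (so a slightly early
   detection, while inflow has not quite ceased, does not bias the root;
   the residual decays at rate `β` after closure, so the window must stay
   short), has a single sign change in `R_prox·C`: small values over-track
   the still-elevated measured pressure, large values under-charge the
   reservoir. A 25-point logarithmic scan over
   `[10⁻³ s, 0.9·RC]` brackets it and bisection refines to relative width
   10⁻⁶. The zero-net-flow time `τ` — where `Q_in = Q_out`, equivalently
   `dP_res/dt = 0` — is then read off as the interior maximum of `P_res`
   in `(t_peak, t_d)` with parabolic sub-sample refinement; a beat whose
   reservoir pressure has no interior maximum there is flagged rather
   than forced.

3. **Closure and SV** (`stroke_volume`). `RC` and `R_prox·C` leave one
   degree of freedom in the triple; fixing `R`, `C` or `R_prox` closes it
   algebraically, and `SV = (1/R_prox)·∫ P_ex dt` by the trapezoidal rule
   over the full beat (diastolic `P_ex ≈ 0` makes the tail contribution
   negligible). A beat whose excess-pressure integral is negative beyond
   5 % of `∫|P_ex| dt` is flagged as a decomposition failure. `SV_Rprox`
   is exactly inversely proportional to the fixed `R_prox`; `SV_R` and
   `SV_C` inherit the same law through the closure algebra.

The reservoir ODE is solved with an exponential integrator that is exact
for piecewise-linear `P_ao` between samples (closed-form per-interval
update, evaluated as a first-order linear recurrence via
`scipy.signal.lfilter`), removing grid-dependent quadrature bias at
200 Hz; against an adaptive LSODA reference at 10⁻¹⁰ relative tolerance
the agreement is far below the 0.05 mmHg the tests require.

## Beat segmentation and landmarks

Beat onsets are the feet of systolic upstrokes: local maxima of the
smoothed derivative (5-sample zero-phase moving average, central
differences; 0.25 s refractory period; peaks below 30 % of the global
maximum ignored) traced back to the preceding pressure minimum. Diastole
onset `t_d` is the minimum rate of pressure change after the systolic
peak, found on the smoothed derivative and then re-localised on the raw
derivative within the smoothing half-width — the smoothing alone drags
the minimum about two samples early, which both biases the diastolic
window and can push the zero-net-flow point out of `(t_peak, t_d)`.
Partial beats at segment edges, beats outside 0.25–2.5 s duration, beats
with less than 10 mmHg foot-to-peak amplitude, and beats whose annotation
fails are discarded. All intervals are half-open `[t0, t_f)` in absolute
recording seconds; exclusion masks cut the recording into independent
segments so no beat spans an artifact.

When the estimated measurement noise of a recording (1.4826·MAD of second
differences / √6) exceeds 0.25 mmHg, the pipeline low-passes the pressure
with a zero-phase 4th-order Butterworth at 10 Hz before segmentation. The
per-beat identification is otherwise noise-limited: at 1 mmHg white noise
the continuity residual (≈0.5 mmHg sensitivity per octave of `R_prox·C`)
and the three-parameter decay fit both degrade enough that trend tracking
collapses. At 90 bpm the 10 Hz cutoff retains the first six pressure
harmonics; clean recordings never trigger the filter, so noiseless
recovery is unaffected.

## Calibration

The population fixed values solve, for each parameter independently, an
exhaustive grid search at 0.001 resolution (in each parameter's native
units) over `R ∈ [0.5, 4.0] mmHg·s/ml`, `C ∈ [0.1, 2.0] ml/mmHg`,
`R_prox ∈ [0.010, 0.300] mmHg·s/ml`, minimising the summed squared
difference between estimated and measured SV over all converged beats
(ties break toward the smaller value; boundary optima raise a warning).
Because each beat's estimate is `k_b·x` or `k_b/x` in the fixed value
`x`, the objective reduces to sufficient statistics
(`∫P_ex dt`, `RC`, `R_prox·C` per beat) and each scan is evaluated in
closed form over the whole grid at once.

## Synthetic data

The simulator drives the forward Windkessel with a half-sine systolic
inflow (`Q_peak = π·SV/(2·T_sys)`, so the inflow integrates exactly to the
prescribed SV) and solves the resulting linear ODE in closed form within
each beat — sinusoid-plus-exponential during ejection, pure decay in
diastole — propagating the reservoir state beat to beat. The recording
starts at the analytic periodic fixed point of the affine beat map, with
five warm-up beats run and discarded on top, so the emitted pressure is in
steady state from the first sample. Ground truth per beat (SV,
valve-closure time = end of ejection, zero-net-flow time from a root find
on the analytic derivative) is exact and independent of any integration
step. A synthetic LV volume trace ejects the cumulative inflow and refills
along a half-cosine, so its per-beat max−min equals the prescribed SV.

Defaults emulate the reported porcine operating regime: R = 1.663
mmHg·s/ml, C = 0.533 ml/mmHg, R_prox = 0.088 mmHg·s/ml, SV 25.3 ml —
population-level values for ~30 kg pigs — with P_msf = 20 mmHg, heart
rate 90 bpm and systolic fraction 0.375 chosen so the simulated mean
pressure (≈86 mmHg, `P_msf + (R+R_prox)·SV·HR/60`) sits in the reported
median MAP range; sampling at 200 Hz matches the reference acquisition
rate. Stepwise per-beat SV staircases emulate the preload reduction of
PEEP recruitment manoeuvres; i.i.d. Gaussian noise is added to the
sampled pressure only, under a caller-supplied seed.

What the simulator deliberately does not reproduce: dicrotic-notch
ringing, reflected waves, respiratory modulation within beats,
beat-to-beat parameter drift, and coloured catheter noise. Passing
recovery tests therefore demonstrates correctness of the inverse machinery
under the model's own assumptions — not performance on real catheter
data, where the pressure is not generated by a three-element Windkessel.

## Evaluation statistics

Agreement is summarised by the distribution of per-beat differences
(measured − estimated, so a positive median means underestimation):
median and 5th/95th percentiles with the linear-interpolation quantile
convention. Trend tracking over a designated region of beats is the
zero-lag Pearson correlation between the two beat-indexed SV series;
regions index rows of the per-beat table, and non-converged beats inside
a region are dropped pairwise.

## Numerical choices and degenerate inputs

* Bisection on `R_prox·C`: relative width 10⁻⁶; decay fit: `curve_fit`
  (TRF) at 10⁻¹⁴ tolerances.
* Constant pressure → no upstrokes → empty beat list with a warning;
  monotone non-decreasing slices → "no diastole"; flat diastole → `RC`
  unidentifiable, beat flagged; every flagged beat carries its reason and
  is excluded from SV output rather than imputed.
* Calibration requires ≥ 10 converged paired beats; grid points with
  non-finite objective are skipped with a warning.
* Sample-rate inference snaps to integer Hz when within rounding error;
  CSV round trips are bit-exact (`%.17g` on write, `round_trip` float
  parsing on read).

## Known limitations

* `R` is the least identifiable element from noisy data (it enters only
  through the slow diastolic asymptote), so `SV_R` leans hardest on
  calibration; this mirrors the physiology rather than a code defect.
* Identification assumes a clean exponential diastole; arrhythmic or
  heavily artifacted beats are flagged, not recovered.
* The per-beat problem sizes used throughout the tests (8–300 beats,
  200 Hz) were chosen as the smallest records on which the recovery
  properties are stable; results do not depend on these sizes beyond
  sampling noise.
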