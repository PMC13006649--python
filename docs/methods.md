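# Methods

This note documents the models, algorithms and numerical choices behind the
package: what is simulated, what is learned, what is controlled, and where
the genuinely open design decisions were resolved.

## The control problem

In DO-stat fed-batch cultivation of *E. coli*, glucose is fed in pulses
triggered by the dissolved-oxygen (DO) signal: when residual glucose runs
out, oxygen uptake collapses and DO spikes upward; feeding restores uptake
and DO falls back.  The level that DO returns to between spikes — the
**baseline** — is set by the balance of oxygen transfer (kLa) and cellular
uptake (OUR) and drifts continuously over a run.  Fixed start/stop DO
thresholds therefore go stale; the system here re-anchors all feeding
thresholds to a continuously re-estimated baseline.  The baseline is not a
measurable quantity, so the estimator is trained on synthetic traces whose
baseline is known by construction.

## Synthetic DO-trace generator (`neurostat.synth`)

A trace (default 240 min, 1-min resolution) is a baseline trajectory plus a
train of depletion spikes plus Gaussian sensor noise, clipped to
[0, 100] % air saturation.

* **Baselines.** Three trend kinds mixed equally: *stable* (constant level
  with a smooth random drift bounded by `drift_max`, default 2 %DO),
  *increasing* and *decreasing* (linear ramps, |slope| ~ U(0.05, 0.5) %DO/min).
  Levels ~ U(10, 70) %DO.
* **Spikes.** Onset gaps ~ U(3, 30) min, heights ~ U(5, 45) %DO,
  linear rise over U(1, 5) min, relaxation over U(2, 15) min.  The
  relaxation is a zero-shifted exponential, `h·(e^{-3z} − e^{-3})/(1 − e^{-3})`
  with `z` the fraction of the decay width elapsed, so the spike returns to
  the baseline exactly at the end of its support while keeping an
  exponential-recovery shape.  The shape function is pluggable.
* **Noise.** Per-trace sd ~ U(0, 1) %DO; inclusion is a flag (default on).
* **Windows.** Training windows are 60-min slices cut at random offsets from
  whole traces (overlap allowed, also a flag), so partial spikes appear at
  window edges exactly as in streaming deployment.  The label is the
  ground-truth baseline at the slice's final minute.

All distribution parameters are configuration, not constants.  Sampling is a
pure function of `(n, params, seed)`: per-trace streams are spawned from the
master seed, so datasets are bit-reproducible and generation may be
parallelised without changing results.

**What the generator does not emulate.** Real DO electrodes drift over days;
real baselines shift abruptly when actuators step; antifoam events and pH
pulses perturb the signal.  None of these are in the corpus, so the
recognition accuracy reported here bounds what the architecture can learn
from this family of signals, not performance on a physical reactor.  Two
consequences show up in closed loop and are handled there (see *Oxygen-supply
cooldown* below): declines through DO ranges that baselines never occupy in
training are read as spike tails, and steep supply-driven climbs are read as
spikes.

## Baseline recognition network (`neurostat.mlp`)

A fully connected ReLU MLP, 60 → 1024 → 512 → 256 → 128 → 1, maps the last
60 one-minute DO values to the baseline at the window's end.  The network and
its training loop (mini-batch Adam on the MSE loss, He-normal seeded
initialisation, float32) are implemented directly in numpy; a transplanted
scikit-learn `MLPRegressor` serves as an independent cross-check of the
forward pass in the test suite.

* **Normalisation.** Inputs and labels are divided by 100, the fixed physical
  span of the DO scale.  Per-dataset min-max scaling would destroy the
  absolute level information a deployment window carries, so it is not used.
* **Training schedule.** Defaults: 100 epochs, batch 256, Adam at 1e-3 with
  cosine decay to 1e-5, a 10 % validation slice, early stopping with
  patience 10 and best-weights restoration.  These are desk-scale settings:
  one training run takes about a minute on a single CPU core.
* **Metrics.** MSE is reported on the raw %DO scale (the internal loss is on
  the /100 scale; the conversion is exactly 100²).  R² is centred
  (`1 − SS_res/SS_tot`); zero-variance labels yield a flagged undefined R²
  rather than a silent NaN.
* **Protocol.** 15,000 windows, shuffled 1:1 train/test split.  Held-out R²
  is ≥ 0.998 across training seeds (typically ≈ 0.999); `scripts/acceptance.py`
  recomputes this from scratch.
* **Model front end.** `BaselineRecognition(dataset).fit()` returns a results
  object with train/test metrics and a `summary()`; the underlying
  `TrainedBaselineModel` carries weights, normalisation and training
  metadata, and round-trips through a single-file checkpoint.

## Causal Savitzky–Golay smoothing (`neurostat.smoothing`)

The per-minute raw baseline stream is smoothed by a Savitzky–Golay filter
fitted to a *trailing* window and evaluated at its newest point (default
window 15 min, order 2).  This endpoint form deliberately differs from the
textbook centred filter: control cannot wait for future samples.  Endpoint
evaluation keeps the filter's defining exactness — polynomials up to the
fitted order pass through unchanged (verified to 1e-9) — at the price of
less attenuation than the centred form.  During warm-up the running mean of
the buffer is returned.

## Control logic (`neurostat.controller`)

Per-second DO samples are averaged into one-minute window values (mean
aggregation; last-value is a config option).  Once per minute, the full
60-value window is passed to the recogniser and the smoother.  Decisions:

* **Feeding** (every second): start a glucose pulse at rate `v_glc` when
  DO > `baseline_smooth + threshold_increase`; stop when
  DO < `baseline_smooth + baseline_increase`; force-stop any pulse reaching
  `max_pulse_duration` (3 min).  All comparisons are strict; ties do nothing.
  The smoothed baseline used is the last completed minute's value.
* **Nitrogen**: latched on at `v_ns` (1.0 g/L/h) from the first glucose
  trigger, never off.
* **Induction** (one-shot): strictly after `induction_time`, dose IPTG
  (0.3 mmol/L default), drop the temperature setpoint 37 → 28 °C, and swap in
  the induction-phase parameter set (defaults override `baseline_increase`,
  `threshold_increase`, `v_glc` to 5, 10, 7 g/L/h).
* **Oxygen supply** (per-minute evaluation, rate-limited): step agitation and
  aeration by +20 rpm / +0.05 L/min when `baseline_smooth < baseline_lb`, and
  by −20 rpm / −0.05 L/min when above `baseline_ub`, clamped to
  [400, 800] rpm and [0.5, 1.5] L/min.

**Oxygen-supply cooldown.** Steps are limited to one per 10 minutes
(`o2_cooldown_min`; setting 1 restores strict per-minute stepping).  This is
a deliberate design choice, and the reason is a genuine feedback pathology:
the recogniser is trained to attribute steep DO climbs to depletion spikes
(baseline unchanged underneath).  If the controller steps the oxygen supply
every minute while the smoothed baseline sits below the bound, the resulting
multi-percent-per-minute DO climb is read as a spike, the smoothed baseline
never rises, stepping continues, and the widening gap between real DO and
estimated baseline eventually crosses `threshold_increase` — triggering
glucose feeding into a glucose-rich broth.  Pure edge-triggered stepping
(one step per bound crossing) fails the other way: during sustained demand
growth the baseline legitimately stays below the bound and the supply stalls.
The cooldown is the middle ground: each step produces a small DO plateau that
the recogniser absorbs into the baseline before the next step fires.

Pump-rate conversion: `v_glc` is g glucose per litre of *culture* per hour;
the pump flow is `v_glc · V / 500` L/h from the 500 g/L feed stock, and the
broth volume increases with everything pumped.

## Plant simulator (`neurostat.plant`)

The plant is openly synthetic — its job is to exercise the control logic
with realistic DO-stat dynamics, not to predict *E. coli* physiology.  State
is biomass X (g/L), glucose S (g/L), DO (%), volume V (L); explicit Euler at
1 s:

    mu  = mu_max · S/(Ks+S) · DO/(Ko+DO)
    qs  = mu · X / Yxs
    dDO = [ kLa(rpm, air) · (100 − DO) − yo·qs/c*_O2 · 100 ] dt
    kLa = kla_a · (rpm/400)^2 · (air/0.5)^0.4

with a first-order sensor lag (30 s) plus Gaussian read noise (0.3 %DO).
The DO Monod term (Ko = 5 %) is essential: it caps glucose uptake at the
oxygen-transfer limit, so depletion-spike periods stay in the minutes range
as biomass accumulates instead of collapsing to seconds, as in a real
transfer-bounded reactor.

Defaults (mu_max 0.6 /h, Ks 0.05 g/L, Yxs 0.5 g/g, yo 0.8 g O₂/g,
c*_O2 7.5 mg/L, kla_a 50 /h, batch glucose 10 g/L in 0.7 L, inoculum
0.12 g/L) were chosen to produce: a gentle DO decline that stays above the
oxygen-deficiency bound until the controller's 60-minute window has warmed
up; batch-glucose depletion near 7.5 h; growth-phase spike periods of
roughly 5 min (within the 3–15 min DO-stat cadence), compressing to ~1–2 min
small top-up pulses under the tight induction-phase thresholds — the
small-pulse/high-frequency regime characteristic of baseline-relative
control.  Mass balance per step is exact to the Euler tolerance and is
tested.

## Induction optimisation (`neurostat.doe`)

Range analysis for balanced orthogonal designs: level means
`k_ij = mean(Y | factor j at level i)`, ranges `R_j = max_i k_ij − min_i k_ij`,
factors ranked by `R_j`, optimum = per-factor argmax level (response is a
yield).  Ties break toward the lowest level with a warning.  The packaged
L9(3⁴) design (three 3-level factors — induction start time, IPTG amount,
start/stop threshold pair — over nine batches; the array's spare fourth
column unassigned) reproduces its published level means at printed precision
except two cells that the original analysis evidently computed from
unrounded responses; those agree to < 1 %.  The specific-fluorescence
transform (cellular fluorescence / OD600) and percent-change helper are
included for response preparation.

## Numerical and testing choices

* Determinism everywhere: every stochastic component takes a seed or a
  `numpy` Generator; closed-loop runs are bit-reproducible per seed.
* Problem sizes in the test suite are desk-scale by design: the compact
  controller-exercise model (3 hidden layers, 4,000 windows) reaches
  R² ≈ 0.995 in seconds; the full protocol (15,000 windows, full
  architecture, three seeds) runs only in the acceptance-level tests and the
  acceptance script, about a minute per seed on one core.
* Closed-loop property checks assert behaviour, not trajectories: actuator
  bounds, pulse-duration cutoff (+1 control tick of slack), residual glucose
  below 0.5 g/L for ≥ 95 % of the feeding phase, monotone nitrogen/induction
  latches, and a sustained depletion-spike sawtooth.
* Degenerate inputs are first-class: zero-variance labels (flagged R²),
  empty CSV (empty frame), truncated checkpoints (explicit error), unbalanced
  designs (error naming the factor), out-of-order samples (ordering error).

## Known limitations

* The recogniser extrapolates poorly outside the generator's baseline range;
  in particular, slow declines through 70–100 %DO resemble spike tails.  The
  closed-loop configuration keeps the operating point inside the trained
  range after warm-up; a deployment against real hardware should retrain
  with the site's observed baseline span.
* The plant omits acetate/overflow metabolism, product kinetics, pH dynamics
  and temperature dependence of growth; the controller never reads these, so
  they are out of the control contract.
* Controller decisions during the first 60 minutes are suppressed (window
  warm-up); processes whose first depletion event can occur inside that hour
  need a shorter window or a pre-filled buffer.
* The 3-minute forced feed stop re-arms immediately; under a persistently
  wrong baseline estimate the controller can chain forced pulses.  The
  oxygen-step cooldown removes the known trigger for that state, but no
  separate glucose-accumulation guard exists (the real system has none
  either — the premise of DO-stat is that high DO implies starvation).
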