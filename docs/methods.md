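# Methods

This note records the model, the estimators, the numerical choices and the
known limitations of `spikeinfo`, in the order the pipeline runs.

## Hidden state

The stimulus is a stationary telegraph process: a binary `x(t)` switching
`0 -> 1` at rate `r_on` (Hz) and `1 -> 0` at `r_off`.  It is simulated in
discrete time with per-step Bernoulli switching probabilities `r_on*dt`
and `r_off*dt` (first order in `dt`; at the default `dt = 0.2 ms` and the
built-in regimes the probabilities are at most ~0.013, so higher-order
corrections are negligible).  Parameter sets with `r*dt >= 1` are
rejected.  The initial state is drawn from the stationary distribution
`p1 = r_on/(r_on+r_off)`, so traces need no burn-in; this convention is a
package choice.  The per-step entropy of the state is the binary entropy
`H_xx = -p1 log2 p1 - (1-p1) log2(1-p1)` bits; empirical entropy plugs
the realized occupancy into the same formula.

## Presynaptic population and input current

`N` conditionally-Poisson neurons fire at `q_on_i` (state ON) or
`q_off_i` (OFF).  Rates are i.i.d. Gaussian with mean `mu_q` and SD
`mu_q/8`; draws below 1e-6 Hz are redrawn, because the weights
`w_i = ln(q_on_i/q_off_i)` need strictly positive rates (the SD is small
enough that redraws are ~1-in-10^15 events at the default regimes — the
floor is a guard, not a distortion).  Spiking is Bernoulli per 0.2 ms bin
(`q*dt <= ~10^-3`, so at most one spike per bin loses nothing); sampling
draws a binomial count over the ON (OFF) bins and places the spikes
uniformly without replacement, which is distribution-identical to per-bin
Bernoulli thinning but O(spikes) instead of O(N x bins).

Each spike contributes its neuron's weight convolved with a causal
exponential kernel (time constant 5 ms, unit area, truncated at 12 time
constants and renormalized; zero initial condition, no wrap-around — the
discrete analogue of a PSC generator).  The constant offset
`theta = sum_i(q_on_i - q_off_i)` is recorded exactly from the realized
draws; a `zero_theta` switch instead forces the idealized value 0 (the
expectation of the draw).  An affine map `I_hold + I_scale * I(t)` turns
the dimensionless trace into an injectable current; double scaling is
rejected.

The useful property of this construction: with `r_off = 2 r_on` the
hidden-state entropy is fixed (~0.9183 bits) while `tau` sets the input's
autocorrelation time and `mu_q` its amplitude, so the two experimental
knobs move independently at controlled information content.

## Decoder and information estimates

The posterior log-odds of `x = 1` given the signal history follows

    dL/dt = r_on (1 + e^-L) - r_off (1 + e^L) + I(t) - theta ,

with `L` in natural-log units (the exponential algebra only closes in
base e); entropies and informations are converted to bits at output.
`L(0)` is the prior log-odds `ln(r_on/r_off)`.

A spike train is decoded through the same equation after reduction to
impulses: conditional rates `q_on_hat`, `q_off_hat` are counted against
the hidden state, each spike contributes an impulse of area
`w_hat = ln(q_on_hat/q_off_hat)` (value `w_hat/dt` in its bin), and
`theta_hat = q_on_hat - q_off_hat`.  A state with zero spikes has its
rate floored at one expected count over the time spent in that state
(`1/T_state`), keeping `w_hat` finite; this is warned about loudly.  The
PSC kernel is deliberately dropped here — delta impulses are exact for
the decoder, the kernel exists only because hardware cannot inject
deltas.

From the pair (`x`, posterior `p`):

- `H_x|y` = time-averaged surprisal (plug-in estimate, an upper bound, so
  `MI = H_xx - H_x|y` is a lower bound and can dip slightly below zero on
  weakly informative signals);
- `F = MI/H_xx`, `FI = MI_spike/MI_input` (flagged undefined when
  `MI_input <= 0`);
- `MSE` of `p` as a state estimate; `MSE_P` normalizes by the mean MSE of
  homogeneous Poisson surrogates with the same spike count (uniform order
  statistics, decoded by the same pipeline; default 100 surrogates, giving
  <2% SE on the normalizer); `FMSE = MSE_spike/MSE_input`;
- delay-corrected `MI*`: the estimate is shifted by the peak lag (searched
  over 0-50 ms, ties to the smallest lag, configurable) of the
  cross-correlogram between `x` and `p`, and MI is recomputed on the
  aligned pair.  The kernel and any downstream integration delay the
  estimate relative to `x`; the starred quantities separate that fixed
  delay from genuine information loss.

Windowed analysis decodes each consecutive window independently — fresh
prior, per-window rate estimates — matching the view of each window as an
independent measurement; the start-up transient (~tau) is negligible
against 20 s windows.

### Numerical integration

The ODE is integrated at the trace's time step with Heun's method
(explicit trapezoid).  The drift is exponential in `L`, hence stiff for
large `|L|`: whenever the Euler predictor or the Heun corrector would
move `L` by more than 1 natural-log unit in a bin, that bin is integrated
instead by adaptive clamped Euler substeps (each limited to 1 log-unit,
input held constant).  Without the guard, a burst of large-weight
impulses can push `L` past the attracting fixed point, and the explicit
step then oscillates between the clip bounds, destroying the estimate.
At physiological drives the guard triggers on a vanishing fraction of
bins and the scheme is plain Heun; refining the step tenfold changes MI
by ~10^-5 relative on all built-in regimes.  `L` is clipped to ±30 and
`p` to `[1e-12, 1 - 1e-12]` before logs; the clip costs <1e-10 bits per
bin.

## Optimal encoder

The Bayesian neuron tracks its input log-odds `L` (equation above) and an
output log-odds `G` driven by the prior dynamics alone; when
`L > G + eta/2` it spikes and `G -> G + eta`.  The threshold is tested
once per bin after the state update (sub-bin event detection is below the
0.2 ms resolution); `G` starts at `L(0)` (zero initial surprise — an
initial-condition convention of this package); the encoder is open-loop
(spikes do not feed back into `L`).  The realized firing rate is
monotonically non-increasing in `eta`, so `eta` is calibrated to a target
rate by geometric bisection on the frozen input (default tolerance 5%; a
0 Hz target is rejected as unattainable at finite `eta`).

### The rate-information optimum

The FI-versus-rate curve of the encoder, swept over `eta`, rises and then
falls: too few spikes miss ON periods, too many spikes fall in OFF
periods.  At high rates the *uncorrected* plug-in FI additionally
collapses (MI goes negative) because the posterior sharpens while
remaining delayed by the fixed encoding lag — a pure delay artifact that
grows with confidence, not an information loss.  The optimum is therefore
read from the delay-corrected curve `FI* = MI*_spike / MI*_input`; the
peak is refined by a quadratic fit in log-rate through the argmax and its
two neighbours (edge peaks fall back to the raw argmax).  At the built-in
regimes (N = 1000, 40 s records) the FI*-optimal rate averages ~36-40 Hz
across regimes.

## Parameter studies

- `sweep_information`: for each (tau, mu_q) cell, generate hidden state +
  population + input and report the seed-mean input fraction `F`.
  Defaults: N = 1000, 20 s per cell, 5 seeds — enough to resolve the
  trade-off at desk scale.  The mu_q required to reach a given `F` scales
  approximately inversely with tau, *provided* tau is well above the 5 ms
  PSC kernel: the kernel blurs switching on its own time scale, flattening
  `F` for tau <~ 20 ms (verified against an exact discrete forward-filter
  decode of the raw delta-spike observations, which shows no such
  flattening).  The packaged trade-off analysis therefore uses tau in
  50-200 ms; crossings of the target level are interpolated linearly in
  (log mu_q, F) and the slope fitted in log-log space.
- `bn_rate_info_curve`: one frozen input per regime; the eta grid is
  geometric between values calibrated to the ends of the requested rate
  span (default 1-100 Hz, 15 points).  Etas that never spike report
  FI = 0.
- `SaturationModel`: nonlinear least squares of
  `FI(r) = 2 f_sat (1/(1+e^-nu_sat r) - 1/2)` (zero at zero rate,
  saturating at `f_sat`); initial guesses `f_sat = max FI`,
  `nu_sat = 1/median rate`; asymptotic t-based standard errors and CIs;
  non-convergence raises with diagnostics rather than returning defaults.
  Coverage of the 95% CIs measured by simulation (sigma = 0.03 noise,
  200 replicates) is 0.96-0.98 — the mild over-coverage expected of
  asymptotic intervals at a dozen points.

## Determinism and problem sizes

One integer seed drives every random stream through `SeedSequence`
children (hidden state, population draw, population spikes, surrogates),
so any artifact is exactly reproducible from its configuration; pipeline
outputs embed a hash of the effective configuration.  Default problem
sizes (20-60 s records, N = 1000, dt = 0.2 ms, 5-20 seeds per condition)
were chosen so each analysis resolves its effect at a few percent
Monte-Carlo error on a single desktop core.

## What the synthetic data does and does not capture

The generator emulates the stimulus paradigm itself — binary world state,
conditionally-Poisson presynaptic population with optimal log-ratio
weights, PSC-shaped current — so tests against it validate the estimator
chain, the encoder, and the designed trade-offs.  It does not emulate
real neurons: no membrane nonlinearity, adaptation, conductance dynamics,
dendritic processing, correlated presynaptic activity, or synaptic
plasticity.  Results on synthetic spike trains therefore bound and
benchmark, but do not predict, the information transfer of recorded
cells; the pipeline emits the same metrics (`FI`, `MSE_P`, `FMSE`, ...)
for recorded spike trains so such data can be scored when available.

## Known limitations

- The MI estimator is a lower bound and assumes ergodic, approximately
  Poisson output; strongly history-dependent trains (the encoder at very
  small `eta`) drive it negative, and the delay correction recovers only
  the fixed-lag part of that bias.
- No limited-sampling bias correction is applied (out of scope by
  design); window-to-window SD is reported instead.
- The exact-ratio regime rates (`r_on,slow = 20/3 Hz`) are used
  internally so the time constants are exactly 50/10/20 ms; the rounded
  decimals conventionally quoted (6.7/13.3/...) are kept alongside for
  reporting.
- Conductance (dynamic-clamp) stimuli, multi-state hidden variables and
  weight learning are out of scope.
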