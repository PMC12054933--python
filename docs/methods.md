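# Methods

## Model

`qifnet` simulates globally coupled networks of quadratic integrate-and-fire
(QIF) neurons,

    tau_m dV_i/dt = V_i^2 + eta_i + ge*Se_i + ghi*Shi_i + gai*Sai_i
                    + I_i(t) + xi_i(t),

with membrane time constant `tau_m = 20 ms`. Each neuron carries a quenched
excitability `eta_i ~ N(0, (pi*tau0)^2)` (`tau0 = 0.02`), which for
`eta > 0` makes it an oscillator with free rate `sqrt(eta)/(pi*tau_m)` —
spontaneous rates span roughly 0–8 Hz — and for `eta < 0` an excitable unit
that fires only when driven. `I_i` is a square-pulse DC stimulus of
amplitude `(50*pi*tau0)^2`, which drives its targets at ~50 Hz; `xi_i` is
independent Gaussian noise of amplitude `4*pi*tau0` (see *Noise
discretization* below).

Neurons are split by the plasticity rule attached to their outgoing
synapses: excitatory (asymmetric Hebbian STDP), Hebbian inhibitory
(symmetric Ricker-wavelet STDP) and anti-Hebbian inhibitory (reversed
Ricker). The reference composition is N = 100 with 80/10/10. Spikes enter
three exponentially decaying synaptic drives per neuron (`tau_de = 2 ms`
excitatory, `tau_di = 5 ms` inhibitory); a spike of pre-synaptic neuron j
of class q increments the class-q drive of every post-synaptic neuron i by
`w_ij / N_q`. Weights obey Dale's sign: `w in [0, 1]` for excitatory
columns, `[-1, 0]` for inhibitory ones, no autapses.

Integration is stochastic Euler with `dt = 1 ms`. When `V` crosses
`Vp = 10` the spike time is corrected by `tau_m/V` (the residual time to
reach infinity), the neuron is reset to `Vr = -10` and held there for
`2*tau_m/V` — together these corrections make the numerical period of an
uncoupled oscillator agree with the closed form to first order in `1/Vp`
(verified to <2% in the tests, <0.1% in practice at dt = 1 ms).

## Plasticity

Weight updates are pairwise and event-driven: whenever pre- or
post-synaptic neuron fires, the synapse is updated once from the timing
difference `dt = t_post_last - t_pre_last` of the two most recent spikes
(nearest-spike pairing; partners that never fired are skipped; two neurons
firing in the same Euler step update their pairwise synapses exactly once,
at their corrected spike times). The raw change passes through steep tanh
soft bounds (`lambda = 100`) that pin the weight inside its class interval
while leaving it plastic almost everywhere, and is scaled by the learning
rate `gamma_l = 0.005`.

The three windows (amplitudes A+ = 5.296, A- = 2.949, A = 3; time constants
tau+ = 20 ms, tau- = 50 ms, tau = 100 ms) share a constant forgetting
offset `f = f0/M` with `f0 = 0.2`: uncorrelated firing slowly erodes
excitatory and Hebbian-inhibitory structure (and slowly strengthens
anti-Hebbian weights). The asymmetric window is continuous at dt = 0 and
potentiates *both* signs of tight coincidences (|dt| < ~7 ms); anti-causal
pairs beyond that depress. This detail matters for the consolidation
balance discussed below. The same `f` is applied to all three windows; the
per-class values are independent configuration knobs.

## Noise discretization (calibrated choice)

The model statement fixes the noise amplitude (`sigma = 4*pi*tau0`) but not
the discretization of the white-noise term in the Euler scheme. Three
readings are implemented (`NetworkParams.noise_mode`):

* `per_step` — the draw enters the update like the deterministic terms
  (per-step kick `sigma*dt/tau_m ≈ 0.013`),
* `em` — Euler–Maruyama in physical time (kick `sigma*sqrt(dt)/tau_m ≈ 0.40`),
* `em_tau_m` — Euler–Maruyama for the equation nondimensionalized by the
  membrane time (kick `sigma*sqrt(dt/tau_m) ≈ 0.056`). **Default.**

The default was calibrated against the model's stated dynamical regime:
with `em_tau_m` the coupled untrained network rests at ~1.1 Hz (stated:
about 1 Hz) with per-neuron rates inside [0, 8] Hz and CV ≈ 0.8–0.95, and —
critically — spontaneous memory recalls ignite from modular weight
matrices, at about one event per 9 s from the 0.7-template (the model's own
forgetting-time arithmetic makes one recall per ~11 s the maintenance
break-even). `per_step` gives 0.57 Hz rest and *no* recall ignition at any
sub-saturated weight level; `em` gives 4.5 Hz rest. The calibration is
asserted in `tests/test_network.py::TestIntegration::test_resting_statistics_calibration`.

## Experimental designs

* **Training** — 5 s rest, then `n_epochs` one-second epochs (800 ms DC on
  one memory's excitatory+inhibitory population, 200 ms relaxation;
  random or strict alternation), then 20 s consolidation; plasticity is on
  throughout. Options reproduce the protocol variants: untrained fraction,
  fresh random target subsets per epoch, multiplicative amplitude jitter.
* **Template matrices** — `MatrixTemplate(style="imperfect")` places all
  strong blocks intra-module (intra 0.7/−0.7, remaining entries
  half-Gaussian of sd 0.15 with the class sign). `style="learned"` places
  the anti-Hebbian strong block laterally (feed-forward to the other
  modules), which is the geometry training actually produces from its
  earliest epochs; consolidation experiments start from this geometry,
  since an "interrupted training" matrix with anti-Hebbian weights
  *intra*-module would self-quench every recall (gai = 400 acting inside
  the module) and no spontaneous events ever occur.
  `MatrixTemplate.trained()` (0.95 blocks, sd 0.05 elsewhere) stands for a
  completed training run, whose measured end state saturates near 0.99.
* **Recovery** — randomize a synapse subset (`E-out`, `I-out`,
  `all-but-EE`) of a learned matrix and evolve spontaneously; module-block
  weight statistics are tracked at a snapshot cadence. Horizons are scaled
  (minutes stand in for the hours-long originals); long-run parity is an
  extrapolation, not an assertion.
* **Capacity scan** — for each (M, NI) at fixed N: the point is
  non-accessible if the excitatory block cannot seed every memory
  (N − NI < M); otherwise a learned template is built (inhibitory pools
  split as evenly as possible, empty pools allowed below the NI = 2M line)
  and 120 s of resting dynamics are classified. The counting rule
  min(NE, NI_H, NI_A) ≥ M predicts the boundary, giving M* = floor(N/3) =
  33 at N = 100.
* **Overlap** — two stimuli sharing excitatory neurons, strict
  alternation; hubs are excitatory neurons whose mean outgoing weight to
  ≥ 2 modules' exclusive excitatory sets exceeds 0.5.

## Indicators

Windowed rates use non-overlapping 50 ms windows. CV requires ≥ 3 spikes
(NaN otherwise). Spike phases interpolate linearly between consecutive
spikes; outside a neuron's first/last spike the phase is undefined and the
neuron is excluded from the Kuramoto order parameter at those times
(freezing the phase instead would manufacture spurious coherence). The
weight-change rate K(t) is the mean off-diagonal weight derivative between
consecutive snapshots, normalized by N(N−1).

Recall detection slides a 0.2 s window (stride = window/4): a window is
attributed to module m when ≥ 50% of m's exclusive excitatory neurons spike
in it while every other module stays below that fraction; multi-module
windows count as one "joint" event; overlapping same-label windows merge.
The 50% participation fraction and the asynchrony ceilings used by the
stability verdict (time-median network R < 0.5, population rate < 20 Hz)
are declared defaults, configurable and reported with every verdict. A
configuration is *stable* when the background is asynchronous and every
module shows at least one recall over the horizon.

The forgetting-time estimate is a simulation oracle on a single excitatory
synapse held at w = 0.5: background drift from two independent 2 Hz Poisson
trains under the pairwise rule, recall boost from one emulated event (two
tightly synchronized volleys, 2.5 ms cross-neuron jitter, 0.2 s apart — a
module neuron fires ~2 spikes per recall); the estimate is boost/|drift|
(≈ 10–11 s at f = 0.1, infinite as f → 0).

## Synthetic data and what passing tests show

There is no external data: every experiment generates its own inputs
(excitabilities, noise, schedules, template matrices) from the declared
distributions. The generator therefore emulates exactly the idealized
conditions of the model — quenched Gaussian heterogeneity, white noise,
square-pulse stimuli, all-to-all or Erdős–Rényi coupling — and none of the
features of biological recordings (measurement noise, non-stationarity,
conductance synapses, delays). Passing tests show the model reproduces its
own stated dynamical regimes, not that those regimes describe a particular
biological circuit.

## Numerical choices and degenerate inputs

Euler drive decay uses the linear factor (1 − dt/tau_d) as part of the
scheme; weights are clamped to their class interval after each update with
tolerance 1e−12 to absorb floating-point overshoot of the tanh bounds;
non-finite membrane potentials abort the run with a diagnostic; a single
global RNG stream per experiment (draw order: excitabilities, initial
potentials, connectivity mask, initial weights, then per-step noise, with
protocol randomness drawn between initialization and the run) makes
manifests bit-reproducible. Simultaneous spikes are ordered by corrected
spike time; exact ties update each pairwise synapse once with dt = 0.

Problem sizes: the shipped experiments use N = 100 (reference), N = 1000
(ten-memory robustness run, 60 s) and 120–600 s horizons for resting runs —
sizes chosen so the full suite and the acceptance script each run in
minutes on one core while keeping every measured quantity in its asymptotic
regime (longer horizons change the reported medians by less than the
sampling tolerances).

## Known limitations

* The consolidation balance is knife-edge by construction (the model's own
  estimate puts maintenance break-even at one recall per ~11 s). Under the
  calibrated discretization, spontaneous events from the 0.7-template
  recover about 85% of the forgetting drift: inter-module excitatory
  weights and the anti-Hebbian lateral block consolidate correctly, but the
  mean intra-module excitatory weight drifts slowly down instead of up,
  the background settles near 1.2 Hz (windowed population-rate mode 0
  rather than 2 Hz), and per-module order parameters sit near 0.2–0.3.
  The root cause is event morphology: detected recalls are partial
  (~50–70% participation) and spread over tens of milliseconds, so
  anti-causal pairs beyond the ~7 ms potentiation notch partially cancel
  the causal reinforcement.
* At the capacity limit (M* = 33, singleton excitatory modules), modules
  whose lone excitatory neuron has eta below about −1.5 sigma are
  intrinsically silent and typically show no exclusive recall within the
  120 s scaled horizon (28–31 of 33 modules are recall-active).
* In the N = 1000 run, global sparse fluctuation peaks reach 10–12% of N
  per 0.2 s bin (mean rate ~0.27 Hz); module weights are nevertheless
  maintained (intra E–E 0.950 → 0.951 over 60 s).
* Exact-event integration, conductance synapses and transmission delays are
  out of scope.
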