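# Methods

## Model

`spikeforce` simulates recurrent networks of N spiking neurons whose
synaptic weight matrix is the sum of a strong random static part and a
learned rank-m feedback part,

    ω = G ω⁰ + Q η φᵀ .

The sparse static matrix ω⁰ (connection probability p, zero-mean normal
entries) places the network in a chaotic spiking regime at sufficiently
large gain G.  The encoders η (N×m, entries uniform on [-1, 1]) project the
network's own decoded output x̂(t) = φᵀ r(t) back into every neuron as a
current Q η x̂, where r(t) are the double-exponentially filtered spike
trains (rise τ_R = 2 ms, decay τ_D = 20 ms unless stated; unit area per
spike).  During training the decoders φ are updated every Δt of simulated
time by recursive least squares (RLS),

    e(t) = x̂(t) − x(t)
    P(t) = P(t−Δt) − P r rᵀ P / (1 + rᵀ P r)
    φ(t) = φ(t−Δt) − P(t) r e(t)ᵀ ,      φ(0) = 0,  P(0) = I_N λ⁻¹,

which clamps the output error from the first presentation of the teaching
signal x(t) while the feedback loop tames the chaos (FORCE learning).  A
run has three phases: chaotic settling (RLS off), training (RLS every Δt),
and testing (decoders frozen).  On any fixed sample stream the update
above is algebraically identical to batch ridge regression with penalty
λ‖φ‖², which is the suite's primary correctness oracle.  A `plain` RLS
variant that applies the φ update with the pre-update gain P(t−Δt)r is
exposed as a configuration flag; the two variants differ only in the
transient, not in the convergence order, and the default is the
`denominator` form above because it is the one that equals ridge
regression exactly.

Three integrate-and-fire models are provided, integrated by forward Euler
(thresholds detected after the update, resets applied before the next
step, spike times recorded at the end of the step):

* **theta**: dθ/dt = (1−cos θ) + π²(1+cos θ)I, spike at the π crossing
  with θ ← θ − 2π.  For constant I > 0 the rate is √I per unit time —
  the closed form used in the oracle tests.
* **LIF**: τ_m v̇ = −v + I with absolute refractory period τ_ref = 2 ms;
  ISI under constant drive is τ_ref + τ_m ln((I−v_reset)/(I−v_t)).
* **Izhikevich**: C v̇ = k(v−v_r)(v−v_t) − u + I with adaptation
  u̇ = a(b(v−v_r) − u), u ← u + d at each spike (standard parameter set:
  C = 250, v_r = −60, v_t = −20, v_peak = 30, v_reset = −65, a = 0.01/ms,
  b = 0, d = 200 pA, k = 2.5, bias 1000 pA = rheobase).

A rate-unit baseline uses the type-I transfer r = F√s (s ≥ 0, else 0)
with τ_s ṡ = −s + Gω⁰r + Qηx̂.

### Units and time bases

LIF and Izhikevich benchmark presets run with milliseconds as the time
unit.  The theta model is dimensionless; its benchmark presets use the
second as the unit time, because the benchmark parameter set (feedback
gain Q = 1e4 acting on an O(1) supervisor, trained mean rates of tens of
Hz, chaos onset near G = 0.02) is self-consistent only on that time base:
a current of 1e4 drives a theta neuron at √1e4 = 100 per unit time, i.e.
100 Hz, not 100 kHz.  The LIF benchmark also runs in seconds (so the
printed λ⁻¹ = 0.0025 corresponds to an O(10³) initial RLS gain and a
single presynaptic spike deflects the membrane by ~1 mV); its integration
step is 5e-5 s, fine enough to resolve threshold crossings with the bias
at exactly the threshold value.  All library operations are
unit-agnostic: the caller chooses the unit and all time constants,
steps and frequencies are expressed in it.

### Static-weight statistics

The nonzero entries of ω⁰ are Normal(0, σ²).  Two published conventions
exist for σ and the package exposes both: σ² = (Np)⁻¹ (`variance="np"`)
and σ² = (Np²)⁻¹ (`variance="np2"`).  The spiking presets use (Np²)⁻¹,
the convention under which the benchmark G values reproduce the reported
behavior (measured here: theta chaos onset at G ≈ 0.02, trained rates
within a few percent of the benchmark values).  For the LIF and theta
models the sample mean of the entries is removed (per-row in the LIF
preset: with the bias exactly at threshold, any per-neuron net DC bias
systematically detunes the operating point; globally elsewhere).  The
rate-network preset uses σ = 1/(F√(Np)): because the type-I transfer
r = F√s amplifies currents by F, the extra 1/F keeps the chaotic
fluctuations of Gω⁰r commensurate with the O(1) learned feedback Qηx̂
(Q = 1.5), which is the balance the FORCE scaling argument
Q = O(G σ_ω √⟨r²⟩) expresses.  With this scale the trained rate network
keeps every unit below 30 Hz and converges like N⁻¹, as expected for the
smooth baseline.

### Numerical scheme for the synaptic filters

Filters are linear, so decay is applied exactly (multiplication by
exp(−dt/τ)) and the h → r coupling of the double exponential uses the
closed-form one-step propagator
τ_rτ_d(e^{−dt/τ_d} − e^{−dt/τ_r})/(τ_d − τ_r); spike impulses are
discrete jumps of the rise variable at the spike step.  This keeps the
per-spike area of r correct to O(dt²), verified to within dt/τ_d in the
suite.  The compiled simulation kernel maintains the projections
y₁ = φᵀr and y₂ = φᵀh by the same scalar recurrences, so the feedback
current uses the current approximant at every integration step at O(m)
cost; the projections are recomputed from scratch at every RLS boundary
to eliminate floating-point drift.

### Initial conditions

Phases are uniform on (−π, π] for the theta model.  LIF/Izhikevich
membrane potentials are uniform on [v_reset, 30 mV]: with bias currents at
rheobase or threshold, a network started strictly below threshold never
fires, so the initially suprathreshold fraction supplies the igniting
burst from which recurrent activity self-sustains.  u = 0, filters at 0,
all draws seeded.

## Benchmark presets and problem sizes

The presets reproduce the desk-scale benchmark experiments: the 1000-unit
rate network and 2000-neuron theta/LIF/Izhikevich networks trained on a
5 Hz sinusoid (and sawtooth, Van der Pol, product-of-sines variants for
theta), the Lorenz system, note-song storage, a songbird-like circuit
driven by a 500-component feedforward pulse chain, and a movie-replay
circuit driven by an external high-dimensional temporal signal (HDTS).
Every printed physics parameter (N, p, G, Q, λ⁻¹, Δt, phase durations)
is frozen in `PARAMETER_MANIFEST` and asserted by a table-driven test.

The test suite runs reduced versions chosen once as the package's CI
conditions and kept fixed: oscillator-rate checks use N = 1000 with
1–2 s settling, 2 s training and 2 s testing (three seeds, ±20% band);
convergence sweeps use N ≤ 2000 with three seeds (the standalone
reproduction script extends the rate sweep to N = 4000); the acceptance
script runs the full N = 2000 presets.  The
long-sequence experiments are represented by desk-scale substitutes:

* a one-bar note song (T = 1 s, 5 components, quarter notes as positive
  2 Hz half-waves) learned by 1000 Izhikevich neurons with τ_d = 50 ms,
  25 s of training, scored by the moving-error replay classifier;
* a Lorenz supervisor (components normalized to zero mean and unit
  max-amplitude, 2 s settling + 25 s training for 1000 theta neurons at
  G = 14, Q = 1e4), checked for bounded two-lobed output and
  perturbation divergence rather than trajectory match (the target is
  chaotic);
* a 64-pixel synthetic "moving blob" movie (2 s, one orbit of a Gaussian
  blob) replayed by 1000 Izhikevich neurons driven by an external
  8-pulse HDTS with the standard 250 ms pulse width (4 Hz assembly
  rate), W_in entries uniform on [−4e3, 4e3], 32 s of training.

## Quantitative read-outs

* **Replay classifier**: E(t) = Σ_i ∫_t^{t+T}(x̂_i(t′) − x_i(t′−t))² dt′
  computed by FFT cross-correlation; a replay is a below-threshold local
  minimum found by a greedy left-to-right scan with non-overlapping
  period-length windows.  The critical value defaults to 25% of the
  supervisor's squared power over one period (the benchmark description
  leaves it unspecified); the perfect-tiling and shifted-copy cases in
  the suite pin the classifier's behavior at both extremes.
* **Chaos diagnostic**: paired simulations identical except that one
  spike is untransmitted (the neuron's own reset still applies — skipping
  the reset is a no-op for the theta phase and numerically divergent for
  the quadratic models).  Divergence is summarized as the fraction of
  final-quarter spikes unmatched between the 1 ms-binned rasters
  (0 = identical, →1 = decorrelated); the onset sweep calls a gain
  chaotic when that fraction exceeds 0.5 with at least 20 tail spikes, in
  a majority of trials.
* **Convergence experiment**: test-phase time-averaged L2 error versus N,
  log–log slope by least squares with a bootstrap CI over repeats.  The
  rate-network sweep trains for 8 s (twice the benchmark schedule):
  measuring a convergence *rate* requires the training residual to be
  negligible, and with 4 s of training the residual dominates at small N
  and bends the fitted slope well away from the clean N⁻¹ law that the
  converged errors follow (measured: slope −1.06, CI [−1.14, −0.99],
  over N = 500–4000 once converged).  The smallest networks (N = 250)
  still sit above the scaling law (reservoir too small), so the rate
  sweep starts at N = 500.
* **Population activity**: Hann-windowed periodogram of the binned
  population rate, dominant frequency excluding DC.

## Known limitations

* Forward Euler without within-step spike-time interpolation biases
  single-neuron rates at the ≲1% level at the benchmark steps; the
  dt-halving tests bound this.
* Chaos onsets under the frozen sweep conditions (N = 500/1000, deletion
  divergence > 0.5 in a majority of three trials) land at G = 0.02
  (theta, 4 s horizon — near-onset rates are sub-Hz, so divergence needs
  seconds to develop) and G = 500 (Izhikevich, 0.6 s horizon), i.e. at
  and within a factor of two of the benchmark values.  The onset concept
  is criterion-dependent in this regime: with the bias exactly at
  rheobase the network is marginally excitable at any gain, and longer
  horizons or larger N shift the detected Izhikevich onset downward.
* The theta network does not learn the discontinuous 5 Hz sawtooth at
  the benchmark parameters in this implementation (test correlation
  ~0.3–0.6 and a post-training rate of ~22 Hz instead of the reported
  29 Hz), although the same configuration learns the sinusoid to
  correlation 0.999 and the Izhikevich network learns the same sawtooth
  to correlation 0.83.  A step discontinuity is not representable by
  filtered spike trains (the readout is continuous), and in seconds
  units the τ_D = 20 ms filter attenuates the ramp's harmonics above
  ~8 Hz; smoothing the edge over 10–20 ms helps but does not fully
  close the gap.  This is the one benchmark behavior the package does
  not reproduce; the corresponding test is expected to fail and the
  discrepancy is documented rather than papered over.
* The synthetic movie/HDTS circuits exercise the machinery of the
  natural-stimulus experiments on smooth synthetic signals; passing them
  shows the circuit stores and manipulates temporally structured
  high-dimensional signals, not that it reproduces any particular natural
  stimulus.
* No synaptic delays, conductances, Dale's-law constraint, or adaptive
  integration.
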