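# Methods

## The model

The striatum is modelled as two populations of GABAergic medium spiny
neurons — D1 ("Go", direct pathway) and D2 ("No-Go", indirect pathway) —
that inhibit themselves and each other, plus fast spiking interneurons
(FSIs) providing feedforward inhibition, preferentially to D1.  All
populations are driven by excitatory cortical input.  The central quantity
is the population rate difference

    Delta_MSN = lam_D1 - lam_D2,

and the central phenomenon is the **decision transition threshold (DTT)**:
the cortical rate at which Delta_MSN changes sign from positive (Go bias)
to negative (No-Go bias).  The DTT exists because the connectivity is
asymmetric — D2→D1 inhibition is stronger than D1→D2 (J12 > J21), and
FSI→D1 is stronger than FSI→D2 (J1F > J2F) — so rising cortical drive
recruits proportionally more inhibition onto D1.

### Mean-field rate model

Population rates obey (time in ms)

    d(lam_D1)/dt = -0.01 lam_D1 + S(-J11 lam_D1 - J12 lam_D2 - J1F lam_FSI + e_D1)
    d(lam_D2)/dt = -0.01 lam_D2 + S(-J21 lam_D1 - J22 lam_D2 - J2F lam_FSI + e_D2)

with the saturating transfer S(z) = z / sqrt(z^2 + 1).  The leak constant
0.01/ms (100 ms relaxation) is interpreted as a membrane-like population
time constant; steady rates are bounded by 100·S ≤ 100 Hz.  Coupling
magnitudes are stored unsigned (defaults: J11 0.06, J12 0.21, J21 0.04,
J22 0.22, J1F 0.09, J2F 0.06, JC1 1.06, JC2 1.0); every equation applies
signs explicitly.

Two input scenarios create the D1 advantage required for a Go regime:

* **additive** — equal unit gains, D1 receives an extra rate Delta_CTX:
  e_D1 = lam_CTX + Delta_CTX, e_D2 = lam_CTX;
* **multiplicative** — equal rates, stronger D1 gain: e_D1 = JC1·lam_CTX,
  e_D2 = JC2·lam_CTX with JC1 > JC2.

Dropping the leak and linearizing S(z) = z yields closed-form fixed points
(a 2×2 linear balance) and exact decompositions of Delta_MSN: Inp_str +
Inp_add for the additive scenario and D1_eff + D2_eff (plus comm_eff in
the symmetric-FSI variant) for the multiplicative one.  The implementation
computes the rates by a generic linear solve and the decomposition terms
from the printed expressions; their agreement to machine precision is a
test invariant, cross-checked against an independent `numpy.linalg.solve`
oracle on 1000 random weight/input draws.

Nonlinear fixed points are found with a hybrid Powell root from the four
corners of [0, 100]² (plus the centre), with residual tolerance 1e-8.  When
recurrent inhibition pins one population at 0 Hz the smooth system has no
non-negative root; those boundary steady states are found by a bracketed
scalar solve for the free population, accepted only if the pinned
population's raw derivative is non-positive, and validated with a
*projected* residual (inward derivatives on the boundary do not count).
If several candidates survive, the terminal state of a long forward-Euler
run selects the dynamically realized one.  Forward integration uses Euler
with dt = 0.1 ms and floors rates at 0 after each step; drives may be
transiently negative (S is odd) so the smooth Jacobian analysis remains
valid.

Stability is assessed from the 2×2 Jacobian built with the analytic
derivative S'(z) = (z² + 1)^(-3/2).  For the reference parameters, both
eigenvalues are real and negative at every fixed point on the standard
sweeps (tested).

### The FSI drive and its calibration

The circuit data constrain the FSI→MSN weights but not the cortex→FSI
transfer, so the FSI rate model is a design choice.  Three modes are
provided: clamped (lam_FSI fixed), proportional, and dynamic (a first-order
rate equation with the same leak and transfer and cortical gain `jcf`).

A purely proportional drive lam_FSI = g·lam_CTX cannot produce a
multiplicative-scenario DTT for *any* gain: in the linear balance both the
cortical and the FSI contributions to Delta_MSN scale with lam_CTX (the
numerator is lam_CTX·(0.0056 − 0.0072·g) for the reference weights), so the
sign never changes, and numerically the full nonlinear sweep is
single-signed as well.  The default proportional mode therefore includes a
rheobase-like cortical **threshold**:

    lam_FSI = gain · max(0, lam_CTX - threshold).

This reflects FSI physiology — their rheobase is far above that of MSNs
(650 vs 437.5 pA in the spiking model here), so they are nearly silent at
low cortical drive and then follow cortex steeply.  The gain is fixed at
3.0 (FSI rates reach ~32 Hz at the top of the standard sweep, a
physiological range); the threshold was calibrated **once** so that the
multiplicative reference sweep crosses at 13 Hz, giving threshold = 9.4 Hz
(`scripts/calibrate_fsi_gain.py`, bisection at 0.1 Hz sweep resolution).
With this single calibration the additive scenario (Delta_CTX = 1 Hz)
crosses at ≈ 14.8 Hz and the critical Delta_CTX above which no transition
exists in the 0–20 Hz sweep is ≈ 1.7 Hz.  These two are *predictions* of
the calibrated model, not separately tuned; the additive threshold sits
structurally above the multiplicative one for every (gain, threshold) pair
on the 13 Hz calibration manifold.

### DTT detection

Sweeps evaluate Delta_MSN on a dense grid (default 0–20 Hz, 0.1 Hz step;
nonlinear fixed points or linear closed forms, recorded in metadata).  Sign
changes between adjacent grid points are linearly interpolated; an exact
zero on a grid point resolves to that point.  A DTT is reported iff there
is exactly one crossing; the crossing direction (positive→negative or the
reverse) is recorded, and zero or multiple crossings are flagged data, not
errors.

### Anatomy → effective weights

Effective MSN→MSN magnitudes are the product N·rho·IPSC·R·tau of
presynaptic count, connection probability, unitary IPSC amplitude, input
resistance and synaptic time constant, from paired-recording measurements
(rho 0.26/0.07/0.36/0.27; IPSC 42/107/107/133 pA; R 238 MΩ; tau 12 ms).
The product fixes only ratios; the normalization constant is chosen so the
D2→D2 entry equals the reference 0.22.  So normalized, all four magnitudes
match the reference weight table within 10%, and the FSI probability ratio
0.54/0.36 = 1.5 equals J1F/J2F exactly.

### Dopamine

Dopamine potentiates cortical synapses onto D1 and depresses those onto
D2; it is parameterized as jc1 → jc1·(1+alpha), jc2 → jc2·(1−alpha)
(alpha > 0: high dopamine; alpha < 0: depletion).  In the mean field the
D1-dominant low-rate regime requires jc1·(J22+J21) > jc2·(J11+J12), a
margin of only 0.0056 at the reference gains, so the DTT exists only for
alpha roughly in (−0.010, +0.006); outside it the sweep is single-signed.
An all-negative sweep is reported as effective DTT 0 (the Go regime is
abolished), an all-positive one as +inf (the No-Go regime lies beyond the
swept range); the effective DTT is monotone non-decreasing in alpha
(tested), and strict shifts are demonstrated at alpha = ±0.005.  The
spiking network tolerates larger |alpha| because its gain asymmetry (3.6
vs 3.0 nS) has a wider margin.

### GPe arbitration

Pallidostriatal feedback is a constant inhibition of the FSI rate (floored
at 0), optionally switched on at an onset time (step protocol, default
400 ms).  The default operating point, lam_CTX = 16 Hz (just above the
13 Hz threshold), starts D2-biased; a 10 Hz FSI inhibition step releases
D1 preferentially and flips the bias to D1 under normal dopamine, but not
under depletion (alpha = −0.2), where the cortical-gain reversal dominates.
The operating point and step size are protocol choices (the source
protocol states the qualitative regime, not values).  In the spiking model
the step is a tonic inhibitory conductance onto the FSIs.

### Symmetric FSI projections

Setting J1F = J2F = jf_sym (default 0.075) removes the feedforward
asymmetry.  These comparisons are statements about the linear closed
forms and are evaluated there (grid 0–40 Hz): in the saturating model the
100 Hz rate ceiling makes Delta_MSN approach zero from above instead of
crossing.  Results with reference weights: the additive scenario keeps a
single positive→negative crossing (≈ 27–31 Hz) whether the FSI rate is
clamped or co-modulated — the MSN↔MSN asymmetry suffices; along the
co-modulated multiplicative diagonal Delta_MSN stays positive (the common
FSI term is proportional to (J11+J12) − (J21+J22) > 0 and favours D1).  A
clamped-FSI multiplicative crossing requires jc1·(J22+J21) < jc2·(J11+J12),
i.e. a gain ratio below 27/26; it exists e.g. at jc1 = 1.02 but not at the
reference 1.06 — with the reference gains both decomposition terms are
positive, so no clamping level can impose a crossing.

### Noisy inputs

The noisy-DTT protocol ramps the cortical rate in a staircase (0–20 Hz,
0.5 Hz per 500 ms) with Ornstein–Uhlenbeck noise (time constant 5 ms) on
the common rate and on the extra D1/D2 drives, integrates the rate
dynamics, locates the crossing time t\* on a 200 ms-smoothed trace, and
reports |∫Delta_MSN| over [t\*−Δ, t\*] and [t\*, t\*+Δ], normalized by the
zero-noise run.  The window Δ defaults to 2000 ms: the linearized gain
d(Delta_MSN)/d(Delta_CTX) ≈ 54 makes Delta_MSN near the crossing
noise-dominated, so very short windows measure noise rather than the bias.
Even so, single-trial normalized areas are noise-inflated; the `n_seeds`
option averages the Delta_MSN trace over independent realizations first,
estimating the expected bias.  The implementation does not reproduce a
specific area-reduction magnitude; only the normalization, determinism and
flagged-no-crossing behaviours are contractual.

### Robustness scan

Connectivity robustness draws the four MSN→MSN magnitudes and the extra
drives uniformly within ±100% of their reference values (magnitudes
floored at 1e-4), runs a linear-mode lam_CTX sweep per draw (0–20 Hz), and
applies the existence criterion: exactly one positive→negative crossing.
Reported are per-sample flags, binned marginal existence per parameter,
and per-pair centroids of the DTT-admitting samples.  With the defaults,
roughly a quarter of draws admit a DTT, existence collapses toward very
small J11/J22, and the centroids lie near the reference values.

## The spiking network

2000 D1 + 2000 D2 MSNs and 80 FSIs, leaky integrate-and-fire with
conductance synapses:

    C dV/dt = -G_rest (V - V_rest) - g_exc (V - V_exc) - g_inh (V - V_inh) + I_ext.

MSN parameters: V_rest −80 mV, V_th −45 mV, V_inh −64 mV, C 200 pF, G_rest
12.5 nS (τ_m = 16 ms, R = 80 MΩ, rheobase 437.5 pA).  FSIs: V_th −54 mV,
V_inh −76 mV, C 500 pF, G_rest 25 nS.  τ_exc = 0.3 ms, τ_inh = 2 ms,
t_ref = 2 ms, reset to V_rest.  Synapses are alpha conductances
g(t) = J·(t/τ)·e^(1−t/τ) (peak J at t = τ), implemented by the equivalent
two-state linear filter propagated exactly over each step; the membrane
uses exponential Euler with conductances frozen over dt = 0.1 ms.
Single-neuron firing matches the closed-form LIF rate within 1 Hz at
dt = 0.01 ms (test), and halving dt changes population rates by < 2% under
a frozen input realization.

Connectivity is independent Bernoulli per ordered pair (no autapses, no
multapses) with the measured probabilities and peak conductances: D1→D1
0.26/0.5 nS, D1→D2 0.07/1.0 nS, D2→D2 0.36/1.0 nS, D2→D1 0.27/1.2 nS
(delay 2 ms), FSI→D1 0.54/2.5 nS, FSI→D2 0.36/2.5 nS (delay 1 ms).  FSIs
receive cortical excitation only.  Delayed events are delivered through a
per-neuron ring buffer; delay fidelity is tested to one step.

Cortical drive: each neuron pools 250 independent afferents at the quoted
per-afferent rate, so 10 Hz reproduces the 2500 Hz aggregate background;
peak conductances 3.6 nS (D1), 3.0 nS (D2), 5.0 nS (FSI).  The swept drive
*replaces* the background (they coincide at 10 Hz).  Scenario II is the
3.6/3.0 nS asymmetry at equal rates; scenario I uses equal peaks with
extra D1 afferent rate.  Membrane potentials start uniformly in
[V_rest, V_th); the first 500 ms are discarded from all rate estimates.
Uncorrelated Poisson input is drawn in-kernel (Knuth sampler, one seeded
stream); correlated input is delivered as precomputed per-neuron events.

Population rates are spike counts over neurons × analysed time; Delta_MSN
confidence intervals are 95% bootstrap over per-neuron rates (1000
resamples).  The spiking DTT is the sign-change interpolation of the
trial-mean Delta_MSN curve.

### Correlated cortical input (two-layer MIP)

Input correlations use a two-layer multiple-interaction process: a mother
Poisson train (rate R_in) is thinned with copy probability B′ into one
pool-mother per target neuron, and each pool-mother is thinned with copy
probability W into that neuron's 250 afferents.  Afferent rate is
R_in·B′·W (held constant across correlation conditions by inverting for
R_in); pairwise count correlation is W within a pool and B = B′·W between
pools, so B ≤ W by construction.  Copies are synchronous (no jitter); for
Poisson mothers the binned-count correlation equals the copy probability
exactly, at any bin width.  The default estimator bin is 5 ms.

For network simulation the pooled conductance is all that matters, so each
selected mother event is delivered once with amplitude
Binomial(250, W)·J_peak — exactly equivalent to materializing the
afferents, since per-afferent copies are conditionally independent
Bernoulli draws.  FSIs keep independent Poisson drive at the same
per-afferent rate in correlation experiments.

The correlation grid labels each (B′, W) cell d1-/d2-biased when the 95%
bootstrap CI of Delta_MSN excludes zero, else "high-conflict" (a
configurable absolute threshold is available); W_opt is the W-grid arg-max
of the trial-mean Delta_MSN (default grid step 0.05).

## Problem sizes and defaults used by the tests

The test-suite and acceptance-script protocols are desk-scale choices:
mean-field sweeps at 0.1 Hz resolution; the spiking threshold sweep on a
5–30 Hz grid at 2.5 Hz steps with 3 seeds and 2.5 s per trial (0.5 s
discarded); correlation grids with B′ = 0.01, W ∈ {0.05 … 0.5}, 2 seeds
and 2 s trials; the robustness scan at 1500–10 000 draws.  Network
realizations use dedicated connectivity seeds; every stochastic quantity
is seeded and reproducible.

## What the synthetic inputs do and do not emulate

The MIP inputs emulate stationary cortical rates and pairwise spike-count
correlations with exactly synchronous shared spikes.  Real cortical input
has temporally jittered correlations, rate nonstationarity and
oscillatory structure, none of which is modelled; passing tests therefore
demonstrate the circuit's threshold behaviour under controlled first- and
second-order input statistics, not under realistic cortical dynamics.
Likewise the mean-field FSI drive is a modelling choice calibrated to one
landmark, not a measured transfer function.

## Known limitations

* The mean-field dopamine window is narrow (see above); large symmetric
  gain changes abolish rather than shift the threshold.
* The saturating transfer bounds rates at 100 Hz; symmetric-FSI
  comparisons are linear-analysis statements.
* GPe enters only as a static or stepped inhibition of FSIs; no pallidal
  dynamics, no GPi/SNr readout, no plasticity, no TANs, no gap junctions,
  single action channel.
* The noisy-input area metric is protocol-sensitive; only its contractual
  behaviours are tested.
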