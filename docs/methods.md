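# Methods

This note documents the model equations as implemented, the numerical
choices, the defaults of every analysis protocol, and the known
limitations — in particular what the desk-scale test conditions do and
do not establish about full-scale networks.

## Spiking-network model

Each neuron obeys the Izhikevich quadratic membrane equation with a
quenched spike threshold `v_θ,i`. The recovery variable `u` is global
per population by default: it relaxes toward `b (⟨v⟩ - v_r)` with time
constant `τ_u` and receives a kick `κ / N` per network spike. A
per-neuron mode (`u_mode="per_neuron"`, kick `κ` per own spike) is
available for comparison; the global approximation tracks the
macroscopic dynamics of per-neuron recovery closely and is what the
mean-field reduction assumes. Synapses are exponential low-pass
filters: a spike of presynaptic neuron `j` increments `s_i` of each
target by the coupling weight `J_ij`; the postsynaptic current is
conductance-based, `g s_i (E - v_i)`. Multi-population networks carry
one synaptic channel per (presynaptic population, synapse type), each
with its own `g`, `E`, `τ_s`.

**Spike cutoff and reset.** `v_p` and `v_0` are free parameters of the
integrator. The mean-field reduction is exact in the limit
`v_p → +∞`, `v_0 → -∞` placed symmetrically about the vertex of the
membrane quadratic; the defaults `v_p = v̄_θ + 240 mV` and
`v_0 = (v_r + v̄_θ) - v_p` approximate that symmetric limit while
keeping the Euler step stable at dt = 0.01 ms. Halving dt changes the
single-neuron inter-spike interval by <0.1% and a 1-s network rate
by <2% (tested).

**Integration.** Explicit Euler, default dt = 0.01 ms, implemented as
numba-compiled kernels. Spike times are recorded at the step where
`v ≥ v_p` without sub-step interpolation; at dt = 0.01 ms the
resulting jitter is immaterial for every statistic computed here.
Rates are spikes/ms internally; Hz appears only in outputs.

**Connectivity.** Each neuron receives exactly `⌊pN⌋` inputs of weight
`J/(pN)` for all-to-all and random-sparse topologies (sampling without
replacement), preserving the total recurrent drive `J` of the
mean-field limit. Ring networks draw `⌊pN⌋` partners i.i.d. from the
power-law kernel `ρ(dist) ∝ dist^-d` of circular distance and sum
duplicate draws into a single weight. The i.i.d. scheme is deliberate:
once `pN` exceeds the size of the kernel bulk (always the case at
p = 0.2 with d ≥ 1), sampling without replacement would force most
partners into the kernel tail and destroy the spatial locality that the
ring topology exists to provide — with distinct-partner sampling the
activity bump diffuses over the whole ring even in homogeneous
networks. Self-connections are excluded (circular distance 0 is
undefined under the power law).

## Mean-field model

The reduction of a Lorentzian-disordered population is the four-ODE
system given in the README. Two notational points are fixed here
because the typeset source forms are ambiguous: the heterogeneity terms
are implemented as `Δ_v k² σ_v (v - v_r) / (πC)` in the rate equation
and `πCr (Δ_v σ_v + πCr/k)` in the potential equation — the unique
reading under which both terms carry the dimensions of the remaining
terms (pA·pF⁻¹·ms⁻¹ after division by C) and the quiescent state
`(0, v_r, 0, 0)` is an exact fixed point at I = 0 (verified to
integrator precision).

Cross-population synapses are composed mechanically: each afferent
synapse type `m` contributes `g_m s_m (E_m - v)` to the potential
equation and `-g_m s_m r` to the rate equation, with
`τ_m ds_m/dt = -s_m + τ_m J_m r_pre`. Conductance and reversal
potential follow the presynaptic cell type (the transmitter is a
property of the source population): RS afferents use E = 0 mV, FS/LTS
afferents E = -65 mV. The two-population coupling matrix is read as
J[post, pre]: RS→RS = 16, FS→RS = 16, RS→FS = 4, FS→FS = 4, giving RS
cells the balanced excitatory/inhibitory drive the coupling table was
designed for. The synapse list API accepts explicit (pre, post) pairs,
so the opposite reading is one argument away.

**Stiffness.** Nearly homogeneous populations (Δ_v ≲ 0.05 mV for FS)
produce rate spikes sharp enough to destabilize Euler at dt = 0.01 ms;
the regime classifier retries at dt/5 and dt/25 before giving up. All
reported results use the default step unless a retry fired.

**Fixed points** are located by damped Newton iteration (numerical
Jacobian, backtracking line search) on a residual scaled per state
variable; stability is read off the Jacobian eigenvalues.

## Regime classification and bifurcation detection

A grid cell (I, Δ_v) is classified by integrating from two initial
conditions — quiescent `(0, v_r, 0, 0)` and an excited self-consistent
high-rate guess — for 2000 ms of settling plus 1000 ms of analysis:

* **oscillatory** if either trace shows ≥ 5 cycles with trough-to-peak
  amplitude ≥ 10 Hz (peak finding with prominence 5 Hz);
* otherwise **bistable** if the two steady rates differ by > 10 Hz;
* otherwise monostable **active**/**quiescent** by the 10 Hz rate
  threshold.

Band boundaries are refined by 3 bisection steps between
differently-labeled neighbors. Classification is invariant to doubling
the settle time (tested).

The ramp-based detectors mirror what can be applied to spiking data:
under a slow input ramp (default 0.01 pA/ms), the fold is the input at
the first crossing of r_T = 10 Hz, and the Hopf interval is the input
range sustaining ≥ 5 consecutive cycles of ≥ 10 Hz amplitude. Spiking
rate traces are smoothed (Gaussian, 10 ms for the slow RS dynamics,
2 ms for the fast FS rhythm at 50–75 Hz) before detection. Two biases
matter and are documented where used: ramped detection lags the true
fold slightly (critical slowing), so ramp-detected spiking folds are
compared against the equally-lagged ramp-detected mean-field fold;
ramped *deterministic* Hopf crossings suffer a large bifurcation delay
(tens of pA) that finite-size fluctuations remove in spiking networks,
so spiking Hopf onsets are compared against the attractor-based grid
boundary instead.

A known systematic: spiking FS networks with IQR-matched *Gaussian*
thresholds begin oscillating ~7 pA below the Lorentzian mean-field
boundary, at every heterogeneity level tested. The Gaussian family
lacks the high-threshold Lorentzian tail whose reluctant neurons damp
collective synchronization; this is a real family difference, not
detector noise (it is stable across seeds).

## Bump protocol

Defaults follow the working-memory protocol: ring of N = 2000 RS
neurons, p = 0.2, kernel exponent d = 1.5, baseline 30 pA (inside the
bistable band), stimulation of a contiguous arc of fraction `p_in`
raised to 60 pA during 500–1000 ms, recording for 3000 ms. Per-neuron
spike trains at 10 samples/ms are smoothed with a unit-area Gaussian of
σ = 200 samples (20 ms); the final 200 ms are averaged, normalized to
the maximum rate, and compared to the binary input mask via RMSE; the
off-bump mean summarizes leakage. The stimulated arc is centered at
ring position 0 — rotation invariance of the metrics makes the location
immaterial (tested). A trial with no spike in the test window is
flagged `silent` and scores RMSE = √p_in by the same formula. Scaled
trials (N = 400, 1500 ms) preserve the heterogeneity ordering of RMSE
and leakage and are what the acceptance checks run.

## Reservoir protocol

Ring networks (d = 0.75) of strongly adapting RS neurons (κ = 100 pA)
are prepared in three regimes (I = 45, 55, 70 pA). After a 2000-ms
burn-in (extended to end at a rate trough when the settled trace
oscillates, in which case the onsets span one measured intrinsic cycle;
otherwise they span 250 ms), a pulse is applied per onset and the
smoothed single-neuron rates over the following 250 ms form the
response matrix X.

Protocol constants the source protocol leaves open, frozen here:

* **Pulse**: contiguous arc of 25% of the ring, +60 pA for 20 ms —
  strong enough to evoke spikes in the stimulated arc in every regime
  (the RS rheobase from rest is ~70 pA, so pulses at the scale of the
  regime drives would often evoke nothing).
* **Features**: spike trains at 1 sample/ms smoothed with a 10-ms
  Gaussian. The slowest target component is 20 Hz; a 10-ms kernel
  attenuates it by ~2× while suppressing spike-timing noise. Heavier
  smoothing (25 ms) erases the 20-Hz content entirely and was rejected.
* **Ridge strength**: γ = 0.1 · trace(XX^T)/N, i.e. one tenth of the
  mean per-neuron feature energy. Scale-relative, hence comparable
  across network sizes and regimes. Orders-of-magnitude weaker ridge
  overfits trial-specific activity (test error above the zero-predictor
  baseline); γ is an explicit argument everywhere.
* **Kernel statistics**: K = X_a^T (X X^T + γI)^{-1} X_a per training
  trial; Q is the entrywise mean absolute difference of K over
  unordered trial pairs and q = ΣQ²; q/T² is reported alongside for
  cross-T comparison. The participation ratio uses the row-centered
  covariance spectrum of the concatenated responses.

**What the scaled runs show.** At the desk scale used in tests
(N = 300, 10 onsets, 8 training/2 test), the dimensionality trend
(participation ratio increasing with Δ_v) reproduces in all three
regimes. The test-error and kernel-variance orderings only partially
reproduce there, for a structural reason: a homogeneous quiescent
network at desk scale sits exactly at a fixed point, so all its trials
are bit-identical — its readout generalizes perfectly regardless of
representational quality, and its kernel variance is ~0 by
construction. Heterogeneous networks pay a trial-variability penalty
that 8 training trials cannot average out; extrapolating the observed
penalty scaling, the orderings invert only near the full protocol size
(40 training trials). Scaled-run outcomes therefore bound what can be
claimed about full-scale behavior for these two metrics.

## Entrainment

The forced mean-field input is `I(t) = I0 + α sin(2πωt)`. Coherence is
the phase-locking value of the analytic-signal phases after band-pass
filtering both traces within ±30% of ω (2nd-order Butterworth,
forward-backward). A rate trace without fluctuation returns 0 with a
flag. Defaults: I0 = 60 pA with the κ = 100 pA RS preset — inside its
oscillatory band, intrinsic rhythm ~5 Hz — α = 4 pA, 8000 ms simulated,
2000 ms discarded; doubling the scored window changes locked-cell PLV
by <0.02. Bandwidths are reported as the number of ω-grid cells with
coherence > 0.9.

## Disorder sampling

Truncated sampling uses the inverse CDF restricted to the quantile
interval [F(low), F(high)] — exact, deterministic given the seed, no
rejection loop. Truncation is symmetric about the center with the lower
bound at `v_r` (margin 0 by default): thresholds stay strictly above
rest, and the open interval is enforced by resampling boundary hits.
The Lorentzian↔Gaussian width conversion matches interquartile ranges:
sd = Δ / z₀.₇₅ ≈ Δ / 0.6745.

## Problem sizes in tests and the acceptance script

Spiking simulations are scaled to one CPU: network comparisons at
N ∈ {200, 1000}, ramp detections at N = 1000, bump trials at N = 400
over 1.5 s, reservoir sweeps at N = 300 with 10 onsets, and 2–5 seeds
per condition. These sizes reproduce every qualitative ordering that
full-scale runs establish except the two reservoir metrics discussed
above; all defaults for full-scale protocols (N = 2000, 50 onsets,
10 seeds) remain the package defaults.

## Known limitations

* Explicit Euler only; no adaptive or higher-order integrators beyond
  the step-refinement fallback in the regime classifier.
* No synaptic delays, conductance noise, or plasticity.
* The mean-field model assumes all-to-all coupling and Lorentzian
  disorder; sparse-network and Gaussian-disorder deviations are
  quantified empirically (see the ~7 pA Hopf offset above) rather than
  corrected analytically.
* Oscillation detection is amplitude-thresholded (10 Hz trough-to-peak);
  regimes with shallower limit cycles classify as monostable.
* The synthetic protocols emulate stationary in-silico networks with
  deterministic dynamics; they contain no measurement noise, no input
  noise, and no slow drift, so passing tests speak to model behavior,
  not to robustness against experimental artifacts.
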