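# Methods

## Model overview

`cbgtsim` simulates action selection in the cortico-basal
ganglia-thalamic (CBGT) loop with populations of conductance-based leaky
integrate-and-fire neurons. Ten populations are modeled: Cx and CxI
(cortex), dSPN, iSPN and FSI (striatum), GPeP and GPeA (external
pallidum), STN, GPi and Th. For an n-choice agent all populations except
the FSI and CxI pools are instantiated once per action channel. The
direct pathway (Cx→dSPN→GPi→Th) carries channel-specific disinhibition,
the indirect/hyperdirect pathways (Cx→iSPN→GPeP→STN→GPi and Cx→STN→GPi)
oppose it, and the pallidostriatal projections (GPeA→dSPN/iSPN/FSI) are
wired only in the stop-signal network, where arkypallidal activation
provides the slow selective brake.

## Membrane and synapse equations

Each neuron integrates, by forward Euler at dt = 0.1 ms,

    C dV/dt = -(C/Taum)(V - V_rest) + I_syn + I_ext
    I_syn   = -g_AMPA (V - E_AMPA) - g_NMDA B(V) (V - E_AMPA)
              - g_GABA (V - E_GABA)
    B(V)    = 1 / (1 + (Mg/3.57) exp(-0.062 V))

A neuron at or above V_thresh at the start of a step spikes (all such
neurons spike simultaneously), is reset to V_reset and clamped there for
the refractory period. Receptor gates decay exponentially (Tau_AMPA =
2 ms, Tau_GABA = 5 ms, Tau_NMDA = 100 ms) and are incremented by the
pathway efficacy per presynaptic spike. The forward-Euler/threshold
scheme is validated against the closed-form LIF f–I curve
(rate = 1000 / (t_ref + Taum ln((V_inf - V_reset)/(V_inf - V_thresh))))
to better than 2 % at dt = 0.1 ms, on both the single-population and the
whole-network integration paths.

Background input is a doubly stochastic process: each step the rate is
drawn from a normal with the configured mean (FreqExt × n_connections, in
spikes/s) and unit variance on the rate scale, truncated at zero; integer
events per neuron are then Poisson at that rate. The mean event count per
step is exactly rate·dt while neurons receive decorrelated shot noise,
which is what keeps population activity asynchronous at the small sizes
used here. A purely Gaussian per-step count with unit rate variance would
be almost deterministic at dt = 0.1 ms and would synchronize whole
populations.

## Connectivity

Pathways are declared as (src, dest, receptor, type, con, eff, plastic)
rows; "syn" rows connect same-channel copies, "common" rows connect
diffusely. Realized connectivity uses a fixed in-degree draw: every
postsynaptic neuron receives exactly round(con × n_available) presynaptic
partners sampled uniformly without replacement (no self-connections),
deterministically under the build seed. At 10–60 neurons per population,
binomial in-degree variance would impose a large quenched asymmetry
between otherwise symmetric action channels (pilot measurements showed
baseline thalamic rates differing two-fold between channels), destroying
chance-level choice; fixing the in-degree removes that artifact while
keeping expected connection counts and partner randomness.

When n channels are built, the efficacy of every pathway converging from
channelized populations onto a shared pool (FSI, CxI) or onto a common
target is divided by n, so the expected summed drive onto those targets
is invariant in the channel count.

## Default parameters

The shipped parameter files (`src/cbgtsim/data/*.json`) are this
package's own operating point: membrane constants (C = 0.5 model units,
Taum = 20 ms, thresholds −50/−55/−70 mV, 2 ms refractory), background
rates tuned so baseline firing is stable and distinguishable (Cx ≈ 5,
CxI/FSI ≈ 12, SPN ≈ 1–2, GPeP/GPi ≈ 30, GPeA ≈ 12, STN ≈ 15, Th ≈ 3
spikes/s), and pathway efficacies tuned so that the ramping stimulus
produces decisions within tens to a few hundreds of ms. They do not claim
equality with any published parameter table. Corticostriatal Cx→SPN
projections carry a fast AMPA component whose efficacy *is* the plastic
weight w (initial 0.03, ceiling dpmn_wmax = 0.08 for dSPN / 0.06 for
iSPN) plus a slower NMDA component scaled proportionally to w; the NMDA
time constant makes striatal drive integrate the cortical stimulus over
~100 ms, which is what gives graded reaction times.

External stimulus magnitudes (maxstim, stop amplitudes) are mapped onto
background frequency through `stim_scale` = 100 spikes/s per unit, so the
default maxstim 0.8 adds 80 spikes/s to a ~216 spikes/s cortical
background. The ramp recursion I_ramp ← I_ramp + 0.1(I_target − I_ramp)
is applied every integrator step.

## Decision readout

The thalamic rate used for the boundary crossing is a 20 ms sliding
window over each channel's Th spike counts, evaluated every step once the
window has filled; the first channel whose smoothed rate exceeds the
threshold (default 30 spikes/s) wins, with simultaneous crossings going
to the higher rate and exact ties broken uniformly at random. The window
length is a compromise: with ~60 thalamic neurons, shorter windows (5–10
ms) let correlated baseline bursts cross 30 spikes/s spuriously within a
second of simulated time, while 20 ms keeps the false-crossing rate
negligible over multi-second runs at the cost of ~20 ms readout lag
(reaction times therefore have a 20 ms floor).

## Trial phases

Phase 0 (decision) runs until a crossing or the choice timeout (default
1000 ms; 300 ms for the stop task), with the ramp applied to every
channel's cortex. Phase 1 (consolidation/movement) runs only on decided
trials, for the movement time (default N(250, 1.5) ms, truncated
positive; `["constant", N]` and `["mean", N]` variants supported); the
selected channel's cortex receives sustainedfraction (default 0.7) of the
phase-0 peak drive, other channels return to baseline, and reward is
drawn at the phase's end. Phase 2 removes all external drive for the
inter-trial interval (default 600 ms). Phase 1 and 2 durations are fixed
by their draws, so only phase 0 has a state-dependent end. Timed-out
("none") trials deliver no reward and trigger no Q or weight update.

## Plasticity

On each decided trial: RPE = reward − Q[choice]; Q[choice] += q_alpha·RPE
(defaults q_alpha = 0.1, C_scale = 30, Q0 = 0.5). The phasic dopamine
transient is C_scale·RPE decaying with dpmn_tauDOP (5 ms) on a zero
baseline; its analytic integral, times an activity-dependent eligibility,
updates the selected channel's weights:

    dw = dpmn_alphaw · elig · C_scale·RPE · dpmn_tauDOP/1000
    elig = (mean Cx rate, kHz) × (mean SPN rate, kHz) over phase 1

with dpmn_alphaw = +39.5 for dSPN and −38.2 for iSPN and clipping to
[0, dpmn_wmax]. Expressing the eligibility in kHz² makes the default
constants yield per-trial steps of a few 10⁻³, i.e. learning and
unlearning over a handful of trials; no additional scale constant is
introduced. Q-values never influence choice — selection depends only on
the corticostriatal weights, which is verifiable by freezing Q while
keeping weights fixed.

## Stimulation

Optogenetic input applies the opsin current I_opto = g(V − V_ChR2) for
g ≥ 0 and −g(V − V_NpHR) for g < 0 (V_ChR2 = 0 mV, V_NpHR = −400 mV) to
every neuron of the target population. As printed, that expression is
negative at rest for positive conductances, so it enters dV/dt with a
leading minus sign; this makes positive amplitudes excitatory and
negative ones inhibitory, and the current vanishes exactly at the
corresponding opsin reversal. Stop signals add stop_amplitude (on the
stim scale) to the AMPA background frequency of the target population.
Both share the six-parameter schedule (amplitude, population, onset,
duration, probability, channel); fractional probabilities select
round(p·n_trials) trials without replacement, durations may name a phase
(spanning exactly the realized phase) or a numeric window on the clock
started at phase-0 onset, and channels resolve as "all", "any"
(uniform per trial) or a label. Overlapping protocols sum.

## Synthetic conditions and what the tests show

All inputs are generated: there are no recorded datasets. The default
network (≈ 500 neurons for two channels) is deliberately small so that a
trial simulates in under a second of wall time; the acceptance runs use
4 × 55 trials for the chance-level check, 20 trials for the decision
boundary, and 5 trials each for the suppression and stop-window checks.
Consequences of the scale: reaction times are shorter and less variable
than behavioral data (tens to ~200 ms plus the 20 ms readout floor), and
learning saturates within a few trials. Passing tests demonstrate the
mechanisms — chance-level symmetric choice, boundary-gated decisions,
reversal tracking, stop-signal suppression — not quantitative fits to
animal or human behavior.

## Numerical choices and edge cases

dt = 0.1 ms forward Euler throughout; non-finite membrane state raises an
integration error naming the population and time. Phase durations are
step-counted and rounded to microseconds so defaults report exactly
1000/600 ms. Reward magnitudes are zero-truncated Gaussians
(reward_std = 0 gives exactly reward_mu). Poisson volatility gaps are
max(1, Poisson(λ)); exact-mode change points fall at λ, 2λ, …;
contingency flips swap the two probabilities and rotate cyclically for
n > 2. A "GPe" pathway name resolves to GPeP. An all-"none" batch reports
undefined (NaN) performance rather than dividing by zero. Simulation i of
a batch uses seed base+i and is a pure function of (configuration, seed),
so serial and process-pool execution are bit-identical.

## Known limitations

Single-compartment neurons and pooled receptor gates (no per-synapse
saturation or delays); no spatial structure or distance-dependent
conductance; plasticity only at Cx→dSPN/iSPN with a trial-level
eligibility rather than spike-timing resolution; cortex is a stimulus
relay, not a recurrent evidence integrator; parameter values are an
operating point chosen for stable qualitative behavior at test scale, not
a fit to electrophysiology.
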