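# cbgtsim

A spiking-network simulator of decision making in the cortico-basal
ganglia-thalamic (CBGT) loop, for computational and systems neuroscientists
who want to generate behavioral and neural predictions from a biologically
structured circuit model — choices, reaction times, and simultaneous firing
rates of every nucleus, under manipulations such as reward reversal,
optogenetic stimulation and stop signals.

## The model

The agent is a network of conductance-based leaky integrate-and-fire
neurons organized into the CBGT nuclei: cortex (excitatory Cx, inhibitory
CxI), striatum (dSPN, iSPN, FSI), external pallidum (prototypical GPeP and
arkypallidal GPeA), subthalamic nucleus (STN), internal pallidum (GPi) and
thalamus (Th). Each membrane follows

    C dV/dt = -(C/τ_m)(V - V_rest) - g_AMPA (V - E_AMPA)
              - g_NMDA B(V)(V - E_AMPA) - g_GABA (V - E_GABA) + I_ext

with exponentially decaying receptor gates and the standard magnesium
block B(V) on NMDA. For an *n*-choice task, every population except FSI
and CxI is replicated once per action channel, and convergent efficacies
onto shared pools are rescaled by 1/n so their expected drive is
independent of the channel count.

A trial runs through three phases. In the **decision phase** a ramping
stimulus, `I_ramp(t) = I_ramp(t-dt) + 0.1 [I_target - I_ramp(t-dt)]`, is
added to the cortical external input frequency of every channel; the first
thalamic population whose smoothed firing rate exceeds the decision
boundary (30 spikes/s) selects its channel, and the elapsed time is the
reaction time. In the **consolidation phase** the selected channel's
cortex holds 70 % of the peak decision-phase drive for the movement time
(default N(250, 1.5) ms); reward is delivered at its end, and the reward
prediction error `RPE = reward − Q[choice]` releases phasic dopamine that
strengthens Cx→dSPN and weakens Cx→iSPN weights of the selected channel
(clipped to [0, w_max]). The **inter-trial interval** (600 ms) lets the
network relax. Q-values are book-kept with a delta rule but never enter
the decision: choice depends only on the corticostriatal weights.

The environment supplies per-action reward probabilities (the "conflict"
tuple) that reverse at change points set by a volatility parameter λ
(exactly every λ trials, or at Poisson(λ) gaps). Stop signals step up the
AMPA background frequency of STN and GPeA, and optogenetic stimulation
injects the opsin current `I_opto = g(V − V_ChR2)` for excitation
(`g ≥ 0`) or `−g(V − V_NpHR)` for inhibition (`g < 0`), with reversal
potentials 0 mV and −400 mV.

## Worked example

```python
from cbgtsim import run_simulations, extract_frames

config = {
    "experimentchoice": "n-choice",
    "seed": 30,
    "channels": ["left", "right"],
    "number_of_choices": 2,
    "n_trials": 20,
    "volatility": [10, "exact"],       # reward contingencies flip every 10 trials
    "conflict": (0.75, 0.25),
    "corticostriatal_plasticity_present": True,
}
results = run_simulations(config, n_sims=3, cores=1)
frames = extract_frames(results)
print(frames.performance)
print(f"total performance: {frames.total_performance:.1f}%")
print(f"mean RT: {frames.rt_dist['decisiontime'].mean():.0f} ms "
      f"over {len(frames.rt_dist)} decided trials")
```

prints

```
  action  percentage
0   left   68.333333
1  right   31.666667
total performance: 61.7%
mean RT: 97 ms over 60 decided trials
```

With the contingencies flipping every 10 trials the agent tracks the
richer action: the percentage of optimal choices (total performance) sits
above chance overall, rising within each block and dipping below 50 %
immediately after each reversal. `frames.firing_rates` holds the
per-millisecond firing-rate traces of every nucleus for plotting, and each
results bundle echoes its configuration plus `datatables` (per-trial
choice, optimal choice, reward, reaction time and phase durations),
`Q_df`, and any recorded weight or stimulation traces.

A CLI wraps the same pipeline:

```bash
cbgtsim run --config config.json --n-sims 3 --out results.zip
cbgtsim extract --results results.zip --out frames/
cbgtsim fixtures --scale tiny --out fixtures/
```

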