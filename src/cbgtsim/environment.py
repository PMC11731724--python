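"""Task environment: reward schedules, trial phases and the decision readout.

A trial runs through three phases:

* **phase 0 (decision)** — a ramping stimulus drives the external input
  frequency of every cortical channel toward ``maxstim`` (recursion
  ``I_ramp(t) = I_ramp(t-dt) + 0.1 [I_target - I_ramp(t-dt)]``, added to the
  baseline external frequency).  The first thalamic population whose
  smoothed firing rate exceeds the decision boundary (default 30 spikes/s)
  selects its channel; the elapsed time is the reaction time.  If no
  crossing occurs within the choice timeout the decision is "none".
* **phase 1 (consolidation / movement)** — only on decided trials: the
  selected channel's cortex receives ``sustainedfraction`` of the phase-0
  peak drive for the movement time (default drawn from N(250, 1.5) ms);
  the reward is drawn at the end of this phase and drives plasticity.
* **phase 2 (inter-trial reset)** — all external drive off for the
  inter-trial interval (default 600 ms).

Reward contingencies come from the conflict tuple and flip at change
points given by the volatility parameter (exactly every lambda trials, or
at Poisson(lambda) gaps); at a change point the probabilities swap for two
actions and rotate cyclically for more than two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .core import ConfigError
from .engine import RealizedNetwork
from .stimulation import StimulationProtocol, opto_drive_current

__all__ = [
    "RewardSchedule",
    "TrialPhaseConfig",
    "TrialRecord",
    "TraceRecorder",
    "generate_reward_schedule",
    "ramp_update",
    "check_decision",
    "sample_movement_time",
    "run_trial",
]


# --------------------------------------------------------------------- reward


@dataclass
class RewardSchedule:
    """Per-trial reward probabilities and magnitudes for each action."""

    probs: np.ndarray                 # (n_trials, n_actions)
    change_points: list[int]
    optimal: np.ndarray               # (n_trials,) index of the richest action
    reward_mu: float = 1.0
    reward_std: float = 0.1

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    def sample_reward(self, trial: int, action: int, rng: np.random.Generator) -> float:
        """Bernoulli delivery at the trial's probability; magnitude is a
        zero-truncated Gaussian N(reward_mu, reward_std)."""
        if rng.random() >= self.probs[trial, action]:
            return 0.0
        if self.reward_std == 0:
            return float(self.reward_mu)
        return float(max(0.0, rng.normal(self.reward_mu, self.reward_std)))


def _permute(probs: np.ndarray) -> np.ndarray:
    # two actions swap; more than two rotate cyclically
    if probs.size == 2:
        return probs[::-1].copy()
    return np.roll(probs, 1)


def generate_reward_schedule(
    conflict: Sequence[float],
    volatility: tuple[float | None, str] | Sequence,
    n_trials: int,
    reward_mu: float = 1.0,
    reward_std: float = 0.1,
    rng: np.random.Generator | None = None,
) -> RewardSchedule:
    """Build the reward schedule from the conflict tuple and volatility.

    ``volatility`` is ``[lam, mode]`` with mode "exact" (contingencies flip
    exactly every lam trials) or "poisson" (inter-change gaps are
    max(1, Poisson(lam))).  ``lam=None`` disables switching (required when
    n_trials is 1 and for the stop-signal task).
    """
    conflict = np.asarray(conflict, dtype=float)
    if np.any(conflict < 0) or np.any(conflict > 1):
        raise ConfigError("conflict entries are probabilities and must lie in [0, 1]")
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    lam, mode = volatility[0], volatility[1]
    if mode not in ("exact", "poisson"):
        raise ConfigError(f"volatility mode must be 'exact' or 'poisson', got {mode!r}")
    change_points: list[int] = []
    if lam is not None:
        lam = float(lam)
        if lam <= 0 or lam >= n_trials:
            raise ConfigError(
                "volatility lambda must satisfy 0 < lambda < n_trials "
                "(it cannot be 0 or the total number of trials); "
                "set it to None to disable switching"
            )
        if mode == "exact":
            step = int(round(lam))
            change_points = list(range(step, n_trials, step))
        else:
            if rng is None:
                raise ConfigError("poisson volatility requires a random generator")
            t = 0
            while True:
                t += max(1, int(rng.poisson(lam)))
                if t >= n_trials:
                    break
                change_points.append(t)

    probs = np.empty((n_trials, conflict.size))
    current = conflict.copy()
    cps = set(change_points)
    for i in range(n_trials):
        if i in cps:
            current = _permute(current)
        probs[i] = current
    optimal = probs.argmax(axis=1)
    return RewardSchedule(probs, change_points, optimal, reward_mu, reward_std)


# ---------------------------------------------------------------- trial setup


@dataclass
class TrialPhaseConfig:
    """Timing and readout parameters of the trial phase machine."""

    thalamic_threshold: float = 30.0      # spikes/s decision boundary
    choice_timeout: float = 1000.0        # ms, max phase-0 duration
    movement_time: Any = None             # None | ["constant", N] | ["mean", N]
    inter_trial_interval: float = 600.0   # ms, phase-2 duration
    sustainedfraction: float = 0.7        # phase-1 drive / phase-0 peak
    maxstim: float = 0.8                  # ramp target on the stim scale
    rate_window: float = 20.0             # ms, sliding window for the readout

    def __post_init__(self) -> None:
        for name in ("thalamic_threshold", "choice_timeout", "inter_trial_interval", "rate_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.sustainedfraction <= 1.0:
            raise ConfigError("sustainedfraction must lie in [0, 1]")


@dataclass
class TrialRecord:
    """Behavioral outcome of one trial."""

    trial: int
    decision: str                 # channel label or "none"
    correctdecision: str
    reward: float
    decision_time: float          # ms; equals phase-0 duration
    phase0_ms: float
    phase1_ms: float
    phase2_ms: float
    opto_applied: bool = False
    stop_applied: bool = False
    phase0_peak_drive: float = 0.0
    phase1_drive: float = 0.0
    decision_rate: float = 0.0    # winning channel's smoothed Th rate at decision
    phase1_rates: dict = field(default_factory=dict)  # mean sp/s of Cx/dSPN/iSPN, selected channel


def ramp_update(i_ramp: float, i_target: float) -> float:
    """One step of the cortical ramping recursion (gain 0.1 per dt)."""
    return i_ramp + 0.1 * (i_target - i_ramp)


def check_decision(
    th_rates: np.ndarray,
    threshold: float,
    elapsed: float,
    choice_timeout: float,
    rng: np.random.Generator,
) -> tuple[str, int | None]:
    """Decision readout: first channel whose smoothed thalamic rate exceeds
    the boundary wins; simultaneous crossings go to the higher rate with
    exact ties broken uniformly at random; no crossing by the timeout gives
    ("timeout", None)."""
    th_rates = np.asarray(th_rates, dtype=float)
    if np.any(th_rates < 0):
        raise ConfigError("firing rates must be non-negative")
    above = th_rates > threshold
    if np.any(above):
        best = th_rates.max()
        winners = np.nonzero(th_rates == best)[0]
        pick = winners[0] if winners.size == 1 else winners[int(rng.integers(winners.size))]
        return ("decision", int(pick))
    if elapsed >= choice_timeout:
        return ("timeout", None)
    return ("continue", None)


def sample_movement_time(spec: Any, rng: np.random.Generator) -> float:
    """Phase-1 duration in ms: default N(250, 1.5); ["constant", N] fixes N;
    ["mean", N] draws from N(N, 1.5).  Draws are truncated positive."""
    if spec is None:
        mean, sd = 250.0, 1.5
    else:
        kind, value = spec[0], float(spec[1])
        if value <= 0:
            raise ConfigError("movement time must be positive")
        if kind == "constant":
            return value
        if kind == "mean":
            mean, sd = value, 1.5
        else:
            raise ConfigError(f"movement_time spec must be ['constant', N] or ['mean', N], got {spec!r}")
    for _ in range(100):
        mt = rng.normal(mean, sd)
        if mt > 0:
            return float(mt)
    return mean  # pragma: no cover - unreachable at sane parameters


# ------------------------------------------------------------------ recording


class TraceRecorder:
    """Accumulates per-step spike counts and stimulation traces.

    Spike counts are kept per population instance per step and binned to
    1 ms for the popfreqs table.  Stimulation values are logged once per
    millisecond for each active protocol.
    """

    def __init__(self, net: RealizedNetwork, record_variables: Sequence[str] = ()):
        self.net = net
        self.record_variables = list(record_variables)
        self.counts: list[np.ndarray] = []
        self.stim_rows: list[dict] = []
        self.weight_rows: list[dict] = []
        self._ms_mark = -1

    def record_step(self, spiked: np.ndarray) -> None:
        self.counts.append(self.net.instance_counts(spiked))

    def record_stim(self, trial: int, proto: StimulationProtocol, chans: Sequence[str], value: float) -> None:
        name = "optogenetic_input" if proto.kind == "opto" else "stop_input"
        if name not in self.record_variables:
            return
        ms = int(self.net.t)  # log once per simulated millisecond
        key = (name, trial, proto.population, tuple(chans), ms)
        if key == getattr(self, "_last_key", None):
            return
        self._last_key = key
        for ch in chans:
            self.stim_rows.append(
                dict(variable=name, time=self.net.t, trial=trial,
                     population=proto.population, channel=ch, value=value)
            )

    def record_weights(self, trial: int) -> None:
        if "weight" not in self.record_variables:
            return
        for (channel, target), w in self.net.weights.items():
            self.weight_rows.append(
                dict(variable="weight", time=self.net.t, trial=trial,
                     population=target, channel=channel, value=w)
            )

    def popfreqs(self):
        """Population firing-rate traces, one column per instance, 1 ms bins."""
        import pandas as pd

        from .core import population_rate

        if not self.counts:
            return pd.DataFrame(columns=["Time"])
        counts = np.asarray(self.counts)
        cols = {}
        for i, inst in enumerate(self.net.instances):
            cols[inst.label] = population_rate(counts[:, i], window=1.0, dt=self.net.dt, n_neurons=inst.n)
        n_bins = len(next(iter(cols.values())))
        out = pd.DataFrame({"Time": np.arange(n_bins, dtype=float)})
        for k, v in cols.items():
            out[k] = v
        return out


# ----------------------------------------------------------------- trial loop


class _ThRateWindow:
    """Rolling per-channel thalamic spike counts over the smoothing window."""

    def __init__(self, net: RealizedNetwork, window_ms: float):
        self.slices = [net.instance("Th", ch).sl for ch in net.spec.channels]
        self.n_th = np.array([s.stop - s.start for s in self.slices], dtype=float)
        self.win_steps = max(1, int(round(window_ms / net.dt)))
        self.window_s = self.win_steps * net.dt / 1000.0
        self.buf = np.zeros((len(self.slices), self.win_steps))
        self.pos = 0
        self.sum = np.zeros(len(self.slices))

    def push(self, spiked: np.ndarray) -> np.ndarray:
        new = np.array([spiked[s].sum() for s in self.slices], dtype=float)
        self.sum += new - self.buf[:, self.pos]
        self.buf[:, self.pos] = new
        self.pos = (self.pos + 1) % self.win_steps
        return self.sum / (self.n_th * self.window_s)


def run_trial(
    net: RealizedNetwork,
    trial: int,
    schedule: RewardSchedule,
    phase_cfg: TrialPhaseConfig,
    protocols: Sequence[StimulationProtocol],
    rng: np.random.Generator,
    recorder: TraceRecorder | None = None,
) -> TrialRecord:
    """Run one trial through phases 0/1/2; returns its behavioral record.

    Mutates the network state in place.  Reward is drawn (and returned in
    the record) at the end of phase 1; the caller applies plasticity.
    """
    channels = net.spec.channels
    dt = net.dt
    i_target = phase_cfg.maxstim * net.spec.stim_scale
    rate_offset = np.zeros(net.n_neurons)
    ext_current = np.zeros(net.n_neurons)
    cx_slices = {ch: net.instance("Cx", ch).sl for ch in channels}
    window = _ThRateWindow(net, phase_cfg.rate_window)

    opto_applied = False
    stop_applied = False

    def apply_stimulation(phase: int, t_since_phase0: float) -> bool:
        """Fill stimulation offsets/currents; returns True if any opto active."""
        nonlocal opto_applied, stop_applied
        any_opto = False
        for proto in protocols:
            if not proto.active(trial, phase, t_since_phase0):
                continue
            chans = proto.targets[trial] if proto.targets else tuple(channels)
            for inst in net.instances_of(proto.population):
                if inst.channel is not None and inst.channel not in chans:
                    continue
                if proto.kind == "stop":
                    rate_offset[inst.sl] += proto.amplitude * net.spec.stim_scale
                    stop_applied = True
                else:
                    ext_current[inst.sl] += opto_drive_current(proto.amplitude, net.V[inst.sl])
                    any_opto = True
                    opto_applied = True
            if recorder is not None:
                recorder.record_stim(trial, proto, chans, proto.amplitude)
        return any_opto

    # ------------------------------------------------------------- phase 0
    t0 = net.t
    i_ramp = dict.fromkeys(channels, 0.0)
    peak_ramp = 0.0
    decision_idx: int | None = None
    decision_time = float(phase_cfg.choice_timeout)
    decision_rate = 0.0
    max_steps = max(1, int(round(phase_cfg.choice_timeout / dt)))
    step_count = 0
    while True:
        elapsed = step_count * dt
        rate_offset.fill(0.0)
        ext_current.fill(0.0)
        for ch in channels:
            i_ramp[ch] = ramp_update(i_ramp[ch], i_target)
            rate_offset[cx_slices[ch]] += i_ramp[ch]
        peak_ramp = max(peak_ramp, max(i_ramp.values()))
        use_current = apply_stimulation(0, elapsed)
        spiked = net.step(rng, rate_offset, ext_current if use_current else None)
        if recorder is not None:
            recorder.record_step(spiked)
        th_rates = window.push(spiked)
        step_count += 1
        elapsed = step_count * dt
        if elapsed < phase_cfg.rate_window:
            continue  # smoothing window not yet filled
        outcome, idx = check_decision(
            th_rates, phase_cfg.thalamic_threshold, elapsed, phase_cfg.choice_timeout, rng
        )
        if outcome == "decision":
            decision_idx = idx
            decision_time = round(elapsed, 6)
            decision_rate = float(th_rates[idx])
            break
        if outcome == "timeout" or step_count >= max_steps:
            break
    phase0_ms = round(step_count * dt, 6)

    # ------------------------------------------------------------- phase 1
    reward = 0.0
    phase1_ms = 0.0
    phase1_drive = 0.0
    phase1_rates: dict[str, float] = {}
    if decision_idx is not None:
        mt = sample_movement_time(phase_cfg.movement_time, rng)
        n_steps = max(1, int(round(mt / dt)))
        phase1_ms = round(n_steps * dt, 6)
        sel = channels[decision_idx]
        phase1_drive = phase_cfg.sustainedfraction * peak_ramp
        sel_slices = {
            pop: net.instance(pop, sel).sl for pop in ("Cx", "dSPN", "iSPN")
        }
        acc = dict.fromkeys(sel_slices, 0.0)
        t1 = net.t
        for _ in range(n_steps):
            rate_offset.fill(0.0)
            ext_current.fill(0.0)
            rate_offset[sel_slices["Cx"]] += phase1_drive
            use_current = apply_stimulation(1, net.t - t0)
            spiked = net.step(rng, rate_offset, ext_current if use_current else None)
            if recorder is not None:
                recorder.record_step(spiked)
            window.push(spiked)
            for pop, s in sel_slices.items():
                acc[pop] += spiked[s].sum()
        dur_s = (net.t - t1) / 1000.0
        for pop, s in sel_slices.items():
            phase1_rates[pop] = acc[pop] / ((s.stop - s.start) * dur_s)
        reward = schedule.sample_reward(trial, decision_idx, rng)

    # ------------------------------------------------------------- phase 2
    n_steps = max(1, int(round(phase_cfg.inter_trial_interval / dt)))
    for _ in range(n_steps):
        rate_offset.fill(0.0)
        ext_current.fill(0.0)
        use_current = apply_stimulation(2, net.t - t0)
        spiked = net.step(rng, rate_offset, ext_current if use_current else None)
        if recorder is not None:
            recorder.record_step(spiked)
        window.push(spiked)
    phase2_ms = round(n_steps * dt, 6)

    decision = channels[decision_idx] if decision_idx is not None else "none"
    return TrialRecord(
        trial=trial,
        decision=decision,
        correctdecision=channels[int(schedule.optimal[trial])],
        reward=reward,
        decision_time=decision_time if decision_idx is not None else float("nan"),
        phase0_ms=phase0_ms,
        phase1_ms=phase1_ms,
        phase2_ms=phase2_ms,
        opto_applied=opto_applied,
        stop_applied=stop_applied,
        phase0_peak_drive=peak_ramp,
        phase1_drive=phase1_drive,
        decision_rate=decision_rate,
        phase1_rates=phase1_rates,
    )
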