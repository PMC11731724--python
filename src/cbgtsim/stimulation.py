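"""Optogenetic and stop-signal stimulation protocols.

An optogenetic stimulus sets an opsin conductance ``g_opto`` on all neurons
of a target population; the resulting current is the piecewise expression

    I_opto = g_opto * (V - V_ChR2)        for g_opto >= 0   (channelrhodopsin)
    I_opto = -g_opto * (V - V_NpHR)       for g_opto <  0   (halorhodopsin)

with opsin reversal potentials V_ChR2 = 0 mV and V_NpHR = -400 mV.  The
expression as printed is negative at rest for positive conductances, so it
couples into the membrane equation with a leading minus sign: the drive
current added to dV/dt is ``-I_opto``, which makes positive amplitudes
depolarizing (excitatory) and negative amplitudes hyperpolarizing
(inhibitory), and vanishes exactly at the corresponding opsin reversal
potential.

A stop signal instead up-regulates the AMPA background frequency of its
target population by ``stop_amplitude`` for the protocol's active window.

Both kinds share a six-parameter schedule: amplitude, population, onset
(ms after phase-0 start), duration (ms, or a phase name that spans exactly
the realized phase), probability (fraction of trials, sampled without
replacement, or an explicit trial list) and channel ("all", "any" or a
label).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ConfigError

__all__ = [
    "V_CHR2",
    "V_NPHR",
    "PHASE_NAMES",
    "StimulationProtocol",
    "opto_current",
    "opto_drive_current",
    "stop_drive",
    "schedule_trials",
    "resolve_targets",
]

V_CHR2 = 0.0      # mV, channelrhodopsin reversal
V_NPHR = -400.0   # mV, halorhodopsin reversal

PHASE_NAMES = ("phase 0", "phase 1", "phase 2")


def opto_current(g_opto: float, V: np.ndarray | float) -> np.ndarray | float:
    """Opsin current for a signed conductance (piecewise in the sign)."""
    if g_opto >= 0:
        return g_opto * (np.asarray(V) - V_CHR2) if isinstance(V, np.ndarray) else g_opto * (V - V_CHR2)
    if isinstance(V, np.ndarray):
        return -g_opto * (V - V_NPHR)
    return -g_opto * (V - V_NPHR)


def opto_drive_current(g_opto: float, V: np.ndarray | float):
    """Opsin current as coupled into dV/dt (``-I_opto``), so that positive
    conductances depolarize at rest and negative ones hyperpolarize."""
    i = opto_current(g_opto, V)
    return -i


def stop_drive(f_ext: float, stop_amplitude: float) -> float:
    """Up-regulated AMPA background frequency during a stop window."""
    out = f_ext + stop_amplitude
    if out < 0:
        raise ConfigError(
            f"stop amplitude {stop_amplitude} drives background frequency negative"
        )
    return out


def schedule_trials(
    probability: float | Sequence[int],
    n_trials: int,
    rng: np.random.Generator,
) -> set[int]:
    """Trials on which a protocol is applied.

    A fraction p selects round(p * n_trials) distinct trials uniformly
    without replacement; an explicit list selects exactly those trials.
    """
    if isinstance(probability, (list, tuple, np.ndarray)):
        trials = [int(t) for t in probability]
        for t in trials:
            if not 0 <= t < n_trials:
                raise ConfigError(f"stimulated trial index {t} out of range [0, {n_trials})")
        return set(trials)
    p = float(probability)
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"stimulation probability must be in [0, 1], got {p}")
    k = int(round(p * n_trials))
    if k == 0:
        return set()
    return set(int(t) for t in rng.choice(n_trials, size=k, replace=False))


def resolve_targets(
    channel: str,
    channels: Sequence[str],
    n_trials: int,
    rng: np.random.Generator,
) -> list[tuple[str, ...]]:
    """Per-trial target channel sets for a protocol.

    ``"all"`` stimulates every channel on every trial, ``"any"`` draws one
    channel uniformly per trial, and a label names a fixed channel.
    """
    channels = list(channels)
    if channel == "all":
        return [tuple(channels)] * n_trials
    if channel == "any":
        return [(channels[int(rng.integers(len(channels)))],) for _ in range(n_trials)]
    if channel not in channels:
        raise ConfigError(f"unknown stimulation channel {channel!r}; known: {channels}")
    return [(channel,)] * n_trials


@dataclass
class StimulationProtocol:
    """One opto or stop protocol, with its realized per-trial schedule."""

    kind: str                        # "opto" | "stop"
    amplitude: float                 # signed conductance (opto) or spikes/s step scale (stop)
    population: str
    onset: float = 0.0               # ms after phase-0 start
    duration: float | str = "phase 0"
    probability: float | Sequence[int] = 1.0
    channel: str = "all"
    trials: set[int] = field(default_factory=set)
    targets: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("opto", "stop"):
            raise ConfigError(f"stimulation kind must be 'opto' or 'stop', got {self.kind!r}")
        if self.onset < 0:
            raise ConfigError("stimulation onset must be >= 0")
        if isinstance(self.duration, str) and self.duration not in PHASE_NAMES:
            raise ConfigError(
                f"phase-named duration must be one of {PHASE_NAMES}, got {self.duration!r}"
            )

    def realize(self, channels: Sequence[str], n_trials: int, rng: np.random.Generator) -> None:
        """Draw the trial set and per-trial channel targets."""
        self.trials = schedule_trials(self.probability, n_trials, rng)
        self.targets = resolve_targets(self.channel, channels, n_trials, rng)

    def active(self, trial: int, phase: int, t_since_phase0: float) -> bool:
        """Whether the protocol is on at this instant of this trial.

        Phase-named durations are active during exactly that phase;
        numeric durations run in [onset, onset + duration) on the clock
        started at phase-0 onset, regardless of phase boundaries.
        """
        if trial not in self.trials:
            return False
        if isinstance(self.duration, str):
            return self.duration == f"phase {phase}"
        return self.onset <= t_since_phase0 < self.onset + float(self.duration)
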