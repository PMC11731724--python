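"""Dopamine-dependent corticostriatal plasticity and action values.

The agent keeps a Q-value per action, updated with a delta rule whose
prediction error drives a phasic dopamine transient:

    RPE       = reward - Q[choice]
    Q[choice] = Q[choice] + q_alpha * RPE
    D(t)      = C_scale * RPE * exp(-t / dpmn_tauDOP)     (baseline 0)

During the consolidation phase the corticostriatal weights of the selected
channel change in proportion to the integrated dopamine transient and an
activity-dependent eligibility (low-passed product of presynaptic cortical
and postsynaptic SPN firing, in kHz^2):

    dw = dpmn_alphaw * eligibility * C_scale * RPE * dpmn_tauDOP / 1000

``dpmn_alphaw`` is positive for dSPNs and negative for iSPNs, so a
dopamine transient above baseline strengthens the direct pathway and
weakens the indirect pathway of the selected channel; unselected channels
are untouched.  Weights are clipped to [0, dpmn_wmax].

Q-values book-keep the agent's reward history but never enter the decision
readout: choice depends only on the corticostriatal weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConfigError

__all__ = [
    "QState",
    "PlasticityParams",
    "WeightState",
    "update_q",
    "dopamine_signal",
    "eligibility",
    "update_weights",
]


@dataclass
class QState:
    """Per-action value estimates and learning constants."""

    q: dict[str, float]
    q_alpha: float = 0.1
    C_scale: float = 30.0

    @classmethod
    def initial(cls, actions, q0: float = 0.5, q_alpha: float = 0.1, C_scale: float = 30.0) -> "QState":
        return cls(q={a: float(q0) for a in actions}, q_alpha=q_alpha, C_scale=C_scale)


@dataclass
class PlasticityParams:
    """Dopamine and weight-update constants for one SPN target."""

    dpmn_alphaw: float            # signed learning rate (dSPN > 0, iSPN < 0)
    dpmn_wmax: float              # weight ceiling; floor is 0
    dpmn_tauDOP: float = 5.0      # ms, dopamine decay
    dpmn_baseline: float = 0.0    # phasic dopamine baseline

    def __post_init__(self) -> None:
        if self.dpmn_wmax <= 0:
            raise ConfigError("dpmn_wmax must be positive")
        if self.dpmn_tauDOP <= 0:
            raise ConfigError("dpmn_tauDOP must be positive")


@dataclass
class WeightState:
    """Corticostriatal weights per (channel, SPN target)."""

    w: dict[tuple[str, str], float] = field(default_factory=dict)

    def get(self, channel: str, target: str) -> float:
        return self.w[(channel, target)]


def update_q(qstate: QState, choice: str, reward: float) -> float:
    """Delta-rule update of the chosen action's value; returns the RPE."""
    if choice not in qstate.q:
        raise ConfigError(f"unknown action {choice!r}; known: {sorted(qstate.q)}")
    rpe = reward - qstate.q[choice]
    qstate.q[choice] += qstate.q_alpha * rpe
    return rpe


def dopamine_signal(
    rpe: float,
    params: PlasticityParams,
    C_scale: float = 30.0,
    dt: float = 0.1,
    duration: float | None = None,
) -> np.ndarray:
    """Phasic dopamine transient: impulse C_scale * RPE decaying with
    dpmn_tauDOP, on top of the (zero) baseline."""
    if duration is None:
        duration = 10.0 * params.dpmn_tauDOP
    t = np.arange(0.0, duration, dt)
    return params.dpmn_baseline + C_scale * rpe * np.exp(-t / params.dpmn_tauDOP)


def eligibility(pre_rate: float, post_rate: float) -> float:
    """Activity-dependent eligibility: product of mean presynaptic (cortical)
    and postsynaptic (SPN) firing over the consolidation phase, in kHz^2."""
    return (pre_rate / 1000.0) * (post_rate / 1000.0)


def update_weights(
    weights: WeightState,
    rpe: float,
    selected: str,
    phase1_rates: dict[str, float],
    dspn_params: PlasticityParams,
    ispn_params: PlasticityParams,
    C_scale: float = 30.0,
    enabled: bool = True,
) -> WeightState:
    """Apply the consolidation-phase weight update to the selected channel.

    ``phase1_rates`` holds the mean Cx/dSPN/iSPN firing rates (spikes/s) of
    the selected channel during phase 1.  With plasticity disabled the
    state is returned unchanged.
    """
    if not enabled:
        return weights
    cx = phase1_rates.get("Cx", 0.0)
    for target, params in (("dSPN", dspn_params), ("iSPN", ispn_params)):
        key = (selected, target)
        if key not in weights.w:
            continue
        dopamine_integral = C_scale * rpe * params.dpmn_tauDOP / 1000.0
        dw = params.dpmn_alphaw * eligibility(cx, phase1_rates.get(target, 0.0)) * dopamine_integral
        weights.w[key] = float(np.clip(weights.w[key] + dw, 0.0, params.dpmn_wmax))
    return weights
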