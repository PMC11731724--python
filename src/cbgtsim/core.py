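"""Conductance-based leaky integrate-and-fire dynamics.

Every neuron in the network follows the same single-compartment membrane
equation, integrated with forward Euler at a fixed step ``dt`` (default
0.1 ms)::

    C dV/dt = -g_L (V - V_rest) + I_syn + I_drive
    g_L     = C / Taum

with synaptic current contributed by three receptor classes,

    I_syn = -g_AMPA (V - E_ampa)
            -g_NMDA B(V) (V - E_ampa)
            -g_GABA (V - E_gaba)

where each conductance ``g_X`` is the sum of exponentially decaying gates
(decay constant ``Tau_X``) incremented by the efficacy of every presynaptic
spike, and the NMDA magnesium block follows

    B(V) = 1 / (1 + Mg/nmda_beta * exp(-nmda_gamma * V)).

A neuron whose potential reaches ``V_thresh`` at the start of a step emits a
spike, is reset to ``V_reset`` and is clamped there for the refractory
period.  All neurons crossing threshold within the same step spike
simultaneously.

Background drive
----------------
Each population receives external input modelled as a doubly stochastic
point process: the per-step rate is drawn from a normal distribution with
the configured mean (``rate * n_connections``) and unit variance on the
spikes/s scale, truncated at zero, and integer event counts per neuron are
then drawn from a Poisson distribution at that rate.  The mean event count
per step is therefore exactly ``rate * n_connections * dt`` while individual
neurons receive decorrelated shot noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellParams",
    "ReceptorParams",
    "BackgroundSpec",
    "PopulationState",
    "IntegrationDivergedError",
    "ConfigError",
    "step_population",
    "background_drive",
    "population_rate",
    "lif_steady_rate",
    "nmda_gate",
]


class ConfigError(ValueError):
    """Invalid configuration or parameter value."""


class IntegrationDivergedError(RuntimeError):
    """Membrane integration produced non-finite state."""


@dataclass
class CellParams:
    """Single-compartment membrane parameters shared by a population.

    ``C`` is in opaque model units; the leak conductance is derived as
    ``C / Taum`` so that the membrane relaxes with time constant ``Taum``.
    """

    C: float = 0.5
    Taum: float = 20.0          # ms
    V_rest: float = -70.0       # mV
    V_thresh: float = -50.0     # mV
    V_reset: float = -55.0      # mV
    refractory: float = 2.0     # ms
    E_ampa: float = 0.0         # mV
    E_gaba: float = -80.0       # mV
    Mg: float = 1.0             # mM, NMDA block

    def __post_init__(self) -> None:
        if self.Taum <= 0 or self.C <= 0:
            raise ConfigError("Taum and C must be positive")
        if self.V_reset >= self.V_thresh:
            raise ConfigError("V_reset must lie below V_thresh")

    @property
    def g_leak(self) -> float:
        return self.C / self.Taum


@dataclass
class ReceptorParams:
    """Receptor gate decay constants and NMDA voltage-gating constants."""

    Tau_AMPA: float = 2.0       # ms
    Tau_GABA: float = 5.0       # ms
    Tau_NMDA: float = 100.0     # ms
    nmda_gamma: float = 0.062   # 1/mV
    nmda_beta: float = 3.57     # mM

    def __post_init__(self) -> None:
        for name in ("Tau_AMPA", "Tau_GABA", "Tau_NMDA"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class BackgroundSpec:
    """External stochastic drive onto one population.

    ``rate`` is the mean event rate per connection in spikes/s;
    ``n_connections`` multiplies it; ``efficacy`` is the conductance
    increment per event; ``sign`` routes events onto the AMPA (excitatory)
    or GABA (inhibitory) gate.
    """

    rate: float                 # spikes/s per connection
    efficacy: float
    n_connections: int = 1
    sign: str = "excitatory"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ConfigError("background rate must be >= 0")
        if self.n_connections < 1:
            raise ConfigError("n_connections must be >= 1")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ConfigError("sign must be 'excitatory' or 'inhibitory'")


@dataclass
class PopulationState:
    """Per-neuron state of one population at one time step."""

    V: np.ndarray                       # mV
    g_ampa: np.ndarray
    g_nmda: np.ndarray
    g_gaba: np.ndarray
    refractory_until: np.ndarray        # ms, absolute clock time
    spiked: np.ndarray                  # bool, spikes of the current step
    t: float = 0.0                      # ms
    dt: float = 0.1                     # ms

    @classmethod
    def zeros(cls, n: int, cell: CellParams, dt: float = 0.1) -> "PopulationState":
        return cls(
            V=np.full(n, cell.V_rest, dtype=float),
            g_ampa=np.zeros(n),
            g_nmda=np.zeros(n),
            g_gaba=np.zeros(n),
            refractory_until=np.full(n, -np.inf),
            spiked=np.zeros(n, dtype=bool),
            dt=dt,
        )

    @property
    def n(self) -> int:
        return self.V.size


def nmda_gate(V: np.ndarray, cell: CellParams, recept: ReceptorParams) -> np.ndarray:
    """Voltage-dependent magnesium unblock factor of the NMDA conductance."""
    return 1.0 / (1.0 + (cell.Mg / recept.nmda_beta) * np.exp(-recept.nmda_gamma * V))


def step_population(
    state: PopulationState,
    cell: CellParams,
    recept: ReceptorParams,
    external_current: float | np.ndarray = 0.0,
    dt: float | None = None,
    label: str = "population",
) -> PopulationState:
    """Advance one population by one time step, in place.

    Spikes are detected from the potential at the start of the step
    (``V >= V_thresh`` emits a spike this step).  Receptor gates decay
    exponentially; increments from presynaptic spikes are the caller's
    responsibility (add to ``g_*`` between steps).  ``external_current`` is
    added directly to the membrane current (drive + opsin currents).
    """
    if dt is None:
        dt = state.dt
    if dt <= 0:
        raise ConfigError("dt must be positive")

    V = state.V
    spiked = V >= cell.V_thresh
    if np.any(spiked):
        V[spiked] = cell.V_reset
        state.refractory_until[spiked] = state.t + cell.refractory
    state.spiked = spiked

    # gate decay
    state.g_ampa *= np.exp(-dt / recept.Tau_AMPA)
    state.g_gaba *= np.exp(-dt / recept.Tau_GABA)
    state.g_nmda *= np.exp(-dt / recept.Tau_NMDA)

    active = state.t >= state.refractory_until
    if np.any(active):
        Va = V[active]
        b = nmda_gate(Va, cell, recept)
        i_syn = (
            -state.g_ampa[active] * (Va - cell.E_ampa)
            - state.g_nmda[active] * b * (Va - cell.E_ampa)
            - state.g_gaba[active] * (Va - cell.E_gaba)
        )
        i_ext = external_current[active] if isinstance(external_current, np.ndarray) else external_current
        V[active] = Va + (dt / cell.C) * (-cell.g_leak * (Va - cell.V_rest) + i_syn + i_ext)
    V[~active] = cell.V_reset

    if not np.all(np.isfinite(V)):
        raise IntegrationDivergedError(
            f"non-finite membrane potential in {label!r} at t={state.t:.3f} ms"
        )
    state.t += dt
    return state


def background_drive(
    spec: BackgroundSpec,
    rng: np.random.Generator,
    dt: float,
    n_neurons: int,
    rate_offset: float = 0.0,
) -> np.ndarray:
    """Draw per-neuron external event counts for one step.

    The per-step rate (spikes/s) is ``max(0, N(rate * n_connections +
    rate_offset, 1))``; event counts are Poisson at that rate.
    ``rate_offset`` carries time-varying additions (ramping stimulus, stop
    signals) and may not drive the total mean negative.
    """
    mean_rate = spec.rate * spec.n_connections + rate_offset
    if mean_rate < 0:
        raise ConfigError("total background rate must remain >= 0")
    if mean_rate == 0.0:
        return np.zeros(n_neurons)
    rate = rng.normal(mean_rate, 1.0, size=n_neurons)
    np.clip(rate, 0.0, None, out=rate)
    return rng.poisson(rate * (dt / 1000.0)).astype(float)


def population_rate(
    spikes: np.ndarray,
    window: float,
    dt: float,
    n_neurons: int | None = None,
) -> np.ndarray:
    """Binned population firing rate in spikes/s.

    ``spikes`` is a (steps, neurons) boolean/int raster or a (steps,) array
    of per-step population spike counts (then ``n_neurons`` is required).
    Non-overlapping bins of ``window`` ms; per-bin rate = count /
    (n_neurons * window).  An empty raster yields an all-zero trace.
    """
    if window <= 0:
        raise ConfigError("window must be positive")
    spikes = np.asarray(spikes)
    if spikes.ndim == 2:
        counts = spikes.sum(axis=1).astype(float)
        n_neurons = spikes.shape[1]
    else:
        if n_neurons is None:
            raise ConfigError("n_neurons required for 1-D spike counts")
        counts = spikes.astype(float)
    if counts.size == 0 or n_neurons == 0:
        return np.zeros(0)
    steps_per_bin = max(1, int(round(window / dt)))
    n_bins = int(np.ceil(counts.size / steps_per_bin))
    padded = np.zeros(n_bins * steps_per_bin)
    padded[: counts.size] = counts
    binned = padded.reshape(n_bins, steps_per_bin).sum(axis=1)
    return binned / (n_neurons * window / 1000.0)


def lif_steady_rate(cell: CellParams, current: float) -> float:
    """Closed-form firing rate (spikes/s) of a LIF neuron under constant current.

    rate = 1000 / (refractory + Taum * ln((I*R - V_reset + V_rest) /
                                          (I*R - V_thresh + V_rest)))
    with R = Taum / C.  Returns 0 for subthreshold current.
    """
    R = cell.Taum / cell.C
    v_inf = cell.V_rest + current * R
    if v_inf <= cell.V_thresh:
        return 0.0
    isi = cell.refractory + cell.Taum * np.log(
        (v_inf - cell.V_reset) / (v_inf - cell.V_thresh)
    )
    return 1000.0 / isi
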