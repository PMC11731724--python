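"""Realized network: drawn connectivity plus the vectorized integration loop.

All populations are flattened into one state vector so a step is a handful
of whole-network numpy operations: spike detection, gate decay, recurrent
propagation (gathering the outgoing rows of the spiking neurons), the
doubly stochastic background draw, and the Euler membrane update.  The
membrane and receptor equations are the ones documented in
:mod:`cbgtsim.core`; this module only reorganizes them for speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigError, IntegrationDivergedError
from .params import POPULATIONS, SHARED_POPS
from .build import NetworkSpec

__all__ = ["RealizedNetwork", "PopulationSlice"]

_RECEPTOR_GATES = {"AMPA": "g_ampa", "NMDA": "g_nmda", "GABA": "g_gaba"}


def _draw_adjacency(
    rng: np.random.Generator, n_pre: int, n_post: int, con: float, same: bool = False
) -> np.ndarray:
    """Fixed in-degree connectivity draw.

    Every postsynaptic neuron receives exactly round(con * n_available)
    connections from presynaptic partners sampled uniformly without
    replacement (self-connections excluded).  Keeping the in-degree fixed
    removes the quenched between-channel asymmetry that binomial in-degree
    variance would impose at the small population sizes this model runs at,
    while partner identity stays random under the build seed.
    """
    avail = n_pre - 1 if same else n_pre
    k = int(round(con * avail))
    adj = np.zeros((n_pre, n_post))
    if k <= 0:
        return adj
    for j in range(n_post):
        pick = rng.choice(avail, size=k, replace=False)
        if same:
            pick = pick + (pick >= j)  # skip the self index
        adj[pick, j] = 1.0
    return adj


@dataclass(frozen=True)
class PopulationSlice:
    """Index range of one population instance inside the flat state vector."""

    pop: str
    channel: str | None         # None for shared pools
    sl: slice

    @property
    def label(self) -> str:
        return self.pop if self.channel is None else f"{self.pop}_{self.channel}"

    @property
    def n(self) -> int:
        return self.sl.stop - self.sl.start


class RealizedNetwork:
    """A network with realized Bernoulli connectivity and mutable state.

    Rebuilding with the same :class:`NetworkSpec` and seed reproduces the
    identical adjacency; the simulation step itself draws randomness only
    from the generator passed to :meth:`step`.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0, dt: float = 0.1):
        if dt <= 0:
            raise ConfigError("dt must be positive")
        self.spec = spec
        self.seed = int(seed)
        self.dt = float(dt)
        self._layout()
        self._alloc_params()
        self._realize(np.random.default_rng(self.seed))
        self.reset_state()

    # ------------------------------------------------------------------ build

    def _layout(self) -> None:
        self.instances: list[PopulationSlice] = []
        start = 0
        for pop in POPULATIONS:
            n = self.spec.popsizes[pop]
            chans = [None] if pop in SHARED_POPS else self.spec.channels
            for ch in chans:
                self.instances.append(PopulationSlice(pop, ch, slice(start, start + n)))
                start += n
        self.n_neurons = start
        self._by_label = {inst.label: inst for inst in self.instances}
        self.pop_index = np.empty(self.n_neurons, dtype=int)
        for i, inst in enumerate(self.instances):
            self.pop_index[inst.sl] = i

    def instance(self, pop: str, channel: str | None = None) -> PopulationSlice:
        label = pop if pop in SHARED_POPS or channel is None else f"{pop}_{channel}"
        try:
            return self._by_label[label]
        except KeyError:
            raise ConfigError(f"no population instance {label!r}") from None

    def instances_of(self, pop: str) -> list[PopulationSlice]:
        return [inst for inst in self.instances if inst.pop == pop]

    def _alloc_params(self) -> None:
        n = self.n_neurons
        self.vrest = np.empty(n)
        self.vthresh = np.empty(n)
        self.vreset = np.empty(n)
        self.tref = np.empty(n)
        self.gl = np.empty(n)
        self.dt_over_C = np.empty(n)
        self.e_ampa = np.empty(n)
        self.e_gaba = np.empty(n)
        self.mg_coef = np.empty(n)
        for inst in self.instances:
            cell = self.spec.cell[inst.pop]
            s = inst.sl
            self.vrest[s] = cell.V_rest
            self.vthresh[s] = cell.V_thresh
            self.vreset[s] = cell.V_reset
            self.tref[s] = cell.refractory
            self.gl[s] = cell.g_leak
            self.dt_over_C[s] = self.dt / cell.C
            self.e_ampa[s] = cell.E_ampa
            self.e_gaba[s] = cell.E_gaba
            self.mg_coef[s] = cell.Mg / self.spec.recept.nmda_beta
        self.nmda_gamma = self.spec.recept.nmda_gamma
        self.dec_ampa = np.exp(-self.dt / self.spec.recept.Tau_AMPA)
        self.dec_gaba = np.exp(-self.dt / self.spec.recept.Tau_GABA)
        self.dec_nmda = np.exp(-self.dt / self.spec.recept.Tau_NMDA)

        # background streams (excitatory -> AMPA gate, inhibitory -> GABA gate)
        self.bg_rate_exc = np.zeros(n)
        self.bg_rate_inh = np.zeros(n)
        self.bg_eff = np.full(n, 0.01)
        for inst in self.instances:
            bg = self.spec.background.get(inst.pop)
            if bg is None:
                continue
            total = bg.rate * bg.n_connections
            if bg.sign == "excitatory":
                self.bg_rate_exc[inst.sl] = total
            else:
                self.bg_rate_inh[inst.sl] = total
            self.bg_eff[inst.sl] = bg.efficacy

    def _pairs(self, p) -> list[tuple[PopulationSlice, PopulationSlice]]:
        srcs = self.instances_of(p.src)
        dests = self.instances_of(p.dest)
        if p.type == "syn" and p.src not in SHARED_POPS and p.dest not in SHARED_POPS:
            return [
                (s, d) for s in srcs for d in dests if s.channel == d.channel
            ]
        return [(s, d) for s in srcs for d in dests]

    def _realize(self, rng: np.random.Generator) -> None:
        n = self.n_neurons
        self.W = {r: np.zeros((n, n)) for r in _RECEPTOR_GATES}
        # plastic corticostriatal blocks keyed by (channel, target population)
        self._plastic: dict[tuple[str, str], list[dict]] = {}
        self._edge_counts: list[dict] = []
        for p in self.spec.pathways:
            for src, dest in self._pairs(p):
                adj = _draw_adjacency(rng, src.n, dest.n, p.con, same=src.sl == dest.sl)
                self.W[p.receptor][src.sl, dest.sl] += adj * p.eff
                self._edge_counts.append(
                    dict(src=src.label, dest=dest.label, receptor=p.receptor,
                         edges=int(adj.sum()), eff=p.eff, plastic=p.plastic)
                )
                if p.plastic:
                    key = (dest.channel, dest.pop)
                    self._plastic.setdefault(key, []).append(
                        dict(receptor=p.receptor, src=src.sl, dest=dest.sl,
                             adj=adj, base_eff=p.eff,
                             ref=(p.receptor == "AMPA"))
                    )
        self._w_nonzero = {r: bool(np.any(self.W[r])) for r in self.W}
        # initial corticostriatal weights = efficacy of the plastic AMPA row
        self.weights: dict[tuple[str, str], float] = {}
        self.w_ref: dict[tuple[str, str], float] = {}
        for key, blocks in self._plastic.items():
            ref = next((b for b in blocks if b["ref"]), blocks[0])
            self.w_ref[key] = ref["base_eff"]
            self.weights[key] = ref["base_eff"]

    def summary(self) -> pd.DataFrame:
        """Population sizes and realized edge counts, one row per block."""
        return pd.DataFrame(self._edge_counts)

    # ---------------------------------------------------------------- weights

    def set_corticostriatal_weight(self, channel: str, target: str, w: float) -> None:
        key = (channel, target)
        if key not in self._plastic:
            raise ConfigError(f"no plastic pathway onto {target}_{channel}")
        ratio = w / self.w_ref[key]
        for b in self._plastic[key]:
            self.W[b["receptor"]][b["src"], b["dest"]] = b["adj"] * (b["base_eff"] * ratio)
            self._w_nonzero[b["receptor"]] = True
        self.weights[key] = float(w)

    # ------------------------------------------------------------------ state

    def reset_state(self) -> None:
        n = self.n_neurons
        self.V = self.vrest.copy()
        self.g_ampa = np.zeros(n)
        self.g_nmda = np.zeros(n)
        self.g_gaba = np.zeros(n)
        self.refr_until = np.full(n, -np.inf)
        self.t = 0.0

    # ------------------------------------------------------------------- step

    def step(
        self,
        rng: np.random.Generator,
        rate_offset: np.ndarray | None = None,
        ext_current: np.ndarray | None = None,
    ) -> np.ndarray:
        """Advance the whole network one time step; returns the spike vector.

        ``rate_offset`` (spikes/s per neuron) adds to the excitatory
        background stream (ramping stimulus, stop signals); ``ext_current``
        adds directly to the membrane current (optogenetic drive).
        """
        V = self.V
        spiked = V >= self.vthresh
        idx = np.nonzero(spiked)[0]
        if idx.size:
            V[idx] = self.vreset[idx]
            self.refr_until[idx] = self.t + self.tref[idx]

        self.g_ampa *= self.dec_ampa
        self.g_gaba *= self.dec_gaba
        self.g_nmda *= self.dec_nmda
        if idx.size:
            if self._w_nonzero["AMPA"]:
                self.g_ampa += self.W["AMPA"][idx].sum(axis=0)
            if self._w_nonzero["NMDA"]:
                self.g_nmda += self.W["NMDA"][idx].sum(axis=0)
            if self._w_nonzero["GABA"]:
                self.g_gaba += self.W["GABA"][idx].sum(axis=0)

        rate = self.bg_rate_exc if rate_offset is None else self.bg_rate_exc + rate_offset
        rate = rng.normal(rate, 1.0)
        np.clip(rate, 0.0, None, out=rate)
        counts = rng.poisson(rate * (self.dt / 1000.0))
        self.g_ampa += self.bg_eff * counts
        if np.any(self.bg_rate_inh):
            rate_i = np.clip(rng.normal(self.bg_rate_inh, 1.0), 0.0, None)
            self.g_gaba += self.bg_eff * rng.poisson(rate_i * (self.dt / 1000.0))

        active = self.t >= self.refr_until
        Va = V[active]
        b = 1.0 / (1.0 + self.mg_coef[active] * np.exp(-self.nmda_gamma * Va))
        i_syn = (
            -(self.g_ampa[active] + self.g_nmda[active] * b) * (Va - self.e_ampa[active])
            - self.g_gaba[active] * (Va - self.e_gaba[active])
        )
        if ext_current is not None:
            i_syn = i_syn + ext_current[active]
        V[active] = Va + self.dt_over_C[active] * (
            -self.gl[active] * (Va - self.vrest[active]) + i_syn
        )
        inactive = ~active
        V[inactive] = self.vreset[inactive]
        if not np.all(np.isfinite(V)):
            bad = int(np.nonzero(~np.isfinite(V))[0][0])
            label = self.instances[self.pop_index[bad]].label
            raise IntegrationDivergedError(
                f"non-finite membrane potential in {label!r} at t={self.t:.3f} ms"
            )
        self.t += self.dt
        return spiked

    def instance_counts(self, spiked: np.ndarray) -> np.ndarray:
        """Per-instance spike counts for one step (popfreqs accumulation)."""
        return np.bincount(self.pop_index, weights=spiked, minlength=len(self.instances))
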