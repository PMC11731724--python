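"""Network construction: populations, action channels and pathways.

The circuit comprises ten populations: cortex (Cx) with a shared inhibitory
pool (CxI); striatal direct- and indirect-pathway spiny projection neurons
(dSPN, iSPN) with shared fast-spiking interneurons (FSI); prototypical and
arkypallidal external pallidum (GPeP, GPeA); subthalamic nucleus (STN);
internal pallidum (GPi); and thalamus (Th).  For an n-choice agent every
population except FSI and CxI is replicated once per action channel.

Pathways are declared in a seven-column table (src, dest, receptor, type,
con, eff, plastic).  ``type`` is ``"syn"`` for channel-specific pathways
(connecting same-channel copies only) or ``"common"`` for diffuse pathways
(connecting across all channels and to/from the shared pools).  Realized
connectivity is drawn as independent Bernoulli(con) per ordered neuron
pair, with self-connections excluded, under a build seed.

When more than one action channel is instantiated, the efficacy of every
pathway that converges from channelized populations onto a shared pool (or
diffusely onto a common target) is divided by the channel count, so the
expected summed drive onto those targets is invariant in the number of
channels.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Any, Iterable

import numpy as np

from .core import BackgroundSpec, CellParams, ConfigError, ReceptorParams
from .params import POPULATIONS, SHARED_POPS, default_paramfile

__all__ = [
    "PathwaySpec",
    "NetworkSpec",
    "build_spec",
    "build_network",
    "apply_newpathways",
    "scale_shared_inputs",
    "resolve_population_name",
]

_RECEPTORS = ("AMPA", "NMDA", "GABA")
_ALIASES = {"GPe": "GPeP"}


def resolve_population_name(name: str) -> str:
    """Map a pathway-table population name onto a canonical population.

    ``"GPe"`` resolves to the prototypical subpopulation GPeP; arkypallidal
    cells must be named GPeA explicitly.
    """
    name = _ALIASES.get(name, name)
    if name not in POPULATIONS:
        raise ConfigError(
            f"unknown population {name!r}; valid names: {', '.join(POPULATIONS)} (GPe = GPeP)"
        )
    return name


@dataclass
class PathwaySpec:
    """One row of the pathway table."""

    src: str
    dest: str
    receptor: str
    type: str = "syn"
    con: float = 0.5
    eff: float = 0.01
    plastic: bool = False

    def __post_init__(self) -> None:
        self.src = resolve_population_name(self.src)
        self.dest = resolve_population_name(self.dest)
        if self.receptor not in _RECEPTORS:
            raise ConfigError(f"receptor must be one of {_RECEPTORS}, got {self.receptor!r}")
        if self.type not in ("syn", "common"):
            raise ConfigError(f"pathway type must be 'syn' or 'common', got {self.type!r}")
        if not 0.0 <= self.con <= 1.0:
            raise ConfigError(f"connection probability must be in [0, 1], got {self.con}")
        self.plastic = bool(self.plastic)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.src, self.dest, self.receptor)


@dataclass
class NetworkSpec:
    """Declarative description of a network before connectivity is drawn."""

    channels: list[str]
    popsizes: dict[str, int]
    pathways: list[PathwaySpec]
    background: dict[str, BackgroundSpec]
    cell: dict[str, CellParams]
    recept: ReceptorParams
    stim_scale: float = 1000.0

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def copy(self) -> "NetworkSpec":
        return copy.deepcopy(self)


def _coerce_pathway_rows(table: Any) -> list[PathwaySpec]:
    """Accept a DataFrame, a list of rows, or a list of tables."""
    try:
        import pandas as pd
    except ImportError:  # pragma: no cover
        pd = None
    if pd is not None and isinstance(table, pd.DataFrame):
        rows = table.values.tolist()
    elif isinstance(table, (list, tuple)) and table and (
        pd is not None and isinstance(table[0], pd.DataFrame)
    ):
        out: list[PathwaySpec] = []
        for sub in table:
            out.extend(_coerce_pathway_rows(sub))
        return out
    else:
        rows = list(table)
    specs = []
    for i, row in enumerate(rows):
        if isinstance(row, PathwaySpec):
            specs.append(row)
            continue
        if isinstance(row, dict):
            try:
                specs.append(PathwaySpec(**row))
            except (TypeError, ConfigError) as exc:
                raise ConfigError(f"malformed pathway row {i}: {exc}") from exc
            continue
        row = list(row)
        if len(row) != 7:
            raise ConfigError(f"malformed pathway row {i}: expected 7 fields, got {len(row)}")
        try:
            specs.append(PathwaySpec(*row))
        except ConfigError as exc:
            raise ConfigError(f"malformed pathway row {i}: {exc}") from exc
    return specs


def build_spec(
    paramfile: dict[str, Any] | None = None,
    channels: Iterable[str] = ("left", "right"),
    task: str = "n-choice",
) -> NetworkSpec:
    """Assemble a :class:`NetworkSpec` from a parameter file."""
    if paramfile is None:
        paramfile = default_paramfile(task)
    channels = [str(c) for c in channels]
    if len(channels) < 1:
        raise ConfigError("at least one channel label is required")
    if len(set(channels)) != len(channels):
        raise ConfigError("channel labels must be unique")

    recept = ReceptorParams(**paramfile["receptordefaults"])
    cell: dict[str, CellParams] = {}
    for pop in POPULATIONS:
        kw = dict(paramfile["celldefaults"])
        kw.update(paramfile.get("popspecific", {}).get(pop, {}))
        cell[pop] = CellParams(**kw)

    background: dict[str, BackgroundSpec] = {}
    for pop, entry in paramfile["basestim"].items():
        pop = resolve_population_name(pop)
        sign = "inhibitory" if "FreqExt_GABA" in entry else "excitatory"
        rate = entry.get("FreqExt_AMPA", entry.get("FreqExt_GABA", 0.0))
        background[pop] = BackgroundSpec(
            rate=float(rate),
            efficacy=float(entry.get("efficacy", 0.01)),
            n_connections=int(entry.get("n_connections", 1)),
            sign=sign,
        )

    pathways = _coerce_pathway_rows(paramfile["pathways"])
    return NetworkSpec(
        channels=channels,
        popsizes={p: int(paramfile["popsizes"][p]) for p in POPULATIONS},
        pathways=pathways,
        background=background,
        cell=cell,
        recept=recept,
        stim_scale=float(paramfile.get("stim_scale", 1000.0)),
    )


def apply_newpathways(spec: NetworkSpec, table: Any) -> NetworkSpec:
    """Override or append pathway rows.

    Rows matching an existing (src, dest, receptor) triple replace that
    row's remaining fields; novel triples are appended.  A list of tables is
    applied in order.  The input spec is not modified.
    """
    spec = spec.copy()
    if table is None:
        return spec
    for row in _coerce_pathway_rows(table):
        for i, existing in enumerate(spec.pathways):
            if existing.key == row.key:
                spec.pathways[i] = row
                break
        else:
            spec.pathways.append(row)
    return spec


def scale_shared_inputs(spec: NetworkSpec, n_channels: int | None = None) -> NetworkSpec:
    """Divide convergent efficacies by the channel count.

    Applies to every pathway whose source is channelized and whose target
    either is a shared pool (FSI, CxI) or receives the pathway diffusely
    (type ``"common"``), keeping the expected summed drive onto those
    targets independent of the number of action channels.
    """
    if n_channels is None:
        n_channels = spec.n_channels
    if n_channels < 1:
        raise ConfigError("n_channels must be >= 1")
    spec = spec.copy()
    if n_channels == 1:
        return spec
    for i, p in enumerate(spec.pathways):
        if p.src in SHARED_POPS:
            continue
        if p.dest in SHARED_POPS or p.type == "common":
            spec.pathways[i] = replace(p, eff=p.eff / n_channels)
    return spec


def build_network(
    paramfile: dict[str, Any] | None = None,
    channels: Iterable[str] = ("left", "right"),
    newpathways: Any = None,
    seed: int = 0,
    task: str = "n-choice",
    dt: float = 0.1,
):
    """Build and realize a network: spec -> pathway overrides -> scaling -> adjacency.

    Returns a :class:`cbgtsim.engine.RealizedNetwork` whose connectivity was
    drawn under ``seed``.
    """
    from .engine import RealizedNetwork

    spec = build_spec(paramfile, channels, task=task)
    spec = apply_newpathways(spec, newpathways)
    spec = scale_shared_inputs(spec)
    return RealizedNetwork(spec, seed=seed, dt=dt)
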