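"""Default agent parameter tables and parameter-file loading.

A parameter file is structured text (JSON or YAML) mirroring the model's
parameter tables: ``celldefaults`` (membrane parameters shared by all
neurons), ``popspecific`` (per-population overrides), ``receptordefaults``
(synaptic gate constants), ``basestim`` (background drive per population),
``dpmndefaults`` / ``dSPNdefaults`` / ``iSPNdefaults`` (dopamine and
corticostriatal plasticity constants), ``popsizes``, ``pathways`` (the
seven-column pathway table: src, dest, receptor, type, con, eff, plastic)
and ``stim_scale`` (spikes/s of external drive per unit of the maxstim /
stop-amplitude scale).

The shipped default files (``data/nchoice_params.json`` and
``data/stopsignal_params.json``) are tuned so that every nucleus shows a
stable, distinguishable baseline firing rate and decisions complete within
a few hundred milliseconds at the default drive.  They are this package's
own operating point, not a reproduction of any published parameter set.
The stop-signal file additionally wires the pallidostriatal (arkypallidal)
projections, which participate only in the stop-signal task.
"""

from __future__ import annotations

import copy
import json
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .core import ConfigError

__all__ = ["load_paramfile", "default_paramfile", "PARAM_TABLES", "POPULATIONS", "SHARED_POPS"]

POPULATIONS = ("Cx", "CxI", "dSPN", "iSPN", "FSI", "GPeP", "GPeA", "STN", "GPi", "Th")
SHARED_POPS = frozenset({"FSI", "CxI"})

PARAM_TABLES = (
    "celldefaults",
    "popspecific",
    "receptordefaults",
    "basestim",
    "dpmndefaults",
    "dSPNdefaults",
    "iSPNdefaults",
    "popsizes",
    "pathways",
    "stim_scale",
)

_TASK_FILES = {
    "n-choice": "nchoice_params.json",
    "stop-signal": "stopsignal_params.json",
}


def default_paramfile(task: str = "n-choice") -> dict[str, Any]:
    """Return a deep copy of the shipped default parameter file for a task."""
    if task not in _TASK_FILES:
        raise ConfigError(
            f"unknown task {task!r}; expected one of {sorted(_TASK_FILES)}"
        )
    text = resources.files("cbgtsim.data").joinpath(_TASK_FILES[task]).read_text()
    return json.loads(text)


def load_paramfile(path: str | Path) -> dict[str, Any]:
    """Load a JSON or YAML parameter file and check its table structure."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return validate_paramfile(raw)


def validate_paramfile(raw: dict[str, Any]) -> dict[str, Any]:
    """Fill missing tables from the defaults and sanity-check entries."""
    if not isinstance(raw, dict):
        raise ConfigError("parameter file must be a mapping of tables")
    merged = default_paramfile()
    for key, value in raw.items():
        if key not in PARAM_TABLES:
            raise ConfigError(
                f"unknown parameter table {key!r}; expected one of {PARAM_TABLES}"
            )
        if key in ("pathways",):
            merged[key] = copy.deepcopy(value)
        elif isinstance(value, dict):
            # shallow table of scalars or of per-population sub-tables
            for k, v in value.items():
                if isinstance(v, dict):
                    merged[key].setdefault(k, {}).update(v)
                else:
                    merged[key][k] = v
        else:
            merged[key] = value
    for pop in merged["popsizes"]:
        if pop not in POPULATIONS:
            raise ConfigError(f"unknown population {pop!r} in popsizes")
        if merged["popsizes"][pop] < 1:
            raise ConfigError(f"population {pop!r} must have >= 1 neuron")
    return merged
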