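"""Configuration parsing and validation.

A simulation is driven by a flat keyed record (dict) whose keys mirror the
agent and environment parameter families: task choice and seed; trial
timing (inter_trial_interval, movement_time, choice_timeout); neural
parameter overrides (params, pops, receps, base, dpmns, dSPN_params,
iSPN_params, newpathways); action channels and reward environment
(channels, number_of_choices, n_trials, volatility, conflict, reward_mu,
reward_std); decision readout (thalamic_threshold, maxstim,
sustainedfraction); learning (Q_support_params, Q_df,
corticostriatal_plasticity_present); recording (record_variables); and the
opt_signal_* / stop_signal_* stimulation families, each a list aligned by
target population.

``None`` values request the documented defaults.  Tables may be given as
pandas DataFrames (single row), dicts, or dicts of per-population dicts;
scalar values wrapped in one-element lists are unwrapped.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import ConfigError
from .params import default_paramfile
from .stimulation import StimulationProtocol

__all__ = ["Configuration", "validate_config", "CONFIG_DEFAULTS"]

CONFIG_DEFAULTS: dict[str, Any] = {
    "experimentchoice": "n-choice",
    "seed": 0,
    "inter_trial_interval": 600.0,
    "thalamic_threshold": 30.0,
    "movement_time": None,
    "choice_timeout": None,     # 1000 ms n-choice, 300 ms stop-signal
    "params": None,
    "pops": None,
    "receps": None,
    "base": None,
    "dpmns": None,
    "dSPN_params": None,
    "iSPN_params": None,
    "channels": None,
    "number_of_choices": None,
    "newpathways": None,
    "Q_support_params": None,   # C_scale 30, q_alpha 0.1
    "Q_df": None,               # 0.5 per action
    "n_trials": 3,
    "volatility": None,
    "conflict": None,
    "reward_mu": 1.0,
    "reward_std": 0.1,
    "maxstim": 0.8,
    "corticostriatal_plasticity_present": None,
    "record_variables": (),
    "sustainedfraction": 0.7,
}

_STIM_KEYS = ("present", "probability", "amplitude", "onset", "duration", "channel", "population")


def _unwrap(value: Any) -> Any:
    """Unwrap one-element lists ([60] -> 60), the printed table convention."""
    if isinstance(value, (list, tuple)) and len(value) == 1 and np.isscalar(value[0]):
        return value[0]
    return value


def _as_table(value: Any, name: str) -> dict[str, Any]:
    """Coerce a one-row DataFrame / dict into a flat {column: scalar} dict."""
    if value is None:
        return {}
    try:
        import pandas as pd
    except ImportError:  # pragma: no cover
        pd = None
    if pd is not None and isinstance(value, pd.DataFrame):
        if len(value) != 1:
            raise ConfigError(f"{name} table must have exactly one row")
        return {str(c): _unwrap(value.iloc[0][c]) for c in value.columns}
    if isinstance(value, dict):
        return {str(k): _unwrap(v) for k, v in value.items()}
    raise ConfigError(f"{name} must be a one-row DataFrame or a dict")


def _as_nested(value: Any, name: str) -> dict[str, dict[str, Any]]:
    """Coerce per-population override tables ({pop: {param: value}})."""
    if value is None:
        return {}
    if not isinstance(value, dict):
        raise ConfigError(f"{name} must be a dict of per-population tables")
    return {str(pop): _as_table(tab, f"{name}[{pop}]") for pop, tab in value.items()}


def _channel_labels(value: Any, n: int | None) -> list[str]:
    try:
        import pandas as pd
    except ImportError:  # pragma: no cover
        pd = None
    if value is None:
        labels = ["left", "right"] if n in (None, 2) else [chr(ord("A") + i) for i in range(n)]
    elif pd is not None and isinstance(value, pd.DataFrame):
        labels = [str(v) for v in value.iloc[:, 0]]
    else:
        labels = [str(v) for v in value]
    if len(set(labels)) != len(labels):
        raise ConfigError("channel labels must be unique")
    return labels


@dataclass
class Configuration:
    """Validated, normalized configuration (all plain picklable types)."""

    experimentchoice: str
    seed: int
    channels: list[str]
    n_trials: int
    conflict: tuple[float, ...]
    volatility: tuple[float | None, str]
    inter_trial_interval: float
    thalamic_threshold: float
    movement_time: Any
    choice_timeout: float
    reward_mu: float
    reward_std: float
    maxstim: float
    sustainedfraction: float
    corticostriatal_plasticity_present: bool
    record_variables: list[str]
    q_alpha: float
    C_scale: float
    q0: dict[str, float]
    paramfile: dict[str, Any]
    newpathways: Any
    protocols: list[StimulationProtocol]
    raw: dict[str, Any] = field(default_factory=dict)

    @property
    def number_of_choices(self) -> int:
        return len(self.channels)


def _stim_family(raw: dict, prefix: str, kind: str) -> list[StimulationProtocol]:
    present = raw.get(f"{prefix}_present")
    if not present:
        return []
    if not isinstance(present, (list, tuple)):
        raise ConfigError(f"{prefix}_present must be a list of booleans")
    n = len(present)
    fams = {}
    for key in _STIM_KEYS[1:]:
        v = raw.get(f"{prefix}_{key}")
        # tolerate the 'populations' plural spelling for the stop family
        if v is None and key == "population":
            v = raw.get(f"{prefix}_populations")
        if v is None:
            raise ConfigError(f"{prefix}_present given but {prefix}_{key} missing")
        if not isinstance(v, (list, tuple)) or len(v) != n:
            raise ConfigError(
                f"{prefix}_{key} must be a list aligned with {prefix}_present (length {n})"
            )
        fams[key] = list(v)
    protocols = []
    for i in range(n):
        if not present[i]:
            continue
        protocols.append(
            StimulationProtocol(
                kind=kind,
                amplitude=float(fams["amplitude"][i]),
                population=str(fams["population"][i]),
                onset=float(fams["onset"][i]),
                duration=fams["duration"][i] if isinstance(fams["duration"][i], str)
                else float(fams["duration"][i]),
                probability=fams["probability"][i],
                channel=str(fams["channel"][i]),
            )
        )
    return protocols


def validate_config(raw: dict[str, Any]) -> Configuration:
    """Validate a raw configuration record and fill documented defaults."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a keyed record (dict)")
    raw = dict(raw)

    task = raw.get("experimentchoice") or raw.get("experiment_choice") or "n-choice"
    if task not in ("n-choice", "stop-signal"):
        raise ConfigError(
            f"experimentchoice must be 'n-choice' or 'stop-signal', got {task!r}"
        )

    def get(key: str) -> Any:
        v = raw.get(key)
        return CONFIG_DEFAULTS.get(key) if v is None else v

    n_choices = raw.get("number_of_choices")
    channels = _channel_labels(raw.get("channels"), n_choices)
    if n_choices is not None and int(n_choices) != len(channels):
        raise ConfigError(
            f"number_of_choices ({n_choices}) does not match channels ({len(channels)})"
        )

    conflict = raw.get("conflict")
    if conflict is None:
        conflict = tuple([1.0] + [0.0] * (len(channels) - 1))
    conflict = tuple(float(p) for p in conflict)
    if len(conflict) != len(channels):
        raise ConfigError(
            f"conflict (width {len(conflict)}) must match channels (width {len(channels)})"
        )

    n_trials = int(get("n_trials"))
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")

    volatility = raw.get("volatility")
    if volatility is None:
        volatility = (None, "exact")
    lam, mode = volatility[0], volatility[1]
    if lam is not None:
        lam = float(lam)
        if n_trials == 1:
            raise ConfigError(
                "with a single trial the volatility parameter must be set to None"
            )
        if lam <= 0 or lam >= n_trials:
            raise ConfigError(
                "volatility lambda cannot be 0 or reach the total number of trials"
            )
    elif task == "n-choice" and n_trials > 1 and len(channels) > 1:
        lam = None  # contingencies never switch; allowed, caller's choice

    choice_timeout = raw.get("choice_timeout")
    if choice_timeout is None:
        choice_timeout = 300.0 if task == "stop-signal" else 1000.0

    plast = raw.get("corticostriatal_plasticity_present")
    if task == "stop-signal":
        plast = False
    elif plast is None:
        plast = True

    # learning constants
    qsup = _as_table(raw.get("Q_support_params"), "Q_support_params")
    q_alpha = float(qsup.get("q_alpha", 0.1))
    C_scale = float(qsup.get("C_scale", 30.0))
    qdf = raw.get("Q_df", raw.get("Q_df_set"))
    if qdf is None:
        q0 = {ch: 0.5 for ch in channels}
    else:
        q0 = {str(k): float(v) for k, v in _as_table(qdf, "Q_df").items()}
        if set(q0) != set(channels):
            raise ConfigError(
                f"Q_df columns {sorted(q0)} must match channels {channels}"
            )

    # assemble the merged parameter file (an explicit "paramfile" entry, as
    # produced by load_paramfile or the fixture generator, replaces the
    # shipped defaults before the per-key overrides are applied)
    if raw.get("paramfile"):
        paramfile = copy.deepcopy(raw["paramfile"])
    else:
        paramfile = default_paramfile(task)
    paramfile["celldefaults"].update(_as_table(raw.get("params"), "params"))
    for pop, tab in _as_nested(raw.get("pops"), "pops").items():
        paramfile["popspecific"].setdefault(pop, {}).update(tab)
    paramfile["receptordefaults"].update(_as_table(raw.get("receps"), "receps"))
    for pop, tab in _as_nested(raw.get("base"), "base").items():
        paramfile["basestim"].setdefault(pop, {}).update(tab)
    paramfile["dpmndefaults"].update(_as_table(raw.get("dpmns"), "dpmns"))
    paramfile["dSPNdefaults"].update(_as_table(raw.get("dSPN_params"), "dSPN_params"))
    paramfile["iSPNdefaults"].update(_as_table(raw.get("iSPN_params"), "iSPN_params"))

    protocols = _stim_family(raw, "opt_signal", "opto") + _stim_family(
        raw, "stop_signal", "stop"
    )
    if task == "stop-signal" and "stop_signal_present" not in raw:
        raise ConfigError(
            "the stop-signal task requires the stop_signal_* parameter family"
        )

    record_variables = list(get("record_variables") or ())

    cfg = Configuration(
        experimentchoice=task,
        seed=int(get("seed")),
        channels=channels,
        n_trials=n_trials,
        conflict=conflict,
        volatility=(lam, str(mode)),
        inter_trial_interval=float(get("inter_trial_interval")),
        thalamic_threshold=float(get("thalamic_threshold")),
        movement_time=raw.get("movement_time"),
        choice_timeout=float(choice_timeout),
        reward_mu=float(get("reward_mu")),
        reward_std=float(get("reward_std")),
        maxstim=float(get("maxstim")),
        sustainedfraction=float(get("sustainedfraction")),
        corticostriatal_plasticity_present=bool(plast),
        record_variables=record_variables,
        q_alpha=q_alpha,
        C_scale=C_scale,
        q0=q0,
        paramfile=paramfile,
        newpathways=_plain_newpathways(raw.get("newpathways")),
        protocols=protocols,
        raw=_jsonable(raw),
    )
    return cfg


def _plain_newpathways(value: Any) -> Any:
    if value is None:
        return None
    try:
        import pandas as pd
    except ImportError:  # pragma: no cover
        return value
    if isinstance(value, pd.DataFrame):
        return value.values.tolist()
    if isinstance(value, (list, tuple)) and value and isinstance(value[0], pd.DataFrame):
        out = []
        for sub in value:
            out.extend(sub.values.tolist())
        return out
    return value


def _jsonable(obj: Any) -> Any:
    """Echo-able copy of the raw config (DataFrames -> row lists)."""
    try:
        import pandas as pd
    except ImportError:  # pragma: no cover
        pd = None
    if pd is not None and isinstance(obj, pd.DataFrame):
        return {"columns": [str(c) for c in obj.columns], "rows": obj.values.tolist()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
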