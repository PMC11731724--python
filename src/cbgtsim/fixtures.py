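"""Programmatic test fixtures: miniature networks and ready-made configs."""

from __future__ import annotations

from typing import Any

from .core import ConfigError
from .params import default_paramfile

__all__ = ["make_fixture_network", "FIXTURE_SIZES"]

FIXTURE_SIZES = {
    # full topology at a fraction of the default scale; "tiny" trades
    # decision reliability for speed and suits smoke tests only
    "tiny": {"Cx": 12, "CxI": 6, "dSPN": 6, "iSPN": 6, "FSI": 4,
             "GPeP": 6, "GPeA": 4, "STN": 6, "GPi": 6, "Th": 12},
    "small": {"Cx": 24, "CxI": 12, "dSPN": 12, "iSPN": 12, "FSI": 6,
              "GPeP": 12, "GPeA": 6, "STN": 12, "GPi": 12, "Th": 30},
}


def make_fixture_network(
    scale: str = "small",
    seed: int = 0,
    task: str = "n-choice",
    channels: tuple[str, ...] = ("left", "right"),
    n_trials: int = 1,
) -> tuple[dict[str, Any], dict[str, Any]]:
    """Return (paramfile, configuration) for a miniature test network.

    The paramfile is the shipped default with reduced population sizes; the
    configuration is minimal and deterministic under ``seed``.
    """
    if scale not in FIXTURE_SIZES:
        raise ConfigError(f"scale must be one of {sorted(FIXTURE_SIZES)}")
    paramfile = default_paramfile(task)
    paramfile["popsizes"] = dict(FIXTURE_SIZES[scale])
    config: dict[str, Any] = {
        "experimentchoice": task,
        "seed": seed,
        "channels": list(channels),
        "number_of_choices": len(channels),
        "n_trials": n_trials,
        "volatility": [None, "exact"],
        "conflict": tuple([1.0] + [0.0] * (len(channels) - 1)),
        "reward_mu": 1.0,
        "reward_std": 0.0,
        "paramfile": paramfile,
    }
    if task == "stop-signal":
        config.update(
            stop_signal_present=[True],
            stop_signal_probability=[1.0],
            stop_signal_amplitude=[0.6],
            stop_signal_onset=[30.0],
            stop_signal_duration=[145.0],
            stop_signal_channel=["all"],
            stop_signal_population=["STN"],
        )
    return paramfile, config
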